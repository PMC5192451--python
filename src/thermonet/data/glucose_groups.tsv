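compound	group	count
Glucose	OH- (secondary)	4
Glucose	-O- (ring)	1
Glucose	>CH2	1
Glucose	>CH- (ring)	5
Glucose	OH- (primary)	1
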