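group	contribution_kj_mol
Ori	-103.4
OH- (secondary)	-131.5
-O- (ring)	-101.7
>CH2	7.1
>CH- (ring)	-10.9
OH- (primary)	-119.7
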