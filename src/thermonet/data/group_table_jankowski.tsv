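group	contribution_kj_mol
Ori	0.0
OH- (secondary)	-173.8
-O- (ring)	-153.2
>CH2	6.8
>CH- (ring)	20.3
OH- (primary)	-173.8
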