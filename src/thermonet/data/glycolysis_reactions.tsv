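id	equation
HEX1	Glucose + ATP = Glucose 6-phosphate + ADP
PGI	Glucose 6-phosphate = Fructose 6-phosphate
PFK	Fructose 6-phosphate + ATP = Fructose 1,6-bisphosphate + ADP
FBA	Fructose 1,6-bisphosphate = Glycerone phosphate + Glyceraldehyde 3-phosphate
TPI	Glycerone phosphate = Glyceraldehyde 3-phosphate
GAPD	Glyceraldehyde 3-phosphate + Pi + NAD = NADH + 3-Phospho-glyceroyl phosphate
PGK	3-Phospho-glyceroyl phosphate + ADP = 3-Phospho-glycerate + ATP
PGM	3-Phospho-glycerate = 2-Phospho-glycerate
ENO	2-Phospho-glycerate = Phosphoenolpyruvate + H2O
PYK	Phosphoenolpyruvate + ADP = Pyruvate + ATP
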