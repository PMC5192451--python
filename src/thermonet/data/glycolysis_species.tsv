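# Species of the yeast glycolysis network, one row per protonation state.
# dfg0_kj_mol values for NAD/NADH are on the NAD-as-zero reference convention
# (reference_group "nicotinamide"); all other rows are absolute.
name	dfg0_kj_mol	charge	n_hydrogen	reactant	compartment	reference_group
3-Phospho-glyceroyl phosphate_4-	-2356.14	-4	4	3-Phospho-glyceroyl phosphate	cytosol
3-Phospho-glyceroyl phosphate_3-	-2401.58	-3	5	3-Phospho-glyceroyl phosphate	cytosol
2-Phospho-glycerate_3-	-1496.38	-3	4	2-Phospho-glycerate	cytosol
2-Phospho-glycerate_2-	-1539.99	-2	5	2-Phospho-glycerate	cytosol
3-Phospho-glycerate_3-	-1502.54	-3	4	3-Phospho-glycerate	cytosol
3-Phospho-glycerate_2-	-1545.52	-2	5	3-Phospho-glycerate	cytosol
ADP_3-	-1906.13	-3	12	ADP	cytosol
ADP_2-	-1947.1	-2	13	ADP	cytosol
ADP_1-	-1971.98	-1	14	ADP	cytosol
ATP_4-	-2768.1	-4	12	ATP	cytosol
ATP_3-	-2811.48	-3	13	ATP	cytosol
ATP_2-	-2838.18	-2	14	ATP	cytosol
Glycerone phosphate_2-	-1296.26	-2	5	Glycerone phosphate	cytosol
Glycerone phosphate_1-	-1328.8	-1	6	Glycerone phosphate	cytosol
Fructose 6-phosphate_2-	-1760.8	-2	11	Fructose 6-phosphate	cytosol
Fructose 6-phosphate_1-	-1796.6	-1	12	Fructose 6-phosphate	cytosol
Fructose 1,6-bisphosphate_4-	-2601.4	-4	10	Fructose 1,6-bisphosphate	cytosol
Fructose 1,6-bisphosphate_3-	-2639.36	-3	11	Fructose 1,6-bisphosphate	cytosol
Fructose 1,6-bisphosphate_2-	-2673.89	-2	12	Fructose 1,6-bisphosphate	cytosol
Glyceraldehyde 3-phosphate_2-	-1288.6	-2	5	Glyceraldehyde 3-phosphate	cytosol
Glyceraldehyde 3-phosphate_1-	-1321.14	-1	6	Glyceraldehyde 3-phosphate	cytosol
Glucose	-915.9	0	12	Glucose	cytosol
Glucose 6-phosphate_2-	-1763.94	-2	11	Glucose 6-phosphate	cytosol
Glucose 6-phosphate_1-	-1800.59	-1	12	Glucose 6-phosphate	cytosol
H2O	-237.19	0	2	H2O	cytosol
NAD	0	-1	26	NAD	cytosol	nicotinamide
NADH	22.65	-2	27	NADH	cytosol	nicotinamide
Phosphoenolpyruvate_3-	-1263.65	-3	2	Phosphoenolpyruvate	cytosol
Phosphoenolpyruvate_2-	-1303.61	-2	3	Phosphoenolpyruvate	cytosol
Pi_2-	-1096.1	-2	1	Pi	cytosol
Pi_1-	-1137.3	-1	2	Pi	cytosol
Pyruvate	-472.27	-1	3	Pyruvate	cytosol
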