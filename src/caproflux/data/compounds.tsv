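name	formula_C	formula_H	formula_O	molar_mass	n_carbon	electron_eq	pKa	extractable
lactate	3	6	3	90.08	3	12	3.86	0
acetate	2	4	2	60.05	2	8	4.76	0
propionate	3	6	2	74.08	3	14	4.87	0
n-butyrate	4	8	2	88.11	4	20	4.82	0
n-valerate	5	10	2	102.13	5	26	4.84	0
n-caproate	6	12	2	116.16	6	32	4.88	1
n-heptylate	7	14	2	130.18	7	38	4.89	1
n-caprylate	8	16	2	144.21	8	44	4.89	1
H2	0	2	0	2.016	0	2		0
CH4	1	4	0	16.04	1	8		0
CO2	1	0	2	44.01	1	0		0
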