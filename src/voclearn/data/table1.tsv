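variable	nw_mean	nw_sd	nw_n	ow_mean	ow_sd	ow_n	p_value
Age (years)	12.9	1.5	28	12.5	1.1	21	0.288
BMI (kg/m2)	19.5	1.8	28	26.7	4.2	21	0.001
Height (cm)	155.0	8.8	28	153.7	8.2	21	0.364
Weight (kg)	47.2	7.8	28	62.7	13.9	21	0.001
Glucose (mg/dl)	93.8	5.9	28	94.1	6.2	21	0.879
HOMA-IR	1.8	1.2	28	1.9	1.4	21	0.794
Energy (kcal/day)	1715.9	678.7	28	1748.0	889.3	21	0.889
Energy fat (%)	32.0	7.6	28	27.7	7.4	21	0.057
Energy carbohydrate (%)	51.2	8.3	28	55.4	10.5	21	0.138
Energy protein (%)	16.3	3.9	28	15.7	6.1	21	0.658
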