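metabolite	direction	auc_ci_low	auc_ci_high	power_roc	specificity	sensitivity	t_p_value	power_t	q_value
5-Methyl-3-hexanone	OW/Ob>NW	0.606	0.899	0.89	1.00	0.52	2.5E-04	0.92	9.5E-03
1-Heptanol	OW/Ob>NW	0.563	0.879	0.79	0.79	0.71	3.4E-03	0.78	3.6E-02
4-Methyl-2-heptanone	OW/Ob>NW	0.543	0.840	0.66	0.64	0.71	3.8E-03	0.77	3.6E-02
2-Hexanol	OW/Ob>NW	0.541	0.815	0.60	0.79	0.52	6.4E-03	0.68	4.0E-02
Dimethyl sulfone	OW/Ob>NW	0.548	0.852	0.70	0.71	0.71	7.5E-03	0.72	4.0E-02
Formammide N,N-dibutyl	OW/Ob>NW	0.515	0.828	0.56	0.61	0.67	1.6E-02	0.56	5.0E-02
1-Hexanol	OW/Ob>NW	0.448	0.782	0.29	0.71	0.57	2.1E-02	0.51	6.0E-02
2-Pentanone	OW/Ob>NW	0.556	0.881	0.78	0.82	0.67	2.2E-02	0.49	6.0E-02
2,4,6-Trimethyl-pyridine	OW/Ob>NW	0.508	0.804	0.49	0.68	0.62	2.7E-02	0.46	6.5E-02
3-Hexanone	OW/Ob>NW	0.517	0.829	0.57	0.64	0.71	2.8E-02	0.49	6.5E-02
3-Octanone	OW/Ob>NW	0.637	0.903	0.93	0.75	0.81	5.0E-02	0.50	8.2E-02
2,4,4-Trimethyl-1-pentanol	OW/Ob>NW	0.529	0.837	0.62	0.54	1.00	7.6E-02	0.32	1.1E-01
1H pyrrole-2-methyl	NW>OW/Ob	0.588	0.862	0.80	0.61	0.90	1.3E-03	0.96	2.4E-02
1-Methyl-2-piperidone	NW>OW/Ob	0.526	0.831	0.60	0.75	0.52	1.3E-02	0.77	4.9E-02
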