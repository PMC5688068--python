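metabolite	chemical_class	mz	match_percent	ri_cal	ri_lit	id_method	occurrence_nw	occurrence_ow
Acetone	Ketones	43	80	—	—	MS/S	100	100
2-Butanone	Ketones	43	90	—	—	MS/S	93	91
2-Pentanone	Ketones	43	72	—	—	MS/S	100	100
3-Pentanone 2,4-dimethyl	Ketones	43	64	—	—	MS	30	4
2-Pentanone 4-methyl	Ketones	43	53	1008	1008	RI/MS	59	65
2-Pentanone-3-methyl	Ketones	43	60	1011	1013	RI/MS	59	65
3-Hexanone	Ketones	43	91	1057	1057	RI/MS	100	96
4-Heptanone	Ketones	43/71	91	1134	1131	RI/MS	100	100
3-Heptanone	Ketones	43/72	64	1160	1162	RI/MS	18	17
2-Heptanone	Ketones	58	87	1192	1191	RI/MS	96	96
4-Octanone	Ketones	43	90	1235	1236	RI/MS	33	39
6-Methyl-5-hepten-2-one	Ketones	43	87	1349	1347	RI/MS	30	30
2-Nonanone	Ketones	58	68	1395	1395	RI/MS	81	78
Isophorone	Ketones	82	86	1402	1607	RI/MS	44	39
Pinocarvone	Ketones	81/108	76	1577	1585	RI/MS	93	100
p-Menthone	Ketones	112	98	1504	1478	RI/MS	4	0
4-Methylacetophenone	Ketones	119	94	—	—	MS	4	9
2-Propanol	Alcohols	45	80	—	—	MS/S	4	—
Ethanol	Alcohols	45	72	—	—	MS/S	100	100
3-Buten-2-ol 2-methyl	Alcohols	71	87	1048	1048	RI/MS	41	56
Isoamyl alcohol	Alcohols	55	78	1223	1222	RI/MS	15	4
1-Hexanol	Alcohols	56	50	1359	1358	RI/MS	74	65
3-Octanol	Alcohols	59	83	1402	1401	RI/MS	41	48
1-Heptanol	Alcohols	70	72	1455	1454	RI/MS	59	52
1-Hexanol-2-ethyl	Alcohols	57	86	1504	1503	RI/MS	96	87
1-Octanol	Alcohols	56	80	1569	1566	RI/MS/S	89	87
Isopulegol	Alcohols	41	95	1573	1574	RI/MS	26	9
Endo fenchol	Alcohols	81	94	1586	1579	RI/MS/S	33	13
2-Furanmethanol	Alcohols	98	95	1674	1678	RI/MS	89	91
1-Decanol	Alcohols	55	83	1776	1778	RI/MS	7	9
Nerol	Alcohols	69	91	1795	1794	RI/MS/S	—	4
Geraniol	Alcohols	69	81	—	—	MS/S	11	9
2-Methyl butanal	Aldehydes	57	59	—	—	MS/S	93	91
3-Methyl butanal	Aldehydes	44	64	—	—	MS/S	81	78
Pentanal	Aldehydes	44	90	—	—	MS/S	4	22
Hexanal	Aldehydes	44	94	1088	1087	RI/MS	100	100
Heptanal	Aldehydes	70	93	1196	1195	RI/MS	41	52
2-Hexanal (E)	Aldehydes	55	93	1231	1230	RI/MS/S	44	22
Furfural	Aldehydes	96	78	1475	1474	RI/MS	37	48
Myrtenal	Aldehydes	79	95	1642	1642	RI/MS	74	74
Benzaldehyde	Aldehydes	105	90	1537	1537	RI/MS/S	15	—
Phellandral	Aldehydes	109	95	1738	1741	RI/MS	11	22
Acetic acid	Acids	43	80	1463	1465	RI/MS	67	52
Propanoic acid 2,2-dimethyl	Acids	57	72	1586	1582	RI/MS	33	22
Nonanoic acid	Acids	60	94	—	—	MS/S	33	30
alpha-Pinene	Terpenes	93	96	1020	1027	RI/MS/S	11	—
alpha-Fenchene	Terpenes	93	72	1054	1071	RI/MS/S	33	43
Camphene	Terpenes	93	92	1053	1053	RI/MS	4	4
Verbenene	Terpenes	91	70	1122	1126	RI/MS	74	78
Phellandrene	Terpenes	93	90	1168	1177	RI/MS	59	61
beta-Myrcene	Terpenes	93	83	1171	1171	RI/MS/S	15	17
alpha-Terpinene	Terpenes	121	97	1183	1183	RI/MS/S	93	87
1,5,8 p-menthatriene	Terpenes	91	94	1202	1210	RI/MS	41	30
dl-limonene	Terpenes	68	97	1205	1206	RI/MS/S	74	91
Eucalyptol	Terpenes	93	96	1215	1215	RI/MS	52	52
cis beta-ocymene	Terpenes	93	74	1251	1250	RI/MS/S	41	30
gamma-Terpinene	Terpenes	93	96	1258	1257	RI/MS/S	96	100
trans beta-ocymene	Terpenes	93	89	1264	1250	RI/MS/S	30	30
p-cymene	Terpenes	119	97	1284	1282	RI/MS	100	100
m-cymene	Terpenes	119	94	1290	1282	RI/MS	100	96
alpha-Terpinolene	Terpenes	93/121	98	1297	1297	RI/MS/S	96	91
Tetrahydro linalool	Terpenes	73	59	1439	1431	RI/MS/S	85	78
cis linalool oxide	Terpenes	59	80	1451	1451	RI/MS/S	85	87
Dihydro myrcenol	Terpenes	59	80	1480	1473	RI/MS	89	83
trans-linalool oxide	Terpenes	59	91	1479	1483	RI/MS/S	78	61
Neroloxide	Terpenes	68	70	1484	1481	RI/MS	4	4
cis-theaspirane	Terpenes	138	93	1516	1507	RI/MS	100	96
Camphor	Terpenes	95	91	1529	1529	RI/MS/S	11	22
Vitispirane	Terpenes	192	95	1545	1543	RI/MS	100	100
Linalool l	Terpenes	71	97	1557	1558	RI/MS/S	85	83
1-Terpineol	Terpenes	81	96	1582	1581	RI/MS	52	65
4-Terpineol	Terpenes	71	95	1610	1616	RI/MS/S	93	87
gamma-Valerolactone	Terpenes	56	60	1616	1617	RI/MS	15	22
Hotrienol	Terpenes	71	78	1616	1616	RI/MS	—	9
beta-Cyclocitral	Terpenes	152	94	1629	1623	RI/MS	44	52
beta-Terpineol	Terpenes	71	97	1629	1629	RI/MS	15	17
Menthol	Terpenes	71/81/95	93	1654	1652	RI/MS	85	83
Safranal	Terpenes	107	95	1661	1648	RI/MS	7	26
beta-Ocimenol (Z)	Terpenes	93	86	1661	1627	RI/MS	7	22
trans-pinocarveol	Terpenes	92	90	1667	1661	RI/MS	89	91
alpha-Phellandren-8-ol	Terpenes	94	72	1680	1680	RI/MS	85	83
Borneol	Terpenes	95	80	1690	1688	RI/MS/S	11	26
Ocimenol	Terpenes	93	90	1712	1710	RI/MS	44	48
alpha-Terpineol	Terpenes	59	91	1667	1677	RI/MS/S	89	78
gamma-Caprolactone	Terpenes	85	87	1719	1720	RI/MS	7	4
beta-Phellandren-8-ol	Terpenes	94	80	1744	1778	RI/MS	74	65
Carvone	Terpenes	82	97	1757	1751	RI/MS/S	52	39
Naphtalene 1,2-dihydro-1,1,6-trimethyl	Terpenes	157	97	1763	1751	RI/MS	89	87
alpha-Bisabolene	Terpenes	93	72	1783	1778	RI/MS	—	9
Myrtenol	Terpenes	79	96	1795	1796	RI/MS	74	78
delta-Caprolactone	Terpenes	42	87	—	—	MS/S	78	56
Cadinene	Terpenes	161	89	—	—	MS	15	9
beta-Damascenone	Terpenes	69	98	—	—	MS/S	100	100
Carveol	Terpenes	109	70	—	—	MS/S	30	22
p-Cymen-8-ol	Terpenes	135	90	—	—	MS	81	87
Calacorene	Terpenes	157	93	—	—	MS	89	74
Nerolidol	Terpenes	69	91	—	—	MS/S	74	78
Furan	Furans	68	87	—	—	MS/S	100	100
2-Methyl furan	Furans	82	70	—	—	MS/S	100	96
2,5-Dimethyl furan	Furans	96	97	—	—	MS/S	100	100
2,3,5-Trimethyl furan	Furans	110	64	1063	1063	RI/MS	96	87
2-Pentyl furan	Furans	81	90	1248	1243	RI/MS	93	91
Methanethiol	Thiols	47	91	—	—	MS	100	100
Thiophene 2-methylthio	Thiols	130	81	1541	1543	RI/MS	37	26
Methyl ethyl sulfide	Others	61	90	—	—	MS	4	4
Dimethyl disulfide	Others	94	97	1079	1071	RI/MS	100	100
Dimethyl trisulfide	Others	126	97	1388	1384	RI/MS	100	91
Benzene 1,2,3-trimethyl	Others	105	93	1346	1332	RI/MS	74	74
Heptanenitrile	Others	82	87	1402	1396	RI/MS	11	—
4-Acetyl-1-methylcyclohexene	Others	95	90	1565	1568	RI/MS	15	26
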