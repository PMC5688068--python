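metabolite	chemical_class	mz	match_percent	ri_cal	ri_lit	id_method	occurrence_nw	occurrence_ow
Acetone	Ketones	43	80	—	—	MS/S	100	100
2-Butanone	Ketones	43	64	—	—	MS/S	93	83
2-Pentanone	Ketones	43	72	—	—	MS/S	96	100
4-Methyl-2-pentanone	Ketones	43	72	1005	1008	RI/MS	22	30
3-Hexanone	Ketones	43	82	1057	1057	RI/MS	70	74
5-Methyl-3-hexanone	Ketones	57	64	1082	1068	RI/MS	66	78
2-Hexanone	Ketones	43	74	1088	1088	RI/MS	30	43
4-Heptanone	Ketones	43	90	1137	1131	RI/MS	89	96
3-Penten-2-one	Ketones	69	72	1140	1138	RI/MS	22	17
3-Penten-2-one-4-methyl	Ketones	83	64	1143	1139	RI/MS	44	43
2-Methyl-4-heptanone	Ketones	57	76	1161	—	MS	18	22
3-Heptanone	Ketones	57	60	1165	1162	RI/MS	18	30
2-Heptanone	Ketones	43	91	1196	1198	RI/MS	100	100
4-Methyl-2-heptanone	Ketones	43	80	1222	1224	RI/MS	55	61
4-Octanone	Ketones	57	87	1238	1236	RI/MS	4	26
3-Octanone	Ketones	57	90	1270	1272	RI/MS	52	56
3-Hepten-2-one	Ketones	55	90	1316	1274	RI/MS	37	48
3-Methylcyclohexanone	Ketones	69	64	1336	1333	RI/MS	26	30
3-Ethylcyclopentanone	Ketones	83	64	1342	—	MS	37	43
6-Methyl-5-hepten-2-one	Ketones	43	78	1349	1347	RI/MS	96	96
2-Cyclopenten-1-one 2-methyl	Ketones	96	72	1378	1373	RI/MS	4	13
3-Octen-2-one	Ketones	55	81	1414	1414	RI/MS	48	61
Pinocarvone	Ketones	81	87	1577	1575	RI/MS	96	96
Seudenone	Ketones	82	83	1597	1592	RI/MS	100	96
Pulegone	Ketones	81	91	1660	1662	RI/MS	65	61
Acetophenone	Ketones	105	87	1666	1669	RI/MS	48	56
Piperitone	Ketones	82	94	1749	1748	RI/MS	96	74
Methylacetophenone	Ketones	119	64	1788	1793	RI/MS	15	26
Ethanol	Alcohols	45	80	—	—	MS/S	100	100
Isobutyl alcohol	Alcohols	43	64	1106	1107	RI/MS	15	9
1-Butanol	Alcohols	56	86	1159	1158	RI/MS	93	100
2-Methyl-4-pentanol	Alcohols	45	64	1180	1181	RI/MS	22	43
2-Hexanol	Alcohols	45	72	1180	1179	RI/MS	22	35
3-Buten-1-ol-3-methyl	Alcohols	56	80	1264	1264	RI/MS	44	52
1-Pentanol	Alcohols	42	78	1267	1270	RI/MS	93	91
1-Hexanol	Alcohols	56	72	1362	1358	RI/MS	100	100
Cyclohexanol	Alcohols	57	62	1406	1407	RI/MS	30	26
2,4,4-Trimethyl-1-pentanol	Alcohols	57	83	1402	1326	RI/MS	100	96
1-Octen-3-ol	Alcohols	57	50	1450	1450	RI/MS	11	22
1-Heptanol	Alcohols	70	86	1463	1463	RI/MS	89	87
1-Hexanol-2-ethyl	Alcohols	57	80	1503	1503	RI/MS	100	100
1-Octanol	Alcohols	56	91	1565	1566	RI/MS/S	100	100
D-Fenchyl alcohol	Alcohols	81	90	1589	1588	RI/MS	55	56
Benzyl alcohol	Alcohols	79	95	—	—	MS/S	100	100
Trimethylamine	Nitrogen compounds	58	90	—	—	MS/S	96	96
Dimethylamine	Nitrogen compounds	44	86	—	—	MS/S	100	100
Isoxazole	Nitrogen compounds	69	43	—	—	MS	59	65
Piperidine	Nitrogen compounds	84	91	1116	1115	RI/MS	93	96
Pyridine	Nitrogen compounds	79	76	1192	1193	RI/MS	48	35
2,6-Dimethyl pyridine	Nitrogen compounds	107	91	1261	1266	RI/MS	37	35
2-Methyl pyrazine	Nitrogen compounds	94	90	1277	1274	RI/MS	100	100
2,5-Dimethyl pyrazine	Nitrogen compounds	108	87	1333	1332	RI/MS	59	48
Formammide N,N-dimethyl	Nitrogen compounds	73	64	1338	1328	RI/MS	4	17
2,6-Dimethyl pyrazine	Nitrogen compounds	108	87	1339	1338	RI/MS	63	61
Ethyl pyrazine	Nitrogen compounds	107	87	1346	1344	RI/MS	44	52
2,3-Dimethyl pyrazine	Nitrogen compounds	108	76	1355	1355	RI/MS	78	61
2,4,6-Trimethyl pyridine	Nitrogen compounds	121	91	1375	1378	RI/MS	30	43
Trimethyl pyrazine	Nitrogen compounds	122	74	1410	1410	RI/MS	44	22
Pyrazine 2-ethyl-6-methyl	Nitrogen compounds	121	87	1391	1390	RI/MS	89	91
Ethenyl pyrazine	Nitrogen compounds	106	90	1442	1438	RI/MS	0	9
1H Pyrrole	Nitrogen compounds	67	87	1524	1524	RI/MS	100	96
1H Pyrrole 2-methyl	Nitrogen compounds	80	86	1585	1580	RI/MS	78	56
Pyrrole 4-ethyl-2-methyl	Nitrogen compounds	94	78	1730	—	MS	85	87
Formammide N,N-dibutyl	Nitrogen compounds	72	94	1785	1773	RI/MS	81	83
1-Methyl-2-piperidone	Nitrogen compounds	113	60	—	—	MS	93	96
1-Piperidinecarboxyaldehyde	Nitrogen compounds	113	93	1781	1786	RI/MS	22	26
4-Terpineol	Terpenes	71	97	1608	1616	RI/MS/S	93	91
Menthol	Terpenes	71	64	1653	1652	RI/MS	85	74
trans Pinocarveol	Terpenes	92	64	1672	1661	RI/MS	93	91
alpha-Terpineol	Terpenes	59	91	1717	1710	RI/MS/S	93	87
Borneol	Terpenes	95	60	1724	1723	RI/MS/S	74	91
Carvol	Terpenes	82	95	1756	1751	RI/MS/S	81	65
Myrtenol	Terpenes	79	96	1795	1796	RI/MS	100	91
2,5-Dimethyl furan	Furans	96	90	—	—	MS/S	11	4
3-Acetoamidofuran	Furans	83	72	1369	—	MS	55	56
2-Acetylfuran	Furans	95	76	1516	1512	RI/MS	74	74
2-Butenoic acid ethyl ester	Esters	69	80	1165	—	RI/MS	11	22
2-Hexenoic acid ethyl ester	Esters	97	97	1352	1357	RI/MS	0	9
Octanoic acid-2-methyl ethyl ester	Esters	102	72	1385	—	MS/S	0	4
Dimethyl disulfide	Sulfur compounds	94	96	1076	1071	RI/MS	96	96
Disulfide methyl-2-propenyl	Sulfur compounds	120	72	1297	1296	RI/MS	44	52
Trisulfide dimethyl	Sulfur compounds	126	91	1388	1389	RI/MS	66	74
Dimethyl sulfone	Sulfur compounds	79	62	—	—	MS	70	78
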