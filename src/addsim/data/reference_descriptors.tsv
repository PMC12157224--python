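cid	hba_ref	hbd_ref	logp_ref	mr_ref	tpsa_ref
4632	15	1	2.6318	64.8315	46.53
8569	16	2	2.3374	66.8545	66.76
8571	15	4	1.7400	64.4085	57.99
8572	13	2	2.3288	60.3625	57.53
11178	75	2	12.6625	180.8236	74.60
12738	87	0	14.1092	214.1690	77.90
15797	29	1	5.3625	98.4805	46.53
16386	65	1	10.7245	169.3960	46.53
17113	14	1	2.4345	65.8540	50.94
24667	36	2	5.3966	108.4540	58.92
31250	63	0	9.4280	156.4850	77.90
31404	25	1	4.2956	71.9710	20.23
62485	28	1	4.8399	99.1260	50.94
62531	21	1	4.3854	90.1340	50.94
64819	120	4	15.8792	348.9130	186.12
70355	18	1	2.5645	59.7573	37.30
77470	27	1	5.3745	104.4380	50.94
90571	19	0	3.0151	72.7905	35.53
91601	67	0	13.2353	203.7500	41.28
93481	28	1	3.5292	100.8300	77.24
112412	32	1	6.7779	138.7880	50.94
172473	36	4	0.8663	86.9732	118.30
3601357	62	0	10.4850	180.9930	82.56
4992761	32	1	6.5373	128.6850	68.13
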