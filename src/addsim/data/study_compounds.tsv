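cid	name	smiles	provenance
4632	2-hydroxy-4-methoxybenzophenone	COc1ccc(C(=O)c2ccccc2)c(O)c1	from_printed_name
8569	2,2'-dihydroxy-4-methoxybenzophenone	COc1ccc(C(=O)c2ccccc2O)c(O)c1	from_printed_name
8571	bis(2,4-dihydroxyphenyl)methanone	Oc1ccc(C(=O)c2ccc(O)cc2O)c(O)c1	from_printed_name
8572	2,4-dihydroxybenzophenone	Oc1ccc(C(=O)c2ccccc2)c(O)c1	from_printed_name
11178	zinc stearate	CCCCCCCCCCCCCCCCCC(=O)[O-].CCCCCCCCCCCCCCCCCC(=O)[O-].[Zn+2]	from_printed_name
12738	octadecyl 3-(3-octadecoxy-3-oxopropyl)sulfanylpropanoate	CCCCCCCCCCCCCCCCCCOC(=O)CCSCCC(=O)OCCCCCCCCCCCCCCCCCC	from_printed_name
15797	2-hydroxy-4-n-octoxybenzophenone	CCCCCCCCOc1ccc(C(=O)c2ccccc2)c(O)c1	from_printed_name
16386	octadecyl 3-(3,5-di-tert-butyl-4-hydroxyphenyl)propanoate	CCCCCCCCCCCCCCCCCCOC(=O)CCc1cc(C(C)(C)C)c(O)c(C(C)(C)C)c1	from_printed_name
17113	2-(2H-benzotriazol-2-yl)-4-methylphenol	Cc1ccc(O)c(-n2nc3ccccc3n2)c1	from_printed_name
24667	butylated hydroxyanisole (two-component record)	COc1ccc(O)c(C(C)(C)C)c1.COc1ccc(O)c(C(C)(C)C)c1	requires_lookup
31250	dodecyl 3-(3-dodecoxy-3-oxopropyl)sulfanylpropanoate	CCCCCCCCCCCCOC(=O)CCSCCC(=O)OCCCCCCCCCCCC	from_printed_name
31404	2,6-di-tert-butyl-4-methylphenol	Cc1cc(C(C)(C)C)c(O)c(C(C)(C)C)c1	from_printed_name
62485	2-(benzotriazol-2-yl)-4-(2,4,4-trimethylpentan-2-yl)phenol	CC(C)(C)CC(C)(C)c1ccc(O)c(-n2nc3ccccc3n2)c1	from_printed_name
62531	2-tert-butyl-6-(5-chlorobenzotriazol-2-yl)-4-methylphenol	Cc1cc(C(C)(C)C)c(O)c(-n2nc3ccc(Cl)cc3n2)c1	from_printed_name
64819	pentaerythritol tetrakis(3-(3,5-di-tert-butyl-4-hydroxyphenyl)propionate)	C(COC(=O)CCc1cc(C(C)(C)C)c(O)c(C(C)(C)C)c1)(COC(=O)CCc1cc(C(C)(C)C)c(O)c(C(C)(C)C)c1)(COC(=O)CCc1cc(C(C)(C)C)c(O)c(C(C)(C)C)c1)COC(=O)CCc1cc(C(C)(C)C)c(O)c(C(C)(C)C)c1	from_printed_name
70355	1-hydroxycyclohexyl phenyl ketone	OC1(C(=O)c2ccccc2)CCCCC1	from_printed_name
77470	2,4-di-tert-butyl-6-(5-chlorobenzotriazol-2-yl)phenol	CC(C)(C)c1cc(C(C)(C)C)c(O)c(-n2nc3ccc(Cl)cc3n2)c1	from_printed_name
90571	2,2-dimethoxy-2-phenylacetophenone	COC(OC)(c1ccccc1)C(=O)c1ccccc1	from_printed_name
91601	tris(2,4-di-tert-butylphenyl) phosphite	CC(C)(C)c1ccc(OP(Oc2ccc(C(C)(C)C)cc2C(C)(C)C)Oc2ccc(C(C)(C)C)cc2C(C)(C)C)c(C(C)(C)C)c1	from_printed_name
93481	methyl 3-[3-(benzotriazol-2-yl)-5-tert-butyl-4-hydroxyphenyl]propanoate	COC(=O)CCc1cc(C(C)(C)C)c(O)c(-n2nc3ccccc3n2)c1	from_printed_name
112412	2-(benzotriazol-2-yl)-4,6-bis(2-phenylpropan-2-yl)phenol	Oc1c(-n2nc3ccccc3n2)cc(C(C)(C)c2ccccc2)cc1C(C)(C)c2ccccc2	from_printed_name
172473	butanedioic acid;1-(2-hydroxyethyl)-2,2,6,6-tetramethylpiperidin-4-ol	OC(=O)CCC(=O)O.OCCN1C(C)(C)CC(O)CC1(C)C	from_printed_name
3601357	3,9-bis(2,6-di-tert-butyl-4-methylphenoxy)-2,4,8,10-tetraoxa-3,9-diphosphaspiro[5.5]undecane	Cc1cc(C(C)(C)C)c(OP2OCC3(CO2)COP(Oc2c(C(C)(C)C)cc(C)cc2C(C)(C)C)OC3)c(C(C)(C)C)c1	from_printed_name
4992761	2-(4,6-diphenyl-1,3,5-triazin-2-yl)-5-hexyloxyphenol	CCCCCCOc1ccc(-c2nc(-c3ccccc3)nc(-c3ccccc3)n2)c(O)c1	requires_lookup
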