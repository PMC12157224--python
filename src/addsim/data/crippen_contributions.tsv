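type	logp	mr	description
C.sp3.cc	0.1441	2.503	primary/secondary aliphatic C bonded only to C/H
C.sp3.cc.branched	0.0000	2.433	tertiary/quaternary aliphatic C bonded only to C/H
C.sp3.het	-0.2035	2.753	primary/secondary aliphatic C with a heteroatom neighbor
C.sp3.het.branched	-0.2051	2.731	tertiary/quaternary aliphatic C with a heteroatom neighbor
C.carbonyl	-0.2783	5.007	sp2 C double-bonded to a heteroatom (C=O, C=N, C=S)
C.sp2	0.1551	3.513	olefinic C
C.sp	0.0017	3.888	acetylenic/allenic C
C.ar.h	0.1581	3.350	aromatic CH
C.ar.fused	0.2955	4.715	aromatic C shared by fused rings or biaryl link
C.ar.c	0.1360	3.509	aromatic C with aliphatic C substituent
C.ar.n	0.4619	4.898	aromatic C with N substituent
C.ar.o	0.5437	4.779	aromatic C with O substituent
C.ar.s	0.2148	3.650	aromatic C with S substituent
C.ar.x	0.1129	2.828	aromatic C with halogen substituent
H.c	0.1230	1.057	H on carbon
H.o	-0.2677	1.395	H on oxygen
H.n	0.2142	0.9627	H on nitrogen
H.s	0.1125	1.112	H on sulfur
N.ar	-0.3239	2.202	aromatic N
N.prim	-1.0190	2.262	primary aliphatic amine N
N.sec	-0.7096	2.173	secondary aliphatic amine N
N.tert	-0.3187	2.629	tertiary aliphatic amine N
N.sp2	-0.3396	2.819	N with a double bond (imine, azo, nitro)
N.nitrile	-0.3260	3.108	nitrile N
N.other	-0.4458	2.134	other N environments
O.ar	0.1552	1.080	aromatic O
O.carbonyl	-0.1526	1.755	carbonyl O (=O)
O.hydroxyl	-0.2893	0.8238	hydroxyl O (alcohol, phenol, acid OH)
O.ether	-0.0684	1.085	ether/ester single-bonded O
O.anion	-1.1890	1.491	charged O (carboxylate, oxide)
O.other	-0.1000	1.100	other O environments
S.any	0.6482	7.110	sulfur
P.any	0.8612	6.920	phosphorus
F	0.4202	0.8970	fluorine
Cl	0.6895	5.853	chlorine
Br	0.8456	8.927	bromine
I	0.8857	14.020	iodine
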