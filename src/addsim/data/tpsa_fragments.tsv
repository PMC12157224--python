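element	aromatic	charge	n_h	n_single	n_double	n_triple	n_aromatic	in_3ring	psa
N	0	0	0	3	0	0	0	0	3.24
N	0	0	0	3	0	0	0	1	3.01
N	0	0	0	1	1	0	0	0	12.36
N	0	0	0	0	0	1	0	0	23.79
N	0	0	0	1	2	0	0	0	11.68
N	0	0	0	0	1	1	0	0	13.60
N	0	0	1	2	0	0	0	0	12.03
N	0	0	1	2	0	0	0	1	21.94
N	0	0	1	0	1	0	0	0	23.85
N	0	0	2	1	0	0	0	0	26.02
N	0	1	0	4	0	0	0	0	0.00
N	0	1	0	2	1	0	0	0	3.01
N	0	1	0	0	0	1	0	0	4.36
N	0	1	1	3	0	0	0	0	4.44
N	0	1	1	1	1	0	0	0	13.97
N	0	1	2	2	0	0	0	0	16.61
N	0	1	2	0	1	0	0	0	25.59
N	0	1	3	1	0	0	0	0	27.64
N	1	0	0	0	0	0	2	0	12.89
N	1	0	0	0	0	0	3	0	4.41
N	1	0	0	1	0	0	2	0	4.93
N	1	0	0	0	1	0	2	0	8.39
N	1	0	1	0	0	0	2	0	15.79
N	1	1	0	0	0	0	3	0	4.10
N	1	1	0	1	0	0	2	0	3.88
N	1	1	1	0	0	0	2	0	14.14
O	0	0	0	2	0	0	0	0	9.23
O	0	0	0	2	0	0	0	1	12.53
O	0	0	0	0	1	0	0	0	17.07
O	0	0	1	1	0	0	0	0	20.23
O	0	-1	0	1	0	0	0	0	23.06
O	1	0	0	0	0	0	2	0	13.14
S	0	0	0	2	0	0	0	0	25.30
S	0	0	0	0	1	0	0	0	32.09
S	0	0	0	2	1	0	0	0	19.21
S	0	0	0	2	2	0	0	0	8.38
S	0	0	1	1	0	0	0	0	38.80
S	1	0	0	0	0	0	2	0	28.24
S	1	0	0	0	1	0	2	0	21.70
P	0	0	0	3	0	0	0	0	13.59
P	0	0	0	1	1	0	0	0	34.14
P	0	0	0	3	1	0	0	0	9.81
P	0	0	1	2	1	0	0	0	23.47
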