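property	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
hydrophobicity	0.62	0.29	-0.9	-0.74	1.19	0.48	-0.4	1.38	-1.5	1.06	0.64	-0.78	0.12	-0.85	-2.53	-0.18	-0.05	1.08	0.81	0.26
hydrophilicity	-0.5	-1	3	3	-2.5	0	-0.5	-1.8	3	-1.8	-1.3	0.2	0	0.2	3	0.3	-0.4	-1.5	-3.4	-2.3
side_chain_mass	15	47	59	73	91	1	82	57	73	57	75	58	42	72	101	31	45	43	130	107
pK1	2.35	1.71	1.88	2.19	2.58	2.34	1.78	2.32	2.2	2.36	2.28	2.02	1.99	2.17	2.17	2.21	2.15	2.29	2.38	2.2
pK2	9.87	10.78	9.6	9.67	9.24	9.6	8.97	9.76	8.9	9.6	9.21	8.8	10.6	9.13	9.04	9.15	9.12	9.74	9.39	9.11
pI	6.11	5.02	2.98	3.08	5.91	6.06	7.64	6.04	9.47	6.04	5.74	5.41	6.3	5.65	10.76	5.68	5.6	6.02	5.88	5.63
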