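index_id	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
KYTJ820101	1.8	2.5	-3.5	-3.5	2.8	-0.4	-3.2	4.5	-3.9	3.8	1.9	-3.5	-1.6	-3.5	-4.5	-0.8	-0.7	4.2	-0.9	-1.3
HOPT810101	-0.5	-1	3	3	-2.5	0	-0.5	-1.8	3	-1.8	-1.3	0.2	0	0.2	3	0.3	-0.4	-1.5	-3.4	-2.3
GRAR740102	8.1	5.5	13	12.3	5.2	9	10.4	5.2	11.3	4.9	5.7	11.6	8	10.5	10.5	9.2	8.6	5.9	5.4	6.2
GRAR740103	31	55	54	83	132	3	96	111	119	111	105	56	32.5	85	124	32	61	84	170	136
ZIMJ680102	11.5	13.46	11.68	13.57	19.8	3.4	13.69	21.4	15.71	21.4	16.25	12.82	17.43	14.45	14.28	9.47	15.77	21.57	21.67	18.03
ZIMJ680103	0	1.48	49.7	49.9	0.35	0	51.6	0.13	49.5	0.13	1.43	3.38	1.58	3.53	52	1.67	1.66	0.13	2.1	1.61
ZIMJ680104	6	5.05	2.77	3.22	5.48	5.97	7.59	6.02	9.74	5.98	5.74	5.41	6.3	5.65	10.76	5.68	5.66	5.96	5.89	5.66
FASG760101	89.09	121.15	133.1	147.13	165.19	75.07	155.16	131.17	146.19	131.17	149.21	132.12	115.13	146.15	174.2	105.09	119.12	117.15	204.24	181.19
KLEP840101	0	0	-1	-1	0	0	0	0	1	0	0	0	0	0	1	0	0	0	0	0
FAUJ880103	1	2.43	2.78	3.78	5.89	0	4.66	4	4.77	4	4.43	2.95	2.72	3.95	6.13	1.6	2.6	3	8.08	6.47
CHOP780201	1.42	0.7	1.01	1.51	1.13	0.57	1	1.08	1.16	1.21	1.45	0.67	0.57	1.11	0.98	0.77	0.83	1.06	1.08	0.69
CHOP780202	0.83	1.19	0.54	0.37	1.38	0.75	0.87	1.6	0.74	1.3	1.05	0.89	0.55	1.1	0.93	0.75	1.19	1.7	1.37	1.47
CHOP780203	0.66	1.19	1.46	0.74	0.6	1.56	0.95	0.47	1.01	0.59	0.6	1.56	1.52	0.98	0.95	1.43	0.96	0.5	0.96	1.14
BHAR880101	0.357	0.346	0.511	0.497	0.314	0.544	0.323	0.462	0.466	0.365	0.295	0.463	0.509	0.493	0.529	0.507	0.444	0.386	0.305	0.42
DAYM780101	100	20	106	102	41	49	66	96	56	40	94	134	56	93	65	120	97	74	18	41
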