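index_id	A	R	N	D	C	Q	E	G	H	I	L	K	M	F	P	S	T	W	Y	V
KYTJ820101	1.8	-4.5	-3.5	-3.5	2.5	-3.5	-3.5	-0.4	-3.2	4.5	3.8	-3.9	1.9	2.8	-1.6	-0.8	-0.7	-0.9	-1.3	4.2
HOPT810101	-0.5	3.0	0.2	3.0	-1.0	0.2	3.0	0.0	-0.5	-1.8	-1.8	3.0	-1.3	-2.5	0.0	0.3	-0.4	-3.4	-2.3	-1.5
GRAR740102	8.1	10.5	11.6	13.0	5.5	10.5	12.3	9.0	10.4	5.2	4.9	11.3	5.7	5.2	8.0	9.2	8.6	5.4	6.2	5.9
GRAR740103	31.0	124.0	56.0	54.0	55.0	85.0	83.0	3.0	96.0	111.0	111.0	119.0	105.0	132.0	32.5	32.0	61.0	170.0	136.0	84.0
GRAR740101	0.0	0.65	1.33	1.38	2.75	0.89	0.92	0.74	0.58	0.0	0.0	0.33	0.0	0.0	0.39	1.42	0.71	0.13	0.20	0.0
ZIMJ680102	11.50	14.28	12.82	11.68	13.46	14.45	13.57	3.40	13.69	21.40	21.40	15.71	16.25	19.80	17.43	9.47	15.77	21.67	18.03	21.57
ZIMJ680104	6.00	10.76	5.41	2.77	5.05	5.65	3.22	5.97	7.59	6.02	5.98	9.74	5.74	5.48	6.30	5.68	5.66	5.89	5.66	5.96
KLEP840101	0.0	1.0	0.0	-1.0	0.0	0.0	-1.0	0.0	0.0	0.0	0.0	1.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0
CHOP780201	1.42	0.98	0.67	1.01	0.70	1.11	1.51	0.57	1.00	1.08	1.21	1.16	1.45	1.13	0.57	0.77	0.83	1.08	0.69	1.06
CHOP780202	0.83	0.93	0.89	0.54	1.19	1.10	0.37	0.75	0.87	1.60	1.30	0.74	1.05	1.38	0.55	0.75	1.19	1.37	1.47	1.70
CHOP780203	0.66	0.95	1.56	1.46	1.19	0.98	0.74	1.56	0.95	0.47	0.59	1.01	0.60	0.60	1.52	1.43	0.96	0.96	1.14	0.50
EISD840101	0.62	-2.53	-0.78	-0.90	0.29	-0.85	-0.74	0.48	-0.40	1.38	1.06	-1.50	0.64	1.19	0.12	-0.18	-0.05	0.81	0.26	1.08
FAUJ830101	0.31	-1.01	-0.60	-0.77	1.54	-0.22	-0.64	0.00	0.13	1.80	1.70	-0.99	1.23	1.79	0.72	-0.04	0.26	2.25	0.96	1.22
BHAR880101	0.357	0.529	0.463	0.511	0.346	0.493	0.497	0.544	0.323	0.462	0.365	0.466	0.295	0.314	0.509	0.507	0.444	0.305	0.420	0.386
FASG760101	89.09	174.20	132.12	133.10	121.15	146.15	147.13	75.07	155.16	131.17	131.17	146.19	149.21	165.19	115.13	105.09	119.12	204.24	181.19	117.15
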