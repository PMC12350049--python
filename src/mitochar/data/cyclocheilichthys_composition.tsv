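Species	Partition	Size	A_pct	T_pct	G_pct	C_pct	AT_pct	AT_skew	GC_skew
C. repasson	mitogenome	16571	33.04	24.66	15.20	27.10	57.70	0.145	-0.281
C. janthochir	mitogenome	16580	33.66	24.64	14.86	26.85	58.30	0.155	-0.288
C. apogon	mitogenome	16586	33.37	24.87	14.89	26.87	58.24	0.146	-0.287
C. heteronema	mitogenome	16573	32.66	25.88	15.30	26.16	58.54	0.116	-0.262
C. repasson	PCG	11406	31.15	26.64	14.60	27.62	57.79	0.078	-0.308
C. janthochir	PCG	11409	31.94	26.71	14.16	27.20	58.65	0.089	-0.315
C. apogon	PCG	11408	31.74	27.05	14.07	27.14	58.79	0.080	-0.317
C. heteronema	PCG	11415	30.70	27.74	14.88	26.69	58.43	0.051	-0.284
C. repasson	rRNA	2587	35.21	19.64	20.49	24.66	54.85	0.284	-0.092
C. janthochir	rRNA	2636	35.62	19.20	20.30	24.89	54.82	0.300	-0.102
C. apogon	rRNA	2634	35.23	19.17	20.58	25.02	54.40	0.295	-0.097
C. heteronema	rRNA	2634	35.65	20.12	20.05	24.18	55.77	0.278	-0.094
C. repasson	tRNA	1567	31.14	24.44	19.40	25.02	55.58	0.121	-0.126
C. janthochir	tRNA	1563	28.92	27.38	23.10	20.60	56.30	0.027	0.057
C. apogon	tRNA	1564	28.96	27.17	23.15	20.72	56.14	0.032	0.055
C. heteronema	tRNA	1568	29.15	28.64	22.64	19.58	57.78	0.009	0.073
C. repasson	CR	918	36.17	32.57	12.09	19.17	68.74	0.052	-0.226
C. janthochir	CR	926	35.21	32.18	12.63	19.98	67.39	0.045	-0.225
C. apogon	CR	932	34.76	31.33	12.45	21.46	66.09	0.052	-0.266
C. heteronema	CR	917	34.68	33.91	13.09	18.32	68.59	0.011	-0.167
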