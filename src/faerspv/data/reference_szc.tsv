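term	a	ror	ror_lo	ror_hi	prr	chi2	ebgm	ebgm05	ic	ic025
Constipation	67	7.19	5.64	9.16	7.04	348.03	7.03	5.74	2.81	2.46
Hypokalaemia	43	20.99	15.53	28.37	20.67	804.86	20.65	16.05	4.37	3.93
Cardiac failure congestive	29	7.38	5.12	10.65	7.32	158.33	7.31	5.39	2.87	2.34
Blood pressure increased	23	3.28	2.18	4.95	3.26	36.21	3.26	2.32	1.71	1.11
Abdominal discomfort	22	2.94	1.93	4.47	2.92	27.86	2.92	2.06	1.55	0.94
Oedema peripheral	19	3.3	2.1	5.19	3.29	30.28	3.29	2.25	1.72	1.07
Dysphagia	14	3.28	1.94	5.55	3.27	22.1	3.27	2.11	1.71	0.96
Ileus	9	16.57	8.61	31.9	16.52	131.16	16.51	9.55	4.05	3.13
Fluid retention	9	3.83	1.99	7.37	3.82	18.74	3.82	2.21	1.93	1.02
Blood sodium increased	6	47.79	21.43	106.57	47.68	273.57	47.57	24.32	5.57	4.48
Choking	5	5.72	2.38	13.76	5.71	19.44	5.71	2.74	2.51	1.33
Large intestine perforation	4	12.62	4.73	33.65	12.6	42.69	12.59	5.54	3.65	2.36
Hypernatraemia	4	17.76	6.66	47.38	17.74	63.13	17.72	7.8	4.15	2.86
Scrotal oedema	3	89.47	28.76	278.3	89.37	260.95	88.97	34.42	6.48	5.03
Faeces hard	3	17.92	5.77	55.63	17.9	47.83	17.89	6.93	4.16	2.72
Faecaloma	3	12.63	4.07	39.19	12.61	32.06	12.61	4.89	3.66	2.21
Hypertransaminaemia	3	11.7	3.77	36.31	11.69	29.3	11.68	4.53	3.55	2.1
Ventricular fibrillation	3	5.77	1.86	17.9	5.76	11.81	5.76	2.23	2.53	1.08
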