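term	a	ror	ror_lo	ror_hi	prr	chi2	ebgm	ebgm05	ic	ic025
Constipation	2105	24.60	23.53	25.73	22.81	43533.55	22.56	21.73	4.50	4.43
Diarrhoea	1151	4.19	3.95	4.45	4.06	2674.56	4.05	3.86	2.02	1.93
Blood potassium	763	112.09	104.11	120.68	109.03	77387.26	103.34	97.14	6.69	6.58
Abdominal discomfort	442	5.87	5.34	6.45	5.79	1751.04	5.78	5.34	2.53	2.39
Flatulence	362	14.75	13.29	16.37	14.57	4546.02	14.47	13.26	3.86	3.70
Abdominal pain upper	322	3.58	3.20	3.99	3.55	589.50	3.54	3.23	1.82	1.66
Muscle spasms	243	2.90	2.56	3.29	2.89	299.87	2.88	2.59	1.53	1.34
Blood potassium	196	14.51	12.60	16.71	14.41	2430.02	14.32	12.72	3.84	3.63
Abdominal distension	143	3.14	2.67	3.70	3.13	207.38	3.13	2.73	1.64	1.40
Cardiac failure congestive	122	3.11	2.60	3.71	3.10	173.18	3.09	2.67	1.63	1.37
Hyperkalaemia	75	4.81	3.83	6.03	4.80	225.12	4.79	3.96	2.26	1.93
Faeces hard	71	45.02	35.57	56.98	44.91	2979.97	43.92	36.07	5.46	5.11
Blood magnesium	59	15.53	12.02	20.07	15.50	794.21	15.39	12.42	3.94	3.57
Retching	57	6.04	4.66	7.84	6.03	238.52	6.01	4.84	2.59	2.21
Blood calcium	34	8.67	6.19	12.14	8.66	229.28	8.62	6.50	3.11	2.62
Blood pressure abnormal	28	3.29	2.27	4.77	3.29	44.62	3.29	2.41	1.72	1.18
Hypercalcaemia	26	4.70	3.20	6.90	4.69	75.39	4.68	3.39	2.23	1.67
Blood phosphorus	17	14.63	9.08	23.59	14.63	214.22	14.53	9.74	3.86	3.18
Blood iron	16	3.26	1.99	5.32	3.26	24.96	3.25	2.16	1.70	1.00
Dyschezia	14	9.12	5.40	15.43	9.12	100.75	9.08	5.85	3.18	2.44
Faecal volume increased	4	17.83	6.66	47.72	17.83	62.95	17.67	7.75	4.14	2.85
Sickle cell anaemia	4	12.57	4.70	33.60	12.57	42.32	12.50	5.49	3.64	2.35
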