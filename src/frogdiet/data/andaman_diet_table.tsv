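taxon	Ht_N	Ht_V	Ht_F	Ht_IRI	Lim_N	Lim_V	Lim_F	Lim_IRI	Fej_N	Fej_V	Fej_F	Fej_IRI
Acari	0	0	0	0	0.32	0.006	0.39	0.12	0.57	0.14	0.84	0.61
Agamidae	0.43	50.44	0.57	29.07	0	0	0	0	0	0	0	0
Amphipoda	0	0	0	0	0.48	0.07	0.58	0.32	0	0	0	0
Anura	0.87	4.95	1.14	6.65	0.32	5.12	0.39	2.12	0	0	0	0
Aranae	3.20	0.73	4	15.74	7.60	2.27	8.59	84.93	7.51	7.75	10.16	155.23
Arthropoda	6.55	0	8.57	56.22	5.50	0	6.64	36.53	0.57	0	0.84	0.48
Blattaria	1.45	0.33	1.90	3.42	1.29	0.71	1.56	3.14	0	0	0	0
Chilopoda	3.35	6.15	2.85	27.15	3.23	2.75	3.9	23.41	1.15	7.62	1.69	14.88
Coleoptera	29.73	12.14	24.57	1029.14	15.85	10.34	15.42	404.29	9.24	20.50	12.71	378.16
Brachyura	0.58	2.40	0.76	2.27	0.16	0.81	0.19	0.19	0	0	0	0
Dermaptera	0.14	0.009	0.19	0.02	1.61	0.20	1.95	3.55	0	0	0	0
Diplopoda	0.87	0.07	0.76	0.72	3.55	0.73	3.12	13.41	0	0	0	0
Diptera	1.89	0.56	1.52	3.74	4.04	0.09	3.9	16.15	14.45	3.38	14.40	256.95
Formicidae	3.93	0.37	3.80	16.42	10.19	0.24	8.00	83.58	38.72	5.80	23.72	1056.60
Gastropoda	4.22	0.71	4	19.76	3.23	1.5	3.32	15.72	0	0	0	0
Geckonnidae	0.14	0.45	0.19	0.11	0	0	0	0	0	0	0	0
Hemiptera	0.58	0.19	0.76	0.59	2.10	0.35	2.34	5.77	5.20	10.96	5.08	82.18
Hymenoptera	0.14	0.004	0.19	0.02	0	0	0	0	1.15	0.86	0.84	1.70
Insecta	1.45	0	1.90	2.77	1.29	0	1.36	1.76	6.35	0	9.32	59.27
Isoptera	2.62	0.24	2.09	6.01	7.44	1.88	4.49	41.89	2.31	0.87	3.38	10.81
Lacertidae	0.29	0.90	0.38	0.45	0	0	0	0	0	0	0	0
Lepidoptera	1.31	0.24	1.33	2.07	0.48	0.14	0.39	0.24	0	0	0	0
Leplarva	6.26	3.01	7.42	68.95	6.63	5.95	6.64	83.59	3.46	15.08	4.23	78.61
Mantodea	0.29	0.72	0.38	0.38	0	0	0	0	0	0	0	0
Odonata	0.72	0.07	0.95	0.76	0.16	0.04	0.19	0.04	0	0	0	0
Oligochaeta	1.31	0.77	1.52	3.18	4.69	54.54	4.10	242.95	0	0	0	0
Opilionida	0	0	0	0	0	0	0	0	0	0	0	0
Orthoptera	24.48	12.62	24.19	897.74	13.26	9.45	14.84	337.34	3.46	20.01	5.08	119.39
Rodentia	0.14	0	0.19	0.02	0	0	0	0	0	0	0	0
Scincidae	0.14	0.62	0.19	0.14	0	0	0	0	0	0	0	0
Serpentes	0.58	0.67	0.76	0.95	0.16	0.04	0.19	0.04	0	0	0	0
Siphonaptera	0	0	0	0	0	0	0	0	0.57	0.075	0.84	0.55
Gastropoda_2	0.29	0.27	0.38	0.21	0.80	1.97	0.78	2.17	0	0	0	0
Unidentified	1.89	0.26	2.47	5.35	5.33	0.69	6.44	38.87	5.20	6.92	6.77	82.19
Zygentoma	0	0	0	0	0.16	0.01	0.19	0.03	0	0	0	0
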