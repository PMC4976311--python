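haplogroup	tibetans	dengs	lhobas	sherpas	monpas	highlanders	n_all	t_rho_kya	sd_rho_kya	t_ml_kya	sd_ml_kya
G3b1	3	2	0	0	1	6	9	8.49	1.79	10.46	2.68
M13a2	4	0	1	2	0	7	13	14.66	4.47	10.68	3.10
M33b1a1	0	8	0	0	0	8	8	1.29	0.64	1.54	1.13
M62	3	1	0	0	0	4	22	26.41	4.46	24.24	5.09
C4a3b	1	1	2	14	0	18	21	9.31	2.55	9.05	2.37
Z3b	0	8	0	0	0	8	10	5.22	2.37	7.54	10.68
D4h1c1a1	0	8	0	0	0	8	8	7.22	3.11	5.94	6.68
D4j1a1	4	1	3	1	0	9	40	6.95	1.50	5.94	1.75
D4j1b	3	0	1	0	1	5	9	11.22	2.57	11.33	3.41
D5a2c	3	2	11	0	2	18	27	7.51	0.98	10.46	1.75
M9a1a1c1b	33	1	4	11	3	52	88	10.95	3.60	9.48	4.35
M9a1a2	4	3	5	3	0	15	23	7.89	2.65	8.51	9.70
M9a1b1c	3	1	5	0	3	12	16	7.39	2.13	6.79	1.85
M9a1b1d	3	31	0	0	1	35	44	7.40	2.77	7.54	1.85
A11a	9	0	4	2	0	15	24	8.45	2.23	7.54	2.78
A15c1a	0	0	0	14	0	14	14	1.66	0.88	1.33	1.13
A6	1	1	4	3	0	9	14	12.55	2.20	14.54	2.58
F1c1a2a1	0	0	7	0	0	7	7	5.22	3.18	5.35	4.00
F1d1a	1	0	7	0	0	8	11	4.51	1.14	4.04	1.44
F1d5	1	1	3	0	0	5	5	6.82	3.15	8.50	5.20
F1g	7	0	3	0	0	10	20	9.22	1.12	9.37	1.33
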