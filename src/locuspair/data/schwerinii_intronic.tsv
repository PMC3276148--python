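segment	n	L	S	singletons	theta_e3	pi_e3	Nh	He	He_sd	D
I-1A	48	711	13	3	4.12	6.68	15	0.794	0.043	1.87
I-1B	42	413	4	1	2.25	2.81	5	0.602	0.041	0.71
I-53B	42	332	7	1	4.90	5.57	11	0.886	0.020	0.37
II-33A	48	421	13	3	6.96	9.47	10	0.762	0.036	1.09
II-33B	42	156	6	0	12.69	8.94	8	0.672	0.062	1.11
II-36A	42	162	10	1	14.35	23.54	13	0.895	0.022	1.12
II-36B	26	363	24	1	17.33	23.74	6	0.774	0.048	1.35
III-4B	28	764	12	6	4.04	2.91	12	0.860	0.045	-0.92
III-24A	44	305	14	2	10.55	12.69	15	0.848	0.037	0.63
III-24B	36	167	5	0	7.22	12.93	5	0.629	0.053	2.06
IV-11A	46	615	9	1	3.33	4.30	10	0.752	0.041	0.83
IV-18A	36	383	19	0	11.96	17.72	10	0.851	0.041	1.61
V-18A	48	304	5	1	3.71	3.61	7	0.746	0.035	-0.06
V-18B	48	436	6	0	3.10	3.94	8	0.754	0.035	0.67
V-20A	44	604	24	7	9.13	7.50	19	0.885	0.032	-0.60
V-20B	48	146	4	0	6.17	10.48	4	0.579	0.050	1.60
VI-4A	42	224	6	0	6.22	10.16	5	0.630	0.049	1.67
VI-4B	44	409	19	7	10.68	10.95	10	0.716	0.057	0.08
VII-1A	44	382	12	4	7.22	5.73	16	0.832	0.050	-0.63
VII-11A	42	615	25	4	9.45	11.31	23	0.952	0.016	0.66
VII-11B	40	499	13	3	6.12	3.04	10	0.708	0.058	-1.57
VIII-5A	38	401	9	1	5.34	7.36	6	0.691	0.046	1.12
VIII-5B	36	569	20	0	8.48	5.62	6	0.770	0.037	-1.23
VIII-14A	44	661	8	2	2.78	2.87	11	0.844	0.032	0.09
VIII-14B	46	336	7	1	4.74	4.00	11	0.688	0.071	-0.42
VIII-22B	48	292	1	0	0.77	1.38	2	0.403	0.060	1.07
X-27A	44	223	8	0	8.25	15.22	7	0.836	0.021	2.36
XII-8A	48	371	6	0	3.64	3.35	7	0.735	0.046	-0.20
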