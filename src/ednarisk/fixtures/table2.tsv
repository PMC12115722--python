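sample_id	ph	ec_us_cm	som_pct	tph_mg_kg	pah_sum_mg_kg	teq_bap_mg_kg
GD1	8.51	2625.53	8.96	182.15	2.34	0.07
GD2	8.03	3261.60	7.56	48.75	16.24	0.01
GD3	8.34	3932.00	7.64	37.75	8.72	0.37
GD4	8.19	4653.40	9.08	194.25	14.03	0.13
GD5	8.39	1532.60	6.74	194.10	4.95	0.28
GD6	8.76	733.38	7.10	183.15	4.39	0.22
GD7	8.26	3891.83	9.32	112.15	4.28	0.00
GD8	8.91	1760.58	4.96	21.30	56.83	0.10
GD9	8.30	1125.65	7.64	153.60	7.47	0.45
GD13	8.53	2338.15	6.37	184.90	11.56	0.08
GD14	8.16	3097.15	5.96	175.45	2.75	0.00
GD15	8.77	2903.55	6.49	67.85	7.98	0.04
GD16	7.93	1359.40	9.67	0.00	1.93	0.15
GD17	8.35	2427.18	8.62	95.60	34.50	0.19
GD18	8.36	2254.73	7.24	156.85	58.66	0.16
GD19	8.26	1749.78	8.50	207.70	3.58	0.36
GD20	7.93	1728.93	9.16	48.25	2.29	0.13
GD21	8.25	859.30	7.59	37.10	8.09	0.52
GD22	8.59	933.58	3.69	189.85	1.37	0.15
GD23	8.09	1969.58	6.23	59.05	2.42	0.00
GD26	8.82	1123.65	7.41	52.05	7.54	0.07
GD27	8.26	1703.70	11.74	19.70	9.27	0.00
GD28	8.03	4767.38	7.59	588.10	37.25	0.19
GD29	8.55	1142.48	5.73	74.00	45.49	0.11
GD31	8.24	3752.65	8.83	191.20	3.15	0.06
GD32	8.20	4281.85	10.83	137.90	21.43	0.13
GD33	8.23	2460.83	5.78	25.15	8.27	0.00
GD34	8.43	4236.90	7.27	122.60	17.86	0.15
GD36	8.70	3471.23	5.60	67.10	18.05	0.09
GD37	8.77	1090.30	5.05	29.35	67.77	0.08
GD38	8.26	1406.73	6.76	4.05	2.92	0.22
GD39	8.00	2534.75	8.28	142.75	5.00	0.13
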