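sample_id	aged_years	teq_sum_mg_kg	rq_ncs	rq_mpcs	rq_level	pi_grade	igeo_grade	nipi_grade
GD1	21	0.18	626.82	0.13	1	5	3	5
GD2	33	0.02	58.01	0.01	1	5	3	5
GD3	5	0.93	3319.46	0.71	4	5	4	5
GD4	20	0.32	1142.69	0.25	4	5	3	5
GD5	31	0.71	2532.71	0.54	4	5	3	5
GD6	7	0.54	1944.23	0.42	4	5	4	5
GD7	32	0.00	15.27	0.00	1	3	1	5
GD8	20	0.26	933.64	0.20	4	5	3	5
GD9	5	1.11	3974.25	0.85	4	5	3	5
GD13	7	0.32	706.76	0.15	3	3	1	5
GD14	7	1.30	9.82	0.00	1	5	3	5
GD15	7	0.14	367.12	0.08	1	5	3	5
GD16	7	0.33	1294.88	0.28	4	4	3	5
GD17	11	0.16	1703.45	0.37	4	5	3	5
GD18	11	0.32	1440.42	0.31	4	5	2	5
GD19	15	0.89	3180.53	0.68	4	5	2	5
GD20	15	0.36	1130.71	0.24	4	5	2	5
GD21	15	0.01	4655.08	1.00	4	2	1	5
GD22	20	0.48	1297.23	0.28	4	4	1	5
GD23	21	0.20	22.54	0.00	1	5	3	5
GD26	21	0.26	588.29	0.13	1	5	3	5
GD27	21	0.21	33.12	0.01	1	2	1	5
GD28	21	0.54	1719.15	0.37	4	5	2	5
GD29	29	0.00	941.62	0.20	4	5	2	5
GD31	30	0.10	502.79	0.11	1	5	3	5
GD32	31	0.40	1129.17	0.24	4	5	4	5
GD33	31	0.01	29.54	0.01	1	5	4	5
GD34	31	0.37	1311.43	0.28	4	5	3	5
GD36	31	0.22	799.30	0.17	3	5	3	5
GD37	36	0.48	749.48	0.16	3	2	2	5
GD38	39	0.01	1941.85	0.42	4	5	4	5
GD39	41	0.36	1169.98	0.25	4	5	3	5
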