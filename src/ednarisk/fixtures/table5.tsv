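species	ec50_before_mg_kg	ec50_after_mg_kg
Bacterium_YC-LK-LKJ36	0.06367	0.2005
Anaerobic_bacterium	0.06390	0.2329
Bacterium_YC-LK-LKJ25	0.07284	0.3298
Bacillus_alkalitelluris	0.1163	0.3532
Bacillus_selenatarsenatis	0.1194	0.4292
Halomonas_ventosae	0.1361	0.4586
Blastococcus_sp.	0.1588	0.7750
Halophibacterium_profundimaris	0.2108	1.580
Bacterium_YC-ZSS-LKJ56	0.2907	1.651
Pseudomonas_borbori	0.3904	2.798
Gemmatimonadetes_bacterium	0.5322	3.126
Rhodovulum_sp.	0.8769	3.785
Tistlia_consotensis	1.366	7.191
Halomonas_xianhensis	3.678	9.918
Lysobacter_maris	4.853	10.52
Palleronia_sp.	11.02	25.41
Photobacterium_halotolerans	17.17	39.47
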