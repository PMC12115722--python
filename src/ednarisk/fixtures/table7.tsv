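species	ec50_before_mg_kg	ec50_after_mg_kg
Bacterium_YC-LK-LKJ36	0.2005	0.1956
Anaerobic_bacterium	0.2329	0.2287
Bacterium_YC-LK-LKJ25	0.3298	0.2801
Bacillus_alkalitelluris	0.3532	0.6575
Bacillus_selenatarsenatis	0.4292	1.074
Halomonas_ventosae	0.4586	1.188
Blastococcus_sp.	0.7750	2.246
Halophibacterium_profundimaris	1.580	2.892
Bacterium_YC-ZSS-LKJ56	1.651	3.883
Pseudomonas_borbori	2.798	3.946
Gemmatimonadetes_bacterium	3.126	4.262
Rhodovulum_sp.	3.785	7.898
Tistlia_consotensis	7.191	10.16
Halomonas_xianhensis	9.918	12.95
Lysobacter_maris	10.52	24.31
Palleronia_sp.	25.41	45.36
Photobacterium_halotolerans	39.47	54.60
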