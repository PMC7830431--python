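contig	size_bp	gc_pct	line_pct	sine_pct	simple_pct	ltr_pct	total_repetitive_pct
Tig1	1120224	35.8	43.43	0.08	0.84	9.77	54.2
Tig467	400437	35.6	26.79	0.69	0.81	4.73	37.1
Tig251	381152	44.6	18.14	1.90	1.1	6.17	32.8
Tig3291	348639	36.5	41.52	0.71	0.92	4.64	50.4
Tig3262	337762	36.5	38.74	0.37	1.63	24.03	65.2
Tig419	307557	43.6	21.81	0.68	0.87	3.31	29.5
Tig223	297467	33.3	67.38	0.16	1.48	2.76	72.0
Tig352	290908	37.9	36.0	1	0.8	10.3	49.1
Tig667	169226	37.1	35.47	0.19	1.43	7.32	46.3
Tig292	139608	40.0	15.1	2.30	0.7	4.0	23.4
Tig469	136307	36.60	58.56	0.11	0.48	2.28	62.76
Tig313	132018	34.5	44.44	0.38	0.77	5.13	53.3
Tig5	124853	34.9	31.4	0	1.3	13.4	46.4
Tig538	107714	34.87	51.3	0.42	1.06	3.07	57.08
Tig3300	65384	43.2	19.77	0.49	0.94	3.98	25.4
Tig723	64517	33.85	30.60	1.07	0.55	2.97	40.02
Tig713	32281	40.1	12.39	0	0	6.27	18.9
Tig3301	29614	43.5	20.13	0	0.73	7.27	29.3
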