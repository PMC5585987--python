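gene	locus	orf_bp	location	aa	domain_start	domain_end	mw	pi	exons
SlZHD1	Solyc01g014970	690	SL2.50ch01:16338200..16339565(-)	229	20	71	25789.04	8.12	2
SlZHD2	Solyc01g102980	873	SL2.50ch01:91639500..91641389(+)	290	64	118	32600.98	7.76	2
SlZHD3	Solyc01g103810	351	SL2.50ch01:92343498..92343848(-)	116	14	68	13144.06	9.46	1
SlZHD4	Solyc01g103820	285	SL2.50ch01:92348106..92348390(-)	94	14	68	10361.66	8.27	1
SlZHD5	Solyc01g103830	633	SL2.50ch01:92352642..92353696(-)	210	10	64	24492.28	9.68	2
SlZHD6	Solyc01g103840	255	SL2.50ch01:92360326..92360580(-)	84	10	64	9529.72	6.27	1
SlZHD7	Solyc02g067310	879	SL2.50ch02:37494131..37495541(+)	292	62	118	32086.75	8.20	2
SlZHD8	Solyc02g067320	996	SL2.50ch02:37520623..37521618(-)	331	53	109	36516.54	7.75	1
SlZHD9	Solyc02g067330	309	SL2.50ch02:37527458..37527766(-)	102	29	83	11208.36	6.18	1
SlZHD10	Solyc02g085160	882	SL2.50ch02:48141575..48142456(-)	293	89	143	33312.95	8.14	1
SlZHD11	Solyc02g087970	273	SL2.50ch02:50205827..50206099(+)	90	23	75	10104.24	9.07	1
SlZHD12	Solyc03g061620	267	SL2.50ch03:31305510..31305776(-)	88	23	77	9648.53	5.76	1
SlZHD13	Solyc03g098060	540	SL2.50ch03:60406311..60406850(-)	179	7	64	19951.89	8.47	1
SlZHD14	Solyc03g116070	252	SL2.50ch03:65585458..65585709(-)	83	21	74	9037.14	8.75	1
SlZHD15	Solyc04g014260	744	SL2.50ch04:4560854..4561970(-)	247	54	107	27722.19	7.16	2
SlZHD16	Solyc04g074990	432	SL2.50ch04:60885156..60886298(+)	143	45	99	16096.89	5.97	3
SlZHD17	Solyc04g080490	873	SL2.50ch04:64650886..64652793(-)	290	57	111	31547.28	8.72	2
SlZHD18	Solyc05g007580	894	SL2.50ch05:2120151..2121044(-)	297	52	108	32814.23	7.26	1
SlZHD19	Solyc05g018740	360	SL2.50ch05:23129391..23129750(-)	119	14	68	13674.54	9.30	1
SlZHD20	Solyc05g020000	360	SL2.50ch05:25503046..25503405(-)	119	14	68	13702.57	9.44	1
SlZHD21	Solyc05g051420	504	SL2.50ch05:61721814..61724132(-)	167	1	50	19300.40	9.75	2
SlZHD22	Solyc09g089550	2418	SL2.50ch09:69252813..69257262(-)	805	554	608	90496.49	6.97	4
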