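transcript_id	P2_30C_r1	P2_30C_r2	P2_30C_r3	P2_16C_r1	P2_16C_r2	P2_16C_r3	P2_4C_r1	P2_4C_r2	P2_4C_r3
P2t00000	86	90	150	215	209	235	65	171	92
P2t00001	49	40	55	42	37	41	80	45	43
P2t00002	243	132	197	392	278	211	217	310	181
P2t00003	106	145	100	144	163	247	111	65	87
P2t00004	109	95	176	111	179	134	124	126	142
P2t00005	123	97	107	138	113	95	121	95	91
P2t00006	91	53	59	143	202	161	196	149	229
P2t00007	308	203	227	453	649	528	340	473	253
P2t00008	191	175	236	168	252	137	195	274	167
P2t00009	96	262	186	182	143	138	187	135	190
P2t00010	1793	2131	1358	1770	2070	2142	1086	566	1200
P2t00011	48	62	66	76	30	59	75	100	78
P2t00012	24	52	22	20	14	9	55	66	64
P2t00013	25	32	19	77	60	67	39	30	21
P2t00014	292	323	306	224	408	387	253	362	418
P2t00015	168	144	144	82	95	63	315	215	340
P2t00016	147	128	134	112	83	59	150	157	139
P2t00017	115	51	77	96	75	51	238	107	107
P2t00018	34	47	45	39	22	34	35	36	48
P2t00019	266	305	245	139	87	156	114	161	142
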