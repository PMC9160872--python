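transcript_id	P1_30C_r1	P1_30C_r2	P1_30C_r3	P1_16C_r1	P1_16C_r2	P1_16C_r3	P1_4C_r1	P1_4C_r2	P1_4C_r3
P1t00000	39	29	31	29	25	23	45	42	42
P1t00001	111	74	111	57	115	63	83	96	129
P1t00002	527	437	576	319	349	730	635	567	635
P1t00003	130	63	136	70	92	124	190	133	113
P1t00004	83	86	76	109	62	71	69	84	87
P1t00005	179	131	146	119	113	161	187	99	110
P1t00006	204	222	168	95	143	62	106	104	91
P1t00007	283	174	188	108	61	106	124	207	258
P1t00008	89	70	73	102	124	88	84	91	104
P1t00009	100	71	67	116	40	41	61	59	110
P1t00010	659	473	568	476	357	522	1305	1065	996
P1t00011	103	107	114	78	182	168	51	64	65
P1t00012	122	168	117	162	174	183	47	56	38
P1t00013	147	186	179	41	78	82	171	110	122
P1t00014	230	345	274	338	333	378	278	228	242
P1t00015	584	602	652	954	1040	1384	267	178	256
P1t00016	146	60	105	299	174	272	108	85	143
P1t00017	14	23	31	16	21	16	6	15	6
P1t00018	93	88	120	80	69	80	105	70	103
P1t00019	190	220	236	386	495	387	480	421	266
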