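transcript_id	F1_30C_r1	F1_30C_r2	F1_30C_r3	F1_16C_r1	F1_16C_r2	F1_16C_r3	F1_4C_r1	F1_4C_r2	F1_4C_r3
P1t00000	21	19	19	13	17	27	29	5	16
P1t00001	26	40	58	52	31	40	42	43	50
P1t00002	218	209	178	211	228	248	309	205	260
P1t00003	53	42	44	39	32	35	25	27	10
P1t00004	41	25	34	44	54	32	52	50	22
P1t00005	64	91	68	294	275	205	63	33	70
P1t00006	21	10	14	38	31	37	60	50	48
P1t00007	151	254	127	267	466	319	276	165	115
P1t00008	68	55	62	35	74	44	41	62	68
P1t00009	19	32	30	15	31	39	40	24	25
P1t00010	1071	1956	1489	1936	1318	879	845	887	1054
P1t00011	80	59	37	80	49	48	29	26	33
P1t00012	74	34	28	104	94	85	27	26	41
P1t00013	14	13	14	20	38	45	15	21	8
P1t00014	157	154	238	122	72	94	189	147	113
P1t00015	319	272	225	84	172	52	484	481	585
P1t00016	71	43	27	555	540	261	70	54	51
P1t00017	16	10	4	11	11	11	31	27	22
P1t00018	33	17	34	23	19	11	34	35	33
P1t00019	20	29	26	64	25	62	201	207	299
P2t00000	23	53	26	29	50	67	49	53	39
P2t00001	29	34	20	19	32	27	18	15	21
P2t00002	117	98	141	117	109	98	146	129	43
P2t00003	90	68	100	124	72	101	26	43	28
P2t00004	42	78	66	63	35	57	47	49	71
P2t00005	43	51	40	250	195	183	51	30	50
P2t00006	41	41	69	86	84	90	69	67	60
P2t00007	59	94	81	98	147	146	73	77	68
P2t00008	62	120	81	92	85	77	121	67	65
P2t00009	119	159	149	150	99	95	77	90	127
P2t00010	434	403	385	237	356	540	310	169	163
P2t00011	31	33	35	32	30	24	18	13	16
P2t00012	14	17	13	34	28	43	10	7	5
P2t00013	10	14	18	12	29	23	12	23	8
P2t00014	242	236	158	163	179	237	157	153	170
P2t00015	36	91	40	35	49	35	103	230	143
P2t00016	67	61	68	626	732	924	85	64	103
P2t00017	39	40	43	65	47	36	57	72	93
P2t00018	21	30	18	28	24	31	18	12	32
P2t00019	42	27	45	62	75	60	220	199	205
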