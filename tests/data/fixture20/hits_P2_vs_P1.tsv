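P2t00000	P1t00000	95.43	723	33	0	1	723	1	723	1.00e-180	289.3
P2t00000	P1t00019	80.00	723	145	0	1	723	1	723	1.00e-60	260.4
P2t00001	P1t00001	96.40	1427	51	0	1	1427	1	1427	1.00e-180	576.0
P2t00001	P1t00000	80.00	1427	285	0	1	1427	1	1427	1.00e-60	518.4
P2t00002	P1t00002	92.53	956	71	0	1	956	1	956	1.00e-180	371.7
P2t00002	P1t00001	80.00	956	191	0	1	956	1	956	1.00e-60	334.5
P2t00003	P1t00003	96.52	1597	56	0	1	1597	1	1597	1.00e-180	642.1
P2t00003	P1t00002	80.00	1597	319	0	1	1597	1	1597	1.00e-60	577.9
P2t00004	P1t00004	98.85	1582	18	0	1	1582	1	1582	1.00e-180	629.3
P2t00004	P1t00003	80.00	1582	316	0	1	1582	1	1582	1.00e-60	566.4
P2t00005	P1t00005	97.46	2110	54	0	1	2110	1	2110	1.00e-180	843.0
P2t00005	P1t00004	80.00	2110	422	0	1	2110	1	2110	1.00e-60	758.7
P2t00006	P1t00006	97.00	714	21	0	1	714	1	714	1.00e-180	287.0
P2t00006	P1t00005	80.00	714	143	0	1	714	1	714	1.00e-60	258.3
P2t00007	P1t00007	93.25	2244	152	0	1	2244	1	2244	1.00e-180	894.7
P2t00007	P1t00006	80.00	2244	449	0	1	2244	1	2244	1.00e-60	805.2
P2t00008	P1t00008	92.26	1003	78	0	1	1003	1	1003	1.00e-180	401.4
P2t00008	P1t00007	80.00	1003	201	0	1	1003	1	1003	1.00e-60	361.2
P2t00009	P1t00009	92.84	735	53	0	1	735	1	735	1.00e-180	295.1
P2t00009	P1t00008	80.00	735	147	0	1	735	1	735	1.00e-60	265.6
P2t00010	P1t00010	94.37	1626	92	0	1	1626	1	1626	1.00e-180	644.7
P2t00010	P1t00009	80.00	1626	325	0	1	1626	1	1626	1.00e-60	580.3
P2t00011	P1t00011	95.48	1068	48	0	1	1068	1	1068	1.00e-180	432.8
P2t00011	P1t00010	80.00	1068	214	0	1	1068	1	1068	1.00e-60	389.5
P2t00012	P1t00012	98.13	730	14	0	1	730	1	730	1.00e-180	289.8
P2t00012	P1t00011	80.00	730	146	0	1	730	1	730	1.00e-60	260.9
P2t00013	P1t00013	92.79	1887	136	0	1	1887	1	1887	1.00e-180	749.4
P2t00013	P1t00012	80.00	1887	377	0	1	1887	1	1887	1.00e-60	674.5
P2t00014	P1t00014	95.65	2294	100	0	1	2294	1	2294	1.00e-180	924.4
P2t00014	P1t00013	80.00	2294	459	0	1	2294	1	2294	1.00e-60	832.0
P2t00015	P1t00015	93.59	659	42	0	1	659	1	659	1.00e-180	257.6
P2t00015	P1t00014	80.00	659	132	0	1	659	1	659	1.00e-60	231.8
P2t00016	P1t00016	96.00	1783	71	0	1	1783	1	1783	1.00e-180	706.6
P2t00016	P1t00015	80.00	1783	357	0	1	1783	1	1783	1.00e-60	635.9
P2t00017	P1t00017	94.33	820	46	0	1	820	1	820	1.00e-180	326.7
P2t00017	P1t00016	80.00	820	164	0	1	820	1	820	1.00e-60	294.0
P2t00018	P1t00018	97.07	1192	35	0	1	1192	1	1192	1.00e-180	479.7
P2t00018	P1t00017	80.00	1192	238	0	1	1192	1	1192	1.00e-60	431.8
P2t00019	P1t00019	92.55	1626	121	0	1	1626	1	1626	1.00e-180	646.3
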