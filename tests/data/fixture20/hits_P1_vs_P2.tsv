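# qseqid	sseqid	pident	length	mismatch	gapopen	qstart	qend	sstart	send	evalue	bitscore
P1t00000	P2t00000	95.43	723	33	0	1	723	1	723	1.00e-180	289.3
P1t00000	P2t00001	90.50	723	69	0	1	723	1	723	1.00e-55	173.6
P1t00001	P2t00001	96.40	1427	51	0	1	1427	1	1427	1.00e-180	576.0
P1t00001	P2t00002	90.50	1427	136	0	1	1427	1	1427	1.00e-55	345.6
P1t00002	P2t00002	92.53	956	71	0	1	956	1	956	1.00e-180	371.7
P1t00002	P2t00003	90.50	956	91	0	1	956	1	956	1.00e-55	223.0
P1t00003	P2t00003	96.52	1597	56	0	1	1597	1	1597	1.00e-180	642.1
P1t00003	P2t00004	90.50	1597	152	0	1	1597	1	1597	1.00e-55	385.3
P1t00004	P2t00004	98.85	1582	18	0	1	1582	1	1582	1.00e-180	629.3
P1t00004	P2t00005	90.50	1582	150	0	1	1582	1	1582	1.00e-55	377.6
P1t00005	P2t00005	97.46	2110	54	0	1	2110	1	2110	1.00e-180	843.0
P1t00005	P2t00006	90.50	2110	200	0	1	2110	1	2110	1.00e-55	505.8
P1t00006	P2t00006	97.00	714	21	0	1	714	1	714	1.00e-180	287.0
P1t00006	P2t00007	90.50	714	68	0	1	714	1	714	1.00e-55	172.2
P1t00007	P2t00007	93.25	2244	152	0	1	2244	1	2244	1.00e-180	894.7
P1t00007	P2t00008	90.50	2244	213	0	1	2244	1	2244	1.00e-55	536.8
P1t00008	P2t00008	92.26	1003	78	0	1	1003	1	1003	1.00e-180	401.4
P1t00008	P2t00009	90.50	1003	95	0	1	1003	1	1003	1.00e-55	240.8
P1t00009	P2t00009	92.84	735	53	0	1	735	1	735	1.00e-180	295.1
P1t00009	P2t00010	90.50	735	70	0	1	735	1	735	1.00e-55	177.0
P1t00010	P2t00010	94.37	1626	92	0	1	1626	1	1626	1.00e-180	644.7
P1t00010	P2t00011	90.50	1626	154	0	1	1626	1	1626	1.00e-55	386.8
P1t00011	P2t00011	95.48	1068	48	0	1	1068	1	1068	1.00e-180	432.8
P1t00011	P2t00012	90.50	1068	101	0	1	1068	1	1068	1.00e-55	259.7
P1t00012	P2t00012	98.13	730	14	0	1	730	1	730	1.00e-180	289.8
P1t00012	P2t00013	90.50	730	69	0	1	730	1	730	1.00e-55	173.9
P1t00013	P2t00013	92.79	1887	136	0	1	1887	1	1887	1.00e-180	749.4
P1t00013	P2t00014	90.50	1887	179	0	1	1887	1	1887	1.00e-55	449.7
P1t00014	P2t00014	95.65	2294	100	0	1	2294	1	2294	1.00e-180	924.4
P1t00014	P2t00015	90.50	2294	218	0	1	2294	1	2294	1.00e-55	554.6
P1t00015	P2t00015	93.59	659	42	0	1	659	1	659	1.00e-180	257.6
P1t00015	P2t00016	90.50	659	63	0	1	659	1	659	1.00e-55	154.6
P1t00016	P2t00016	96.00	1783	71	0	1	1783	1	1783	1.00e-180	706.6
P1t00016	P2t00017	90.50	1783	169	0	1	1783	1	1783	1.00e-55	423.9
P1t00017	P2t00017	94.33	820	46	0	1	820	1	820	1.00e-180	326.7
P1t00017	P2t00018	90.50	820	78	0	1	820	1	820	1.00e-55	196.0
P1t00018	P2t00018	97.07	1192	35	0	1	1192	1	1192	1.00e-180	479.7
P1t00018	P2t00019	90.50	1192	113	0	1	1192	1	1192	1.00e-55	287.8
P1t00019	P2t00019	92.55	1626	121	0	1	1626	1	1626	1.00e-180	646.3
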