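transcript_id	length
P1t00000	723
P1t00001	2435
P1t00002	2137
P1t00003	1597
P1t00004	1582
P1t00005	2647
P1t00006	714
P1t00007	2244
P1t00008	1003
P1t00009	735
P1t00010	1816
P1t00011	2940
P1t00012	2340
P1t00013	2403
P1t00014	2294
P1t00015	2465
P1t00016	1783
P1t00017	820
P1t00018	2600
P1t00019	1626
P2t00000	1751
P2t00001	1427
P2t00002	956
P2t00003	2817
P2t00004	2454
P2t00005	2110
P2t00006	1506
P2t00007	2557
P2t00008	1864
P2t00009	1608
P2t00010	1626
P2t00011	1068
P2t00012	730
P2t00013	1887
P2t00014	2720
P2t00015	659
P2t00016	2646
P2t00017	2569
P2t00018	1192
P2t00019	2079
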