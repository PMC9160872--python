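pair_id	p1_transcript	p2_transcript	condition	bin	true_b	p1_expr	p2_expr	hybrid_expr	len_p1	len_p2
pair00000	P1t00000	P2t00000	30C	no_change	0	57.61824178	57.61824178	57.61824178	723	1751
pair00001	P1t00001	P2t00001	30C	no_change	0	35.08494195	35.08494195	35.08494195	2435	1427
pair00002	P1t00002	P2t00002	30C	no_change	0	235.3898127	235.3898127	235.3898127	2137	956
pair00003	P1t00003	P2t00003	30C	no_change	0	59.39274593	59.39274593	59.39274593	1597	2817
pair00004	P1t00004	P2t00004	30C	no_change	0	45.16731729	45.16731729	45.16731729	1582	2454
pair00005	P1t00005	P2t00005	30C	no_change	0	48.74331345	48.74331345	48.74331345	2647	2110
pair00006	P1t00006	P2t00006	30C	ELD_P2	0	236.0769815	59.01924538	59.01924538	714	1506
pair00007	P1t00007	P2t00007	30C	no_change	1.58669447	99.89759817	99.89759817	99.89759817	2244	2557
pair00008	P1t00008	P2t00008	30C	no_change	0	104.735088	104.735088	104.735088	1003	1864
pair00009	P1t00009	P2t00009	30C	no_change	-0.9247035853	106.6468151	106.6468151	106.6468151	735	1608
pair00010	P1t00010	P2t00010	30C	ELD_P2	1.715951763	295.0668671	1180.267469	1180.267469	1816	1626
pair00011	P1t00011	P2t00011	30C	no_change	-0.3826086498	46.1679836	46.1679836	46.1679836	2940	1068
pair00012	P1t00012	P2t00012	30C	no_change	0	41.53177719	41.53177719	41.53177719	2340	730
pair00013	P1t00013	P2t00013	30C	ELD_P2	0	61.44091805	15.36022951	15.36022951	2403	1887
pair00014	P1t00014	P2t00014	30C	no_change	0	128.3397445	128.3397445	128.3397445	2294	2720
pair00015	P1t00015	P2t00015	30C	no_change	0	214.3636499	214.3636499	214.3636499	2465	659
pair00016	P1t00016	P2t00016	30C	no_change	0	61.85259912	61.85259912	61.85259912	1783	2646
pair00017	P1t00017	P2t00017	30C	no_change	0	29.92053703	29.92053703	29.92053703	820	2569
pair00018	P1t00018	P2t00018	30C	no_change	-0.8545052927	30.39324449	30.39324449	30.39324449	2600	1192
pair00019	P1t00019	P2t00019	30C	transgressive_down	0.3170793822	132.8597906	132.8597906	33.21494766	1626	2079
pair00000	P1t00000	P2t00000	16C	additivity	0	28.80912089	115.2364836	72.02280222	723	1751
pair00001	P1t00001	P2t00001	16C	no_change	0	35.08494195	35.08494195	35.08494195	2435	1427
pair00002	P1t00002	P2t00002	16C	no_change	0	235.3898127	235.3898127	235.3898127	2137	956
pair00003	P1t00003	P2t00003	16C	no_change	0	59.39274593	59.39274593	59.39274593	1597	2817
pair00004	P1t00004	P2t00004	16C	no_change	0	45.16731729	45.16731729	45.16731729	1582	2454
pair00005	P1t00005	P2t00005	16C	transgressive_up	0	48.74331345	48.74331345	194.9732538	2647	2110
pair00006	P1t00006	P2t00006	16C	no_change	0	118.0384908	118.0384908	118.0384908	714	1506
pair00007	P1t00007	P2t00007	16C	ELD_P2	1.58669447	49.94879908	199.7951963	199.7951963	2244	2557
pair00008	P1t00008	P2t00008	16C	no_change	0	104.735088	104.735088	104.735088	1003	1864
pair00009	P1t00009	P2t00009	16C	no_change	-0.9247035853	106.6468151	106.6468151	106.6468151	735	1608
pair00010	P1t00010	P2t00010	16C	ELD_P2	1.715951763	295.0668671	1180.267469	1180.267469	1816	1626
pair00011	P1t00011	P2t00011	16C	no_change	-0.3826086498	46.1679836	46.1679836	46.1679836	2940	1068
pair00012	P1t00012	P2t00012	16C	ELD_P1	0	83.06355437	20.76588859	83.06355437	2340	730
pair00013	P1t00013	P2t00013	16C	no_change	0	30.72045902	30.72045902	30.72045902	2403	1887
pair00014	P1t00014	P2t00014	16C	no_change	0	128.3397445	128.3397445	128.3397445	2294	2720
pair00015	P1t00015	P2t00015	16C	ELD_P2	0	428.7272998	107.1818249	107.1818249	2465	659
pair00016	P1t00016	P2t00016	16C	transgressive_up	0	123.7051982	30.92629956	494.820793	1783	2646
pair00017	P1t00017	P2t00017	16C	no_change	0	29.92053703	29.92053703	29.92053703	820	2569
pair00018	P1t00018	P2t00018	16C	no_change	-0.8545052927	30.39324449	30.39324449	30.39324449	2600	1192
pair00019	P1t00019	P2t00019	16C	ELD_P2	0.3170793822	265.7195813	66.42989532	66.42989532	1626	2079
pair00000	P1t00000	P2t00000	4C	no_change	0	57.61824178	57.61824178	57.61824178	723	1751
pair00001	P1t00001	P2t00001	4C	no_change	0	35.08494195	35.08494195	35.08494195	2435	1427
pair00002	P1t00002	P2t00002	4C	no_change	0	235.3898127	235.3898127	235.3898127	2137	956
pair00003	P1t00003	P2t00003	4C	ELD_P2	0	118.7854919	29.69637297	29.69637297	1597	2817
pair00004	P1t00004	P2t00004	4C	no_change	0	45.16731729	45.16731729	45.16731729	1582	2454
pair00005	P1t00005	P2t00005	4C	no_change	0	48.74331345	48.74331345	48.74331345	2647	2110
pair00006	P1t00006	P2t00006	4C	no_change	0	118.0384908	118.0384908	118.0384908	714	1506
pair00007	P1t00007	P2t00007	4C	no_change	1.58669447	99.89759817	99.89759817	99.89759817	2244	2557
pair00008	P1t00008	P2t00008	4C	no_change	0	104.735088	104.735088	104.735088	1003	1864
pair00009	P1t00009	P2t00009	4C	no_change	-0.9247035853	106.6468151	106.6468151	106.6468151	735	1608
pair00010	P1t00010	P2t00010	4C	no_change	1.715951763	590.1337343	590.1337343	590.1337343	1816	1626
pair00011	P1t00011	P2t00011	4C	ELD_P1	-0.3826086498	23.0839918	92.3359672	23.0839918	2940	1068
pair00012	P1t00012	P2t00012	4C	ELD_P1	0	20.76588859	83.06355437	20.76588859	2340	730
pair00013	P1t00013	P2t00013	4C	ELD_P2	0	61.44091805	15.36022951	15.36022951	2403	1887
pair00014	P1t00014	P2t00014	4C	no_change	0	128.3397445	128.3397445	128.3397445	2294	2720
pair00015	P1t00015	P2t00015	4C	ELD_P2	0	107.1818249	428.7272998	428.7272998	2465	659
pair00016	P1t00016	P2t00016	4C	no_change	0	61.85259912	61.85259912	61.85259912	1783	2646
pair00017	P1t00017	P2t00017	4C	ELD_P2	0	14.96026851	59.84107405	59.84107405	820	2569
pair00018	P1t00018	P2t00018	4C	no_change	-0.8545052927	30.39324449	30.39324449	30.39324449	2600	1192
pair00019	P1t00019	P2t00019	4C	ELD_P1	0.3170793822	265.7195813	66.42989532	265.7195813	1626	2079
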