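haplogroup	n	pct	sd_generations	se_generations	tmrca_ybp	se_ybp
G-P15	40	12.3	373.6	132.1	9339	3302
E-V13	31	9.5	94.2	33.3	2354	832
J-M410*	31	9.5	150.7	53.3	3767	1332
R-M17	17	5.2	172.2	60.9	4305	1522
J-M267	16	4.9	130.4	53.8	3261	1345
R-P312	15	4.6	175.2	61.9	4380	1549
R-U152	14	4.3	80.1	28.3	2002	708
R-U106	12	3.7	82.6	29.2	2066	730
J-M92	11	3.4	146.3	55.3	3658	1382
J-M12	11	3.4	148.6	52.6	3716	1314
J-M67	10	3.1	130.8	46.3	3271	1157
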