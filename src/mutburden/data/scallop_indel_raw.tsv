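sample_id	genome_total	genome_insertion	genome_deletion	cds_total	cds_insertion	cds_deletion
Control_1	1511400	681992	829408	8606	3515	5091
Control_2	1580568	713062	867506	9233	3773	5460
Control_3	1556430	701814	854616	8946	3658	5288
Control_4	1545887	696134	849753	9278	3786	5492
Treated_1	1424749	636777	787972	9113	3679	5434
Treated_2	1457488	657042	800446	8424	3439	4985
Treated_3	1341891	607142	734749	7787	3100	4687
Treated_4	1500738	676211	824527	8239	3268	4971
Treated_5	1465430	660129	805301	8808	3582	5226
Treated_6	1466508	659425	807083	8789	3627	5162
Treated_7	1412924	639855	773069	7794	3170	4624
Treated_8	1468654	661746	806908	8444	3403	5041
Treated_9	1589485	716156	873329	9387	3718	5669
Treated_10	1312194	593108	719086	7694	3144	4550
Treated_11	1535662	692346	843316	8785	3588	5197
Treated_12	1574406	709673	864733	8958	3599	5359
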