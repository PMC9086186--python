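sample_id	snp_number	transition	transversion	ts_tv	exonic	intronic	mutation_rate_pct
Control_1	144157	74612	69545	1.07	5221	55337	0.001343
Control_2	133641	69136	64505	1.07	5076	47083	0.001041
Control_3	140421	72744	67677	1.07	5093	52157	0.001207
Control_4	121144	63020	58124	1.08	4217	45983	0.001023
Treated_1	919124	486397	432727	1.12	33221	343986	0.009153
Treated_2	899577	474911	424666	1.12	31786	338180	0.009498
Treated_3	1259663	665325	594338	1.12	44543	480891	0.013323
Treated_4	836603	441775	394828	1.12	28400	317373	0.008701
Treated_5	884410	467731	416679	1.12	31431	336862	0.008839
Treated_6	844165	447477	396688	1.13	31064	322816	0.008732
Treated_7	1301091	686338	614753	1.12	43564	499773	0.013240
Treated_8	1283904	676586	607318	1.11	43240	484351	0.013017
Treated_9	1479438	779953	699485	1.12	49384	557013	0.012682
Treated_10	1188795	625965	562830	1.11	40539	451110	0.012474
Treated_11	1452761	768189	684572	1.12	51409	553680	0.014352
Treated_12	1467033	772501	694532	1.11	48801	547507	0.013249
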