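sample_id	synonymous	nonsynonymous	stopgain	stoploss
Control_1	2453	2664	62	7
Control_2	2343	2604	68	6
Control_3	2461	2551	52	9
Control_4	2057	2065	49	4
Treated_1	18232	14477	287	33
Treated_2	17661	13667	278	31
Treated_3	24730	19120	363	36
Treated_4	15773	12174	235	24
Treated_5	17551	13420	289	25
Treated_6	17308	13317	248	27
Treated_7	24464	18451	365	46
Treated_8	24100	18551	344	43
Treated_9	27652	21062	367	50
Treated_10	22710	17300	310	52
Treated_11	29038	21696	366	49
Treated_12	27137	21004	375	53
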