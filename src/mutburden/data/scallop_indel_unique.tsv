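sample_id	genome_total	genome_insertion	genome_deletion	cds_total	cds_insertion	cds_deletion
Control_1	47081	21178	25903	658	263	395
Control_2	38755	17315	21440	634	236	398
Control_3	37598	18524	19074	623	225	356
Control_4	46987	17568	29419	645	261	387
Treated_1	167843	76623	101422	1867	721	1146
Treated_2	169398	76465	103672	1501	589	912
Treated_3	175975	107611	142501	1913	668	1245
Treated_4	178045	73190	96208	1260	432	828
Treated_5	180137	112309	147840	1525	589	936
Treated_6	238232	76062	99913	1518	599	919
Treated_7	250112	72360	95483	1771	662	1109
Treated_8	253471	129826	168342	1847	664	1183
Treated_9	260149	109500	143971	2288	843	1445
Treated_10	284295	123192	161103	1837	696	1141
Treated_11	295252	128607	166645	2096	782	1314
Treated_12	298168	102954	135278	2151	777	1347
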