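sample_id	group	clean_read_pairs	clean_bases	q30_read1	q30_read2	gc_read1	gc_read2
Control_1	control	72397388	10730101234	89.0	89.6	35.0	34.9
Control_2	control	86746906	12841328031	88.1	89.0	35.5	35.3
Control_3	control	78575284	11637694182	88.9	89.2	35.1	35.0
Control_4	control	80070256	11846376980	88.2	88.6	36.1	36.0
Treated_1	treated_large	67832690	10041975926	90.2	91.0	35.9	35.9
Treated_2	treated_large	64159190	9470920591	88.7	87.3	35.4	35.4
Treated_3	treated_large	63990224	9454811079	87.3	87.6	35.1	35.1
Treated_4	treated_large	65044560	9615563726	87.5	87.7	34.9	34.8
Treated_5	treated_large	67712528	10006244700	87.8	87.4	35.7	35.7
Treated_6	treated_normal	65341510	9667122876	87.9	88.3	35.7	35.7
Treated_7	treated_normal	66519728	9826753951	87.3	86.9	34.8	34.7
Treated_8	treated_normal	66587084	9863157597	88.2	89.1	34.9	34.8
Treated_9	treated_normal	78747896	11665293124	89.0	89.6	35.2	35.1
Treated_10	treated_normal	64408982	9530201612	88.8	89.2	34.8	34.7
Treated_11	treated_small	68486448	10122154287	88.2	87.5	35.7	35.7
Treated_12	treated_small	74752348	11073164954	88.7	89.1	34.9	34.7
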