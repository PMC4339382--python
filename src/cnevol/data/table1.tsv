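patient_id	age_bracket	stage	response	treatment	ca125_change	pfs_days	os_days	samples_used	samples_taken	th_index	ce_index	star_p
1	I	IV	PR	Neo	-93	271	511	16	20	4.73	1.26	<0.001
2	IV	IV	PR	Neo	-92	363	977	3	5	NA	0.71	0.67
3	V	IV	SD	Neo	-92	153	209	18	20	3.74	1.24	<0.001
4	I	IIIC	PR	Neo	-91	616	625	1	3	NA	NA	NA
5	IV	IV	PR	Neo	-76	303	547	29	29	3.8	1.47	<0.001
6	III	IV	SD	Neo	-80	298	744	8	8	6.59	0.73	0.001
7	IV	IV	PR	Neo	-43	358	1587	7	8	3	0.68	<0.001
8	II	IIIC	PR	Neo	-24	373	889	11	14	3.42	2.24	<0.001
9	VI	IV	SD	Neo	-100	563	1278	15	16	4.49	0.65	<0.001
10	III	IIIC	PR	Neo	-87	303	1139	9	11	4.72	0.87	<0.001
11	III	IIIC	PR	Neo	-98	382	1556	7	17	5.7	0.48	0.28
12	III	IIIC	SD	Neo	-88	534	1565	1	4	NA	NA	NA
13	III	IIIC	PR	Neo	-28	776	1166	3	3	NA	0.62	0.48
14	IV	IIIC	PR	Neo	NA	601	1513	3	4	4.62	0.61	0.74
15	II	IV	SD	Neo	NA	332	706	3	5	NA	0.74	0.74
16	III	IIIC	PR	Neo	NA	1380	1405	1	3	NA	NA	NA
17	III	IIIC	SD	PS	NA	293	849	3	4	NA	0.86	0.64
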