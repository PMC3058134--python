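subject_id	sample_id	sample_type	stage	load_percent	replicate_index	pool_id
S1	E01	embryo	day3	31.4717		
S1	E02	embryo	day3	0.0		
S1	E03	embryo	day3	2.3236		
S1	E04	embryo	day3	33.0147		
S1	E05	embryo	day3	59.8915		
S1	E06	embryo	day3	4.832		
S1	E07	embryo	day3	54.5798		
S1	E08	embryo	day3	0.0		
S1	E09	embryo	day3	6.8501		
S1	E10	embryo	day3	81.2366		
S1	E11	embryo	day3	14.6218		
S1	E12	embryo	day3	10.4931		
S1	E13	embryo	day3	0.0		
S1	E14	embryo	day3	61.1591		
S1	E15	embryo	day3	2.9575		
S1	E16	embryo	day3	38.848		
S1	E17	embryo	day3	62.2698		
S1	E18	embryo	day3	18.9155		
S1	E19	embryo	day3	0.0		
S1	E20	embryo	day3	42.7484		
S1	E21	embryo	day3	45.0995		
S1	E22	embryo	day3	0.0		
S1	E23	embryo	day3	14.1059		
S1	E24	embryo	day3	35.1554		
S1	E25	embryo	day3	10.1659		
S1	E26	embryo	day3	9.0181		
S1	E27	embryo	day3	86.5469		
S1	E28	embryo	day3	16.1027		
S1	E29	embryo	day3	35.4333		
S1	E30	embryo	day3	60.0659		
S1	E31	embryo	day3	12.8916		
S1	E32	embryo	day3	15.0915		
S1	E33	embryo	day3	50.9859		
S1	E34	embryo	day3	72.7049		
S1	E35	embryo	day3	14.1692		
S1	E01	blastomere	day3	30.3255	1	
S1	E01	blastomere	day3	33.8377	2	
S1	E02	blastomere	day3	0.464	1	
S1	E02	blastomere	day3	2.5355	2	
S1	E03	blastomere	day3	1.2439	1	
S1	E03	blastomere	day3	0.0	2	
S1	E04	blastomere	day3	34.9853	1	
S1	E04	blastomere	day3	32.8297	2	
S1	E05	blastomere	day3	61.3863	1	
S1	E05	blastomere	day3	58.2754	2	
S1	E06	blastomere	day3	1.1519	1	
S1	E06	blastomere	day3	0.0	2	
S1	E07	blastomere	day3	57.4819	1	
S1	E07	blastomere	day3	57.3331	2	
S1	E08	blastomere	day3	0.1446	1	
S1	E08	blastomere	day3	1.3246	2	
S1	E09	blastomere	day3	7.3646	1	
S1	E09	blastomere	day3	5.0055	2	
S1	E10	blastomere	day3	80.2086	1	
S1	E10	blastomere	day3	79.2431	2	
S1	E11	blastomere	day3	14.5738	1	
S1	E11	blastomere	day3	17.0876	2	
S1	E12	blastomere	day3	8.4177	1	
S1	E12	blastomere	day3	6.1972	2	
S1	E13	blastomere	day3	3.611	1	
S1	E13	blastomere	day3	0.3961	2	
S1	E14	blastomere	day3	62.0291	1	
S1	E14	blastomere	day3	60.5502	2	
S1	E15	blastomere	day3	5.5521	1	
S1	E15	blastomere	day3	2.6335	2	
S1	E16	blastomere	day3	40.177	1	
S1	E16	blastomere	day3	40.9764	2	
S1	E17	blastomere	day3	62.9737	1	
S1	E17	blastomere	day3	64.9506	2	
S1	E18	blastomere	day3	22.5263	1	
S1	E18	blastomere	day3	20.0957	2	
S1	E19	blastomere	day3	0.0	1	
S1	E19	blastomere	day3	1.2457	2	
S1	E20	blastomere	day3	37.1668	1	
S1	E20	blastomere	day3	39.7411	2	
S1	E21	blastomere	day3	42.3827	1	
S1	E21	blastomere	day3	41.6045	2	
S1	E22	blastomere	day3	1.2407	1	
S1	E22	blastomere	day3	2.069	2	
S1	E23	blastomere	day3	15.8645	1	
S1	E23	blastomere	day3	19.0895	2	
S1	E24	blastomere	day3	36.0767	1	
S1	E24	blastomere	day3	37.5175	2	
S1	E25	blastomere	day3	10.0474	1	
S1	E25	blastomere	day3	7.8256	2	
S1	E26	blastomere	day3	11.3376	1	
S1	E26	blastomere	day3	10.1843	2	
S1	E27	blastomere	day3	81.4734	1	
S1	E27	blastomere	day3	82.8283	2	
S1	E28	blastomere	day3	13.8616	1	
S1	E28	blastomere	day3	17.4766	2	
S1	E29	blastomere	day3	30.8505	1	
S1	E29	blastomere	day3	35.5994	2	
S1	E30	blastomere	day3	60.9465	1	
S1	E30	blastomere	day3	60.2279	2	
S1	E31	blastomere	day3	17.4262	1	
S1	E31	blastomere	day3	15.002	2	
S1	E32	blastomere	day3	17.7936	1	
S1	E32	blastomere	day3	16.5605	2	
S1	E33	blastomere	day3	51.0121	1	
S1	E33	blastomere	day3	51.5229	2	
S1	E34	blastomere	day3	77.013	1	
S1	E34	blastomere	day3	75.0468	2	
S1	E35	blastomere	day3	13.5418	1	
S1	E35	blastomere	day3	12.5319	2	
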