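snp_id	chrom	pos	alleles	ihs	pihs	window	gene	distance_bp	region_label
rs109140890	5	54155228	A/G	4.71	5.61	54	SLC16A7	0	intron
rs109099698	5	54195124	A/G	4.54	5.26	54	SLC16A7	0	intron
rs134749225	5	54198119	A/G	-4.58	5.34	54	SLC16A7	0	intron
rs137138760	5	54272467	G/T	-4.47	5.11	55	LOC101907520	33220	intergenic
rs109120533	5	54288524	C/T	4.57	5.32	55	LOC101907520	49277	intergenic
rs135504287	5	54295924	A/C	-4.78	5.76	55	LOC101907520	56677	intergenic
rs133591560	5	54350533	C/T	-4.46	5.08	55	LOC101907520	111286	intergenic
rs111002641	5	54379176	A/C	4.84	5.89	55	LOC101907520	139929	intergenic
rs133087713	5	54399438	A/G	-4.57	5.32	55	LOC101907520	160191	intergenic
rs135847398	5	54511415	C/T	-4.46	5.09	55	LOC101907520	272168	intergenic
rs110300059	5	54745039	C/T	-4.56	5.29	55	LRIG3	139355	intergenic
rs133256279	5	54747486	A/C	-4.86	5.93	55	LRIG3	136908	intergenic
rs132685585	5	55175674	G/T	-4.43	5.03	55	LRIG3	239313	intergenic
rs136462146	5	55199380	C/T	-4.51	5.19	55	LRIG3	263019	intergenic
rs108956573	5	57606624	C/T	-4.58	5.33	58	RPS26	0	5' UTR
rs41657485	5	57625533	A/G	-4.55	5.28	58	IKZF4	0	intron
rs134894252	5	57634601	A/C	-4.59	5.35	58	IKZF4	0	intron
rs135485666	5	57643602	C/T	4.43	5.02	58	SUOX	0	intron
rs134235538	5	57647574	C/T	-4.55	5.27	58	RAB5B	0	3' UTR
rs137809406	5	57679838	C/T	4.52	5.22	58	DGKA	0	intron
rs29018280	5	57681031	G/T	4.61	5.40	58	DGKA	0	intron
rs135598509	5	57690096	C/T	-4.60	5.37	58	DGKA	0	intron
rs134140651	5	57697408	C/T	-4.52	5.21	58	DGKA	0	intron
rs137073278	5	57710890	C/T	-4.59	5.36	58	PYM1	0	intron
rs135368690	5	57729851	A/C	-4.59	5.36	58	PYM1	5697	intergenic
rs133170163	5	57736703	C/T	-4.59	5.36	58	PYM1	12552	intergenic
rs134681832	5	57741701	C/T	-4.68	5.55	58	PYM1	17550	intergenic
rs135835510	5	58467329	A/G	-4.43	5.02	59	LOC782296	2533	intergenic
rs109346532	5	60260395	C/T	-4.47	5.11	60	TESPA1	5391	intergenic
rs134633547	5	60261561	C/T	-4.47	5.11	60	TESPA1	4225	intergenic
rs109158476	5	60263049	C/T	4.56	5.28	60	TESPA1	2737	intergenic
rs134963725	5	60267575	A/G	4.54	5.25	60	TESPA1	0	intron
rs29002144	5	62646555	C/T	-4.55	5.28	63	LOC101905642	253100	intergenic
rs108993286	5	65656474	A/G	4.62	5.42	66	SPIC	5989	intergenic
rs109866300	5	68257487	A/G	4.52	5.22	68	TXNRD1	0	intron
rs110636438	5	72348422	C/T	4.61	5.39	73	LARGE	0	intron
rs110912484	5	72353301	A/G	4.79	5.79	73	LARGE	0	intron
rs41669840	5	72405286	G/T	-5.26	6.85	73	LARGE	0	intron
rs136536638	5	72410862	A/C	-4.47	5.11	73	LARGE	0	intron
rs137267491	14	25505663	G/T	4.44	5.05	25	IMPAD1	39242	intergenic
rs41627946	14	25506575	G/T	-4.62	5.41	25	IMPAD1	38330	intergenic
rs134846474	14	25537252	A/G	-4.53	5.22	25	IMPAD1	7653	intergenic
rs137748068	14	25819872	A/G	-4.47	5.10	25	FAM110B	230370	intergenic
rs42299083	14	25846511	C/T	-4.52	5.22	25	FAM110B	203731	intergenic
rs42299080	14	25851646	C/T	-4.75	5.70	25	FAM110B	198596	intergenic
rs136141080	14	25863924	C/T	-4.66	5.50	25	FAM110B	186318	intergenic
rs133252286	14	25866853	C/T	-4.54	5.24	25	FAM110B	183389	intergenic
rs134567839	14	25877586	C/T	-4.57	5.31	25	FAM110B	172656	intergenic
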