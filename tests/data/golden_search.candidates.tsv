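variant_id	chrom	pos	ref	alt	edit_class	editor	strand	protospacer_start	protospacer_end	spacer_seq	pam_seq	window_pos	bystanders	preferential
1	chr1	251	G	A	create_c_to_t	VQR-BE3	-	241	260	TACGTACGCCGCATTACCTT	TGA	10	7,9	false
1	chr1	251	G	A	create_c_to_t	xBE3	-	236	255	ACGCCGCATTACCTTTGATA	CG	5	4,7	false
2	chr1	351	C	T	create_c_to_t	SaKKH-BE3	+	344	364	GATAAAGCTCATAATGCGCTT	GTAAAT	8	10	false
2	chr1	351	C	T	create_c_to_t	xBE3	+	344	363	GATAAAGCTCATAATGCGCT	TG	8	.	true
3	chr1	1261	C	T	create_c_to_t	SaKKH-BE3	+	1252	1272	TACTGGAGCCACGTGAATGCT	CAAAGT	10	3,9,12	false
3	chr1	1261	C	T	create_c_to_t	xBE3	+	1258	1277	AGCCACGTGAATGCTCAAAG	TG	4	6	false
3	chr1	1261	C	T	create_c_to_t	xBE3	+	1256	1275	GGAGCCACGTGAATGCTCAA	AG	6	5,8	false
5	chr1	451	A	G	correct_t_to_c	SaKKH-BE3	-	436	456	GCTTTCGATCAGGGTTGTATA	CATAAT	6	10	false
6	chr1	806	A	G	correct_t_to_c	VQR-BE3	-	794	813	AATGAAACTGCATTGCCAGA	TGA	8	11	false
6	chr1	806	A	G	correct_t_to_c	VQR-BE3	-	797	816	TATAATGAAACTGCATTGCC	AGA	11	.	true
6	chr1	806	A	G	correct_t_to_c	SaKKH-BE3	-	796	816	TATAATGAAACTGCATTGCCA	GATGAT	11	.	true
6	chr1	806	A	G	correct_t_to_c	xBE3	-	794	813	AATGAAACTGCATTGCCAGA	TG	8	.	true
7	chr1	147	A	G	correct_t_to_c	BE3	-	133	152	CCTTACTCTTCGATTGCCAT	CGG	6	8	false
7	chr1	147	A	G	correct_t_to_c	eBE-S3	-	133	152	CCTTACTCTTCGATTGCCAT	CGG	6	8	false
7	chr1	147	A	G	correct_t_to_c	BE4max	-	133	152	CCTTACTCTTCGATTGCCAT	CGG	6	8	false
7	chr1	147	A	G	correct_t_to_c	AncBE4max	-	133	152	CCTTACTCTTCGATTGCCAT	CGG	6	8	false
7	chr1	147	A	G	correct_t_to_c	hA3A-BE3	-	133	152	CCTTACTCTTCGATTGCCAT	CGG	6	2,8,11	false
7	chr1	147	A	G	correct_t_to_c	hA3A-BE3-Y130F	-	133	152	CCTTACTCTTCGATTGCCAT	CGG	6	8	false
7	chr1	147	A	G	correct_t_to_c	hA3A-eBE-Y130F	-	133	152	CCTTACTCTTCGATTGCCAT	CGG	6	8	false
7	chr1	147	A	G	correct_t_to_c	YE1-BE3	-	133	152	CCTTACTCTTCGATTGCCAT	CGG	6	.	true
7	chr1	147	A	G	correct_t_to_c	YE2-BE3	-	133	152	CCTTACTCTTCGATTGCCAT	CGG	6	.	true
7	chr1	147	A	G	correct_t_to_c	EE-BE3	-	133	152	CCTTACTCTTCGATTGCCAT	CGG	6	.	true
7	chr1	147	A	G	correct_t_to_c	YEE-BE3	-	133	152	CCTTACTCTTCGATTGCCAT	CGG	6	.	true
7	chr1	147	A	G	correct_t_to_c	VRER-BE3	-	132	151	CTTACTCTTCGATTGCCATC	GGCG	5	7,10	false
7	chr1	147	A	G	correct_t_to_c	xBE3	-	132	151	CTTACTCTTCGATTGCCATC	GG	5	7	false
7	chr1	147	A	G	correct_t_to_c	xBE3	-	133	152	CCTTACTCTTCGATTGCCAT	CG	6	8	false
7	chr1	147	A	G	correct_t_to_c	BE-PLUS	-	133	152	CCTTACTCTTCGATTGCCAT	CGG	6	8,11	false
8	chr1	1031	T	C	correct_t_to_c	xBE3	+	1028	1047	ACTCGGCACTCAAACTGCCT	TG	4	7	false
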