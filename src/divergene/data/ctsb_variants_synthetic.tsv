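type	genomic_position	HAB	LAB	location	rel_position	mrna_position	snp_id
SNP	63097731	A	T	promoter	-2269		.
SNP	63097770	T	G	promoter	-2230		.
insertion	63097810	-	G	promoter	-2190		.
SNP	63097850	C	T	promoter	-2150		.
SNP	63097900	A	G	promoter	-2100		.
SNP	63097955	A	G	promoter	-2045		.
SNP	63098100	G	C	promoter	-1900		.
SNP	63098400	C	G	promoter	-1600		.
insertion	63098700	-	G	promoter	-1300		.
SNP	63099050	G	A	promoter	-950		.
SNP	63099400	G	T	promoter	-600		.
SNP	63099750	G	T	promoter	-250		.
SNP	63100199	A	T	intron-1	200		.
SNP	63100349	T	C	intron-1	350		.
deletion	63100499	C	-	intron-1	500		.
SNP	63100699	A	C	intron-1	700		.
SNP	63100899	T	G	intron-1	900		.
SNP	63101099	G	A	exon-2	1100	200	.
SNP	63101249	C	A	intron-2	1250		.
SNP	63101399	G	A	intron-2	1400		.
insertion	63101549	-	T	intron-2	1550		.
SNP	63101699	A	G	intron-2	1700		.
deletion	63101899	TAG	-	intron-2	1900		.
SNP	63102049	G	C	intron-2	2050		.
SNP	63102249	G	T	intron-2	2250		.
SNP	63102399	A	C	exon-3	2400	300	.
SNP	63102599	A	G	intron-3	2600		.
deletion	63102626	GG	-	intron-3	2627		.
deletion	63102653	T	-	intron-3	2654		.
SNP	63102680	G	T	intron-3	2681		.
SNP	63102707	G	C	intron-3	2708		.
SNP	63102734	C	A	intron-3	2735		.
insertion	63102761	-	TCC	intron-3	2762		.
SNP	63102788	T	G	intron-3	2789		.
SNP	63102815	A	T	intron-3	2816		.
SNP	63102842	G	T	intron-3	2843		.
SNP	63102869	C	G	intron-3	2870		.
SNP	63102896	A	T	intron-3	2897		.
SNP	63102923	T	A	intron-3	2924		.
SNP	63102950	T	A	intron-3	2951		.
insertion	63102977	-	T	intron-3	2978		.
SNP	63103004	A	C	intron-3	3005		.
SNP	63103031	A	T	intron-3	3032		.
SNP	63103148	T	G	intron-3	3149		.
SNP	63103599	C	G	intron-4	3600		.
deletion	63103635	CCA	-	intron-4	3636		.
SNP	63103671	G	T	intron-4	3672		.
insertion	63103707	-	A	intron-4	3708		.
SNP	63103743	T	A	intron-4	3744		.
SNP	63103779	C	T	intron-4	3780		.
SNP	63103815	A	T	intron-4	3816		.
SNP	63103851	A	C	intron-4	3852		.
SNP	63103887	T	G	intron-4	3888		.
SNP	63103923	T	G	intron-4	3924		.
SNP	63103959	T	A	intron-4	3960		.
SNP	63103998	C	A	intron-4	3999		.
SNP	63104979	G	A	exon-5	4980	580	.
SNP	63105049	A	G	exon-5	5050	650	.
SNP	63105199	C	A	intron-5	5200		.
SNP	63105399	T	G	intron-5	5400		.
deletion	63105599	C	-	intron-5	5600		.
SNP	63105949	A	G	intron-6	5950		.
SNP	63106199	A	G	intron-6	6200		.
insertion	63106449	-	T	intron-6	6450		.
SNP	63106699	G	T	intron-6	6700		.
SNP	63106899	G	A	intron-6	6900		.
SNP	63106999	T	G	exon-7	7000	900	.
SNP	63107199	A	C	intron-7	7200		.
SNP	63107499	C	G	intron-7	7500		.
SNP	63107849	C	T	exon-8	7850	1050	.
SNP	63108099	T	C	intron-8	8100		.
SNP	63108499	A	G	intron-8	8500		.
deletion	63108899	GAC	-	intron-8	8900		.
SNP	63109099	A	C	intron-8	9100		.
SNP	63109499	C	G	intron-9	9500		.
SNP	63109799	T	C	intron-9	9800		.
SNP	63110099	A	T	intron-9	10100		.
SNP	63110399	T	C	exon-10	10400	1300	.
SNP	63110499	C	G	exon-10	10500	1400	.
SNP	63111199	A	G	DER	11200		.
insertion	63111231	-	CCA	DER	11232		.
SNP	63111263	G	C	DER	11264		.
SNP	63111295	T	A	DER	11296		.
SNP	63111327	T	A	DER	11328		.
SNP	63111359	T	A	DER	11360		.
deletion	63111391	C	-	DER	11392		.
SNP	63111423	G	A	DER	11424		.
SNP	63111455	G	A	DER	11456		.
SNP	63111487	A	C	DER	11488		.
SNP	63111519	T	G	DER	11520		.
deletion	63111548	G	-	DER	11549		.
SNP	63112199	A	T	DER	12200		.
SNP	63112699	A	G	DER	12700		.
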