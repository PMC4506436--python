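mode	deg_direction	tf	pmid	cell_line	K	k	n	N	printed_fold_ratio
enriched	up	TRIM28	21343339	HEK293	85	21	1477	23284	3.9
enriched	up	ESR1	21235772	MCF-7	213	36	1477	23284	2.7
enriched	up	CLOCK	20551151	293T	398	58	1477	23284	2.3
enriched	up	ESR2	21235772	MCF-7	392	57	1477	23284	2.3
enriched	up	SMAD3	21741376	HESC	1074	144	1477	23284	2.1
enriched	up	SOX2	20726797	SW620	2060	275	1477	23284	2.1
enriched	up	RELA	24523406	A549	1147	152	1477	23284	2.1
enriched	up	BACH1	22875853	HELA-AND-SCP4	1183	150	1477	23284	2.0
enriched	up	GATA1	19941826	K562	700	84	1477	23284	1.9
enriched	up	TP53	18474530	U2OS	734	88	1477	23284	1.9
enriched	up	GATA2	21666600	HMVEC	634	75	1477	23284	1.9
enriched	up	PAX3-FKHR	20663909	RHABDOMYOSARCOMA	975	115	1477	23284	1.9
enriched	up	SMAD4	21741376	HESC	2032	237	1477	23284	1.8
enriched	up	DROSHA	22980978	HELA	441	51	1477	23284	1.8
enriched	up	ZNF217	24962896	MCF7	1400	160	1477	23284	1.8
enriched	up	NFE2L2	22581777	LYMPHOBLASTOID	508	58	1477	23284	1.8
enriched	up	EOMES	21245162	HESC	861	98	1477	23284	1.8
enriched	up	SMAD2	18955504	HaCaT	1643	184	1477	23284	1.8
enriched	up	SMAD3	18955504	HaCaT	1643	184	1477	23284	1.8
enriched	up	NR3C1	21868756	MCF10A	1023	111	1477	23284	1.7
enriched	up	DNAJC2	21179169	NT2	803	87	1477	23284	1.7
enriched	up	EGR1	20690147	ERYTHROLEUKEMIA	5216	549	1477	23284	1.7
enriched	up	SOX2	21211035	LN229_GBM	2830	288	1477	23284	1.6
enriched	up	GATA2	19941826	K562	1727	175	1477	23284	1.6
enriched	up	MYC	19915707	AK7	1793	177	1477	23284	1.6
enriched	up	AR	19668381	PC3	2958	291	1477	23284	1.6
enriched	up	ATF3	23680149	GBM1-GSC	1995	193	1477	23284	1.5
enriched	up	SMAD4	21799915	A2780	2302	220	1477	23284	1.5
enriched	up	GATA1	21571218	MEGAKARYOCYTES	2388	228	1477	23284	1.5
enriched	down	TRIM28	21343339	HEK293	85	22	2010	23284	3.0
enriched	down	ESR2	21235772	MCF-7	392	98	2010	23284	2.9
enriched	down	CTNNB1	24651522	LGR5+INTESTINAL	138	30	2010	23284	2.5
enriched	down	SOX2	20726797	SW620	2060	433	2010	23284	2.4
enriched	down	IRF1	21803131	MONOCYTES	326	67	2010	23284	2.4
enriched	down	TFAP2C	20629094	MCF7	1125	229	2010	23284	2.4
enriched	down	ESR1	21235772	MCF-7	213	43	2010	23284	2.3
enriched	down	ZNF217	24962896	MCF7	1400	271	2010	23284	2.2
enriched	down	FOXM1	23109430	U2OS	253	47	2010	23284	2.2
enriched	down	NR1H3	23393188	ATHEROSCLEROTIC-FOAM	574	104	2010	23284	2.1
enriched	down	CDX2	20551321	CACO-2	383	69	2010	23284	2.1
enriched	down	BACH1	22875853	HELA-AND-SCP4	1183	211	2010	23284	2.1
enriched	down	AHR	22903824	MCF7	621	109	2010	23284	2.0
enriched	down	FOXO3	23340844	DLD1	650	114	2010	23284	2.0
enriched	down	AR	21909140	LNCAP	258	45	2010	23284	2.0
enriched	down	TP53	16413492	HCT116	276	48	2010	23284	2.0
enriched	down	SMAD2	18955504	HaCaT	1643	285	2010	23284	2.0
enriched	down	SMAD3	18955504	HaCaT	1643	285	2010	23284	2.0
enriched	down	TP53	18474530	U2OS	734	122	2010	23284	1.9
enriched	down	RELA	24523406	A549	1147	187	2010	23284	1.9
enriched	down	TP63	23658742	EP156T	3355	541	2010	23284	1.9
enriched	down	ARNT	22903824	MCF7	912	147	2010	23284	1.9
enriched	down	SMAD4	19686287	HaCaT	348	56	2010	23284	1.9
enriched	down	TCF4	18268006	LS174T	392	63	2010	23284	1.9
enriched	down	CLOCK	20551151	293T	398	62	2010	23284	1.8
enriched	down	PAX3-FKHR	20663909	RHABDOMYOSARCOMA	975	144	2010	23284	1.7
enriched	down	TP63	22573176	HFKS	3867	570	2010	23284	1.7
enriched	down	GATA1	19941826	K562	700	103	2010	23284	1.7
enriched	down	SMAD3	21741376	HESC	1074	158	2010	23284	1.7
enriched	down	CTNNB1	20460455	HCT116	900	130	2010	23284	1.7
enriched	down	FOXA2	19822575	HepG2	2791	402	2010	23284	1.7
enriched	down	SMAD4	21741376	HESC	2032	290	2010	23284	1.7
enriched	down	ELF5	23300383	T47D	920	130	2010	23284	1.6
enriched	down	GATA2	19941826	K562	1727	241	2010	23284	1.6
enriched	down	TRIM28	17542650	NTERA2	680	94	2010	23284	1.6
enriched	down	GATA2	21666600	HMVEC	634	87	2010	23284	1.6
enriched	down	AR	19668381	PC3	2958	398	2010	23284	1.6
enriched	down	HNF4A	19761587	CACO-2	816	108	2010	23284	1.5
enriched	down	AR	22383394	PROSTATE_CANCER	1690	221	2010	23284	1.5
depleted	up	ELF1	17652178	JURKAT	99	0	1477	23284	Inf
depleted	up	GABP	17652178	JURKAT	655	9	1477	23284	4.6
depleted	up	EST1	17652178	JURKAT	636	9	1477	23284	4.5
depleted	up	ETS1	20019798	JURKAT	1446	28	1477	23284	3.3
depleted	up	KDM6A	18722178	U937_AND_SAOS2	410	9	1477	23284	2.9
depleted	up	FOXP3	21729870	TREG	1300	43	1477	23284	1.9
depleted	up	VDR	23849224	CD4+	2029	69	1477	23284	1.9
depleted	up	GABP	19822575	HepG2	2430	92	1477	23284	1.7
depleted	up	HOXC9	25013753	NEUROBLASTOMA-BE2-C	1858	72	1477	23284	1.6
depleted	down	GABP	17652178	JURKAT	655	16	2010	23284	3.5
depleted	down	KDM6A	18722178	U937_AND_SAOS2	410	14	2010	23284	2.5
depleted	down	ETS1	20019798	JURKAT	1446	59	2010	23284	2.1
depleted	down	EST1	17652178	JURKAT	636	28	2010	23284	2.0
depleted	down	GABP	19822575	HepG2	2430	132	2010	23284	1.6
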