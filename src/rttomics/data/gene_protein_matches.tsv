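gene	protein	accession	gene_fold_change	protein_fold_change	ptm	rtt_refs
Mecp2	MeCP2	Q9Z2D6	-0.66	-10.6	none	1,2
Rnpep	RNPEP	Q8VCT3	-0.78	-3.47	none	2
Pdia4	ERp72	P08003	-0.71	-2.22	none	2,3
Hsph1	HSPH1	Q61699	-0.80	-2.13	none	4
Rnpep	RNPEP(Ac)	Q8VCT3	-0.78	-2.02	acetyl	2
Aldh1a1	ALDH1A1	P24549	-0.67	-1.95	none	2
Slc9a3r1	NHERF1(P)	P70441	-0.74	-1.79	phospho	3
Ugt8a	UGT8	Q64676	-0.79	-1.76	none	
Qdpr	QDPR	Q8BVI4	-0.74	-1.68	none	2
Ugp2	UGP2	Q91ZJ5	-0.73	-1.67	none	2
Car2	Ca2	P00920	-0.72	-1.61	none	
Grm3	mGluR3	Q9QYS2	-0.63	-1.6	none	2
Ephx2	EPHX2	P34914	-0.71	-1.59	none	2
Hpcal4	HPCAL4	Q8BGZ1	-0.69	-1.51	none	2,3
Spr	SPR	Q64105	-0.77	-1.47	none	
Sash1	SASH1	P59808	-0.82	-1.44	none	
Calr	CRT	P14211	-0.80	-1.43	none	3
Aacs	AACS	Q9D2R0	-0.79	-1.37	none	2
S1pr1	S1P1	O08530	-0.78	-1.28	none	
Slc9a3r1	NHERF1(Ac)	P70441	-0.74	-1.24	acetyl	3
Nova1	NOVA1	Q9JKN6	1.26	1.28	none	
Slc24a4	Nckx4	Q8CGQ8	1.58	1.3	none	3
Kcnab3	Kvb3.1	P97382	1.27	1.43	none	
Me3	NADP-ME3	Q8BMF3	1.28	1.46	none	
Tfrc	TfR	Q62351	1.32	1.48	none	
Dgkg	DGKg	Q91WG7	1.42	1.51	none	2,3
Prkcg	PKCg(P)	P63318	-0.82	1.66	phospho	3
Rasgrf1	RasGRF1	P27671	1.32	1.68	none	
Zmat4	ZMAT4	Q8BZ94	1.50	1.88	none	3
Myo1b	Myo1b	P46735	1.32	2.02	none	2,3
Fkbp5	FKBP5	Q64378	1.81	2.02	none	2,3,4,5,6
Wipf3	WIPF3	P0C7L0	1.23	2.26	none	
Itih3	ITI-HC3	Q61704	1.52	2.37	none	
Gfra1	GDNFRa1	P97785	1.26	2.64	none	2,3
Sun2	SUN2	Q8BJS4	1.42	2.86	none	3
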