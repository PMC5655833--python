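gene	log2_fold_change	prior_direction	prior_refs
Aacs	-0.79	Decrease	4
Aldh1a1	-0.67	Decrease	4
Arhgdig	-0.69	Decrease	2
Auts2	1.40	Increase	7
C1qa	-0.76	Decrease	7
Cacnb3	-0.79	Increase	2
Calb1	-0.79	Decrease	5
Calr	-0.80	Decrease	8
Dgkg	1.42	Increase	4,8
Ephx2	-0.71	Decrease	4
Fabp7	-0.39	Decrease	2,5
Fkbp5	1.81	Increase	3,4,5,7,8
Gabra3	-0.81	Decrease	6
Gfra1	1.26	Increase	4,8
Grm3	-0.63	Decrease	4
Hpcal4	-0.69	Decrease	4,8
Hsph1	-0.80	Decrease	3
Itm2a	-0.73	Decrease	5
Mecp2	-0.66	Decrease	1,4
Msmo1	-0.77	Decrease	5
Myo1b	1.32	Increase	4,8
Pcsk1	-0.74	Decrease	6
Pdia4	-0.71	Decrease	4,8
Plagl1	1.37	Increase	5
Prkcg	-0.82	Decrease	8
Pvalb	1.27	Increase	2
Pygm	1.29	Increase	6
Qdpr	-0.74	Decrease	4
Rnpep	-0.78	Decrease	4
Sgk1	1.37	Increase	2,3
Slc24a4	1.58	Increase	4
Slc9a3r1	-0.74	Decrease	8
Sun2	1.42	Increase	8
Ugp2	-0.73	Decrease	4
Zmat4	1.5	Increase	8
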