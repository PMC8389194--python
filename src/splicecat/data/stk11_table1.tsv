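rna_consequence	name	mean_reads	mean_percentage	biotype	pct_samples	previously_published	marker	flag_reason
r.-272_-186del	Δ5′UTR	64	0.026	terminal modification	33	no		
r.-245_-209del	Δ5′UTR	56	0.023	terminal modification	50	no		
r.-258_-185del	Δ5′UTR	150	0.061	terminal modification	50	no		
r.-323_597del	Δ5′UTR	86	0.029	terminal modification	33	no		name_coord_conflict
r.290_291ins290+2456_290+2554	▼1A	608	0.207	cryptic exon inclusion	67	yes		
r.290_291ins290+5106_290+5326	▼1B	44	0.015	cryptic exon inclusion	50	yes		
r.290_291ins291-2149_291-2019	▼1C	10912	3.717	cryptic exon inclusion	100	yes		
r.290_291ins291-2038_291-102	▼1D	70	0.024	cryptic exon inclusion	83	yes		
r.290_291ins291-2897_291-2755	▼1E	72	0.025	cryptic exon inclusion	33	no		
r.290_291ins291-2149_291-1782	▼1F	105	0.071	cryptic exon inclusion	67	no		
	▼1G	146	0.050	cryptic exon inclusion	100	yes		missing_coordinates
r.290_291ins290+114_290+190	▼1H	116	0.040	cryptic exon inclusion	17	yes	‡	
r.290_291ins291-2149_291-1324	▼1I	175	0.060	cryptic exon inclusion	17	yes	‡	
intron 1 junction	/	293569	/	intron 1 junction	100	yes		
r.374delinsAC	Δ2pA	405	0.141	exonic donor shift	100	no		sequence_level
r.374insA_375delG	Δ2pB	117	0.041	exonic donor shift	100	no		sequence_level
r.373_376del	Δ2,3q	274	0.096	exonic acceptor shift	100	no		compound_style
r.291_464del	Δ2–3	1140	0.373	multiple exon skipping	100	yes		
intron 2 junction	/	286038	/	intron 2 junction	100	yes		
r.373_378del	Δ3q	227	0.079	exonic acceptor shift	67	no		name_coord_conflict
intron 3 junction	/	316895	/	intron 3 junction	100	yes		
r.465_597del	Δ4	532	0.186	exon skipping	100	yes		
r.490_653del	Δ4p,Δ5q	67	0.022	mixed	50	no		compound_style
r.465_734del	Δ4–5	6	0.002	multiple exon skipping	100	yes	§	
r.465_920del	Δ4–7	62	0.023	multiple exon skipping	100	yes		
intron 4 junction	/	254161	/	intron 4 junction	100	yes		
r.706_734del	Δ5	342	0.125	exon skipping	83	yes		name_coord_conflict
r.734del	Δ5p	29	0.010	exonic donor shift	83	no		
intron 5 junction	/	295148	/	intron 5 junction	100	yes		
r.862del	Δ6p	36	0.015	exonic donor shift	100	no		
r.862_863ins862+281_863-103	▼7A	1545	0.661	cryptic exon inclusion	100	yes		
r.862_863ins862+286_863-103	▼7B	1218	0.521	cryptic exon inclusion	100	yes		
r.862_863ins863-283_863-103	▼7C	3230	1.382	cryptic exon inclusion	100	yes		
r.862_863ins863-253_863-103	▼7D	4570	1.956	cryptic exon inclusion	100	yes		
r.862_863ins863-195_863-103	▼7E	186	0.079	cryptic exon inclusion	67	no		
r.858_862del+r.862_863ins863-125_863-103	▼7F	16	0.007	mixed	33	no		compound_style
r.862_863ins863-126_863-103	▼7G	25	0.011	cryptic exon inclusion	33	no		letter_history
r.862_863ins863-125_863-103	▼7H	202	0.087	cryptic exon inclusion	100	no		letter_history
r.820_921ins921-34_921-1	▼7q	29	0.012	intronic acceptor shift	17	yes	‡	anchor_typo
intron 6 junction	/	233667	/	intron 6 junction	100	yes		
r.920_921ins921-105_921-1	▼8qA	185	0.074	intronic acceptor shift	100	yes		
r.920_921ins921-87_921-1	▼8qB	186	0.074	intronic acceptor shift	83	yes		
intron 7 junction	/	250858	/	intron 7 junction	100	yes		
r.1180_1181ins1108+466_1108+600	▼8A	749	0.331	cryptic exon inclusion	100	yes		anchor_typo
r.1180_1181ins_1180+1_1108+187	▼8p	141	0.062	intronic donor shift	33	no		anchor_typo
r.1180_1181ins1108+466_1109-641	▼8B	95	0.042	cryptic exon inclusion	50	yes		anchor_typo
intron 8 junction	/	226042	/	intron 8 junction	100	yes		
r.1109_1113del	Δ9q	9881	4.371	exonic acceptor shift	100	yes		
r.1109_*16del	Δ9	67	0.047	exon skipping	33	yes		
intron 9 junction	/	56173	/	intron 9 junction	100	yes		
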