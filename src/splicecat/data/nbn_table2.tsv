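rna_consequence	name	mean_reads	mean_percentage	biotype	pct_samples	previously_published	marker	flag_reason
r.37_38ins37+466_37+648	▼1A	72	0.179	cryptic exon inclusion	50	No		
r.37_38ins37+698_37+779	▼1B	33	0.080	cryptic exon inclusion	50	No		
intron 1 junction	/	52217	/	intron 1 junction	100	No		
r.38_40del	Δ2q	17	0.033	exonic acceptor shift	67	No		
r.171_172ins172-479_172-430	▼2	12105	11.297	cryptic exon inclusion	100	yes		
r.171_172ins172-27_172-1	▼3q	50	0.070	intronic acceptor shift	83	No		
r.171_172ins171+1_171+4	▼4p	35	0.048	intronic donor shift	100	No		name_coord_conflict
intron 2 junction	/	72077	/	intron 2 junction	100	No		
r.38_171del	Δ2	31	0.169	exon skipping	83	No		
intron 3 junction	/	115981	/	intron 3 junction	100	No		
r.172_320del	Δ3–4	21	0.020	multiple exon skipping	33	No		duplicate_name
r.172_320del	Δ3	137	0.145	exon skipping	83	No		
r.321_325del	Δ4qA	37	0.032	exonic acceptor shift	67	No		
r.321_361del	Δ4qB	3341	2.881	exonic acceptor shift	100	No		
r.172_361del NM_001024688.2		31	/	exon skipping+exonic acceptor shift	83	No		unnamed
r.172_361del	Δ3+4qC	118	0.126	exon skipping+exonic acceptor shift	67	No		compound_style
r.480_481ins480+306_480+395	▼4	1294	1.041	cryptic exon inclusion	100	No		
intron 4 junction	/	138006	/	intron 4 junction	100	No		
r.38_480del	Δ2–4	24	0.023	multiple exon skipping	83	No		
r.321_480del	Δ4	58	0.045	exon skipping	50	No		
r.172_480del	Δ3–4	43	0.040	multiple exon skipping	33	No		
r.481del	Δ5qB	22	0.016	exonic acceptor shift	100	No		orphan_letter
intron 5 junction	/	135653	/	intron 5 junction	100	No		
r.481_584del	Δ5	891	0.651	exon skipping	100	Yes		
r.321_584del	Δ4–5	161	0.116	multiple exon skipping	100	Yes		
r.172_584del	Δ3–5	37	0.035	multiple exon skipping	33	No		
r.38_584del	Δ2–5	164	0.174	multiple exon skipping	83	No		
r.589del	Δ6qB	86	0.064	exonic acceptor shift	100	No		name_coord_conflict
intron 6 junction	/	139974	/	intron 6 junction	100	No		
r.585_702del	Δ6	75	0.054	exon skipping	50	No		
r.703_820del	Δ7q	127	0.090	exonic acceptor shift	50	Yes		
intron 7 junction	/	179463	/	intron 7 junction	100	No		
r.585_896del	Δ6–7	118	0.075	multiple exon skipping	83	Yes		
r.481_896del	Δ5–7	202	0.224	multiple exon skipping	67	No		
r.38_896del	Δ2–7	61	0.052	multiple exon skipping	67	No		
r.897del	Δ8q	17	0.010	exonic acceptor shift	100	No		
r.994_995ins994+1178_995-1769	▼8A	86	0.041	cryptic exon inclusion	67	No		
r.994_995ins995-1769_995-1604	▼8B	34	0.015	cryptic exon inclusion	33	No		
intron 8 junction	/	202305	/	intron 8 junction	100	No		
r.1124_1125ins1124+703_1124+760	▼9	391	0.220	cryptic exon inclusion	100	Yes		
intron 9 junction	/	181550	/	intron 9 junction	100	No		
r.995_1124del	Δ9	173	0.270	exon skipping	100	No		
intron 10 junction	/	127561	/	intron 10 junction	100	No		
r.1398del	Δ11qA	29	0.023	exonic acceptor shift	100	No		
r.1398_1403del	Δ11qB	83	0.065	exonic acceptor shift	33	No		
r.1398_1471del	Δ11qC	70	0.055	exonic acceptor shift	83	No		
r.1845_1846ins1845+1521_1845+1597	▼11	22	0.030	cryptic exon inclusion	33	No		
r.1845_1846ins1846-23_1846-1	▼12q	68	0.052	intronic acceptor shift	83	No		
intron 11 junction	/	132009	/	intron 11 junction	100	No		
r.1846_1849del	Δ12q	46	0.035	exonic acceptor shift	67	No		
intron 12 junction	/	128083	/	intron 12 junction	100	No		
r.1896_1914del	Δ12p	152	0.118	exonic donor shift	100	No		
r.1846_1914del	Δ12	894	1.030	exon skipping	100	No		
r.1915_1932del	Δ13qA	316	0.247	exonic acceptor shift	100	No		
r.1915_2009del	Δ13qB	114	0.089	exonic acceptor shift	67	Yes		
intron 13 junction	/	128636	/	intron 13 junction	100	No		
r.1915_2070del	Δ13	1576	1.228	exon skipping	100	Yes		
r.1846_2070del	Δ12–13	96	0.074	multiple exon skipping	83	No		
r.2184_2185ins2184+417_2184+464	▼14A	59	0.042	cryptic exon inclusion	100	No		
r.2184_2185ins2184+1511_2184+1578	▼14B	58	0.036	cryptic exon inclusion	67	No		
r.2184_2185ins2185-735_2185-610	▼14C	76	0.059	cryptic exon inclusion	83	No		
r.2184_2185ins2185-718_2185-610	▼14D	184	0.149	cryptic exon inclusion	100	Yes		
r.2184_2185ins2185-4_2185-1ins	▼14q	33	0.026	intronic acceptor shift	33	No		consequence_typo
intron 14 junction	/	123705	/	intron 14 junction	100	No		
r.2071_2184del	Δ14	98	0.077	exon skipping	100	No		
r.1915_2184del	Δ13–14	45	0.073	multiple exon skipping	83	No		
r.1846_2184del	Δ12–14	222	0.174	multiple exon skipping	100	Yes		
intron 15 junction	/	136201	/	intron 15 junction	100	No		
r.2185_2234del	Δ15	70	0.054	exon skipping	83	No		
r.1915_2234del	Δ13–15	100	0.075	multiple exon skipping	100	No		
r.*39_*541del	Δ3′UTR	93	0.068	terminal modification	67	No		
r.2003_*1085del	Δ13p+Δ14–15	74	0.058	multiple exon skipping+exonic donor shift	33	No		name_coord_conflict
r.*1076_*1143del	Δ3′UTR	27	0.020	terminal modification	33	No		
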