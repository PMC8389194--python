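#gene	STK11
#transcript	NM_000455.4
#chrom	chrS
#strand	+
#cds_start	371
#cds_end	1672
1	10001	10660
2	22661	22744
3	23245	23334
4	23835	23967
5	24468	24604
6	25105	25232
7	26233	26290
8	26791	26978
9	28379	28588
10	29089	29388
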