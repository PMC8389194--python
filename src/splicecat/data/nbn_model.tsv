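#gene	NBN
#transcript	NM_002485.4
#chrom	chrN
#strand	-
#cds_start	101
#cds_end	2365
1	43429	43565
2	41495	41628
3	40146	40294
4	39486	39645
5	38382	38485
6	37764	37881
7	37070	37263
8	36472	36569
9	32542	32671
10	30669	30941
11	29721	30168
12	26252	26320
13	25596	25751
14	24982	25095
15	21732	21781
16	20001	21231
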