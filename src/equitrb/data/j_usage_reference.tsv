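j_gene	cluster	clonotypes	d1	d2	nd	mean_cdr3	cdr3_min	cdr3_max
TRBJ1-1	1	12	6	0	6	12.25	9	16
TRBJ1-2	1	25	14	2	9	12.04	9	16
TRBJ1-3	1	0	0	0	0			
TRBJ1-4	1	4	2	0	2	12.75	11	14
TRBJ1-5	1	4	1	1	2	12.00	11	13
TRBJ1-6	1	19	9	1	9	12.57	10	17
TRBJ2-1	2	42	9	22	11	12.69	9	18
TRBJ2-2	2	5	0	1	4	12.40	10	14
TRBJ2-3	2	21	6	7	8	12.90	10	16
TRBJ2-4	2	37	4	22	11	12.76	10	16
TRBJ2-5	2	12	1	8	3	12.17	10	16
TRBJ2-6	2	9	1	4	4	13.89	12	17
TRBJ2-7	2	22	0	13	9	12.54	10	15
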