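subgroup	n_genes	n_p	n_f	n_orf
TRBV1	1	0	1	0
TRBV2	3	2	1	0
TRBV3	3	0	3	0
TRBV4	5	5	0	0
TRBV5	20	13	6	1
TRBV6	6	0	6	0
TRBV7	11	7	4	0
TRBV8	7	5	0	2
TRBV9	0	0	0	0
TRBV10	4	3	1	0
TRBV11	4	3	1	0
TRBV12	7	3	3	1
TRBV13	4	3	1	0
TRBV14	4	1	3	0
TRBV15	5	2	3	0
TRBV16	5	3	2	0
TRBV17	5	5	0	0
TRBV18	7	7	0	0
TRBV19	6	6	0	0
TRBV20	8	7	1	0
TRBV21	4	0	4	0
TRBV22	2	1	0	1
TRBV23	4	4	0	0
TRBV24	1	1	0	0
TRBV25	1	0	1	0
TRBV26	2	2	0	0
TRBV27	2	0	2	0
TRBV28	3	0	3	0
TRBV29	1	0	1	0
TRBV30	1	1	0	0
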