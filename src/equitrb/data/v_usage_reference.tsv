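subgroup	clonotypes	resolved
TRBV1	0	
TRBV2	2	TRBV2-2:2
TRBV3	9	TRBV3-3:5
TRBV4	0	
TRBV5	26	TRBV5-2:1;TRBV5-4:1;TRBV5-7:4;TRBV5-12:3;TRBV5-13:4;TRBV5-15:6;TRBV5-19:1
TRBV6	2	TRBV6-6:1
TRBV7	7	TRBV7-7:4
TRBV8	3	TRBV8-3:2;TRBV8-5:1
TRBV9	0	
TRBV10	0	
TRBV11	1	TRBV11-4:1
TRBV12	11	TRBV12-2:10;TRBV12-7:1
TRBV13	0	
TRBV14	14	TRBV14-3:5;TRBV14-4:2
TRBV15	6	TRBV15-2:2;TRBV15-5:3
TRBV16	0	
TRBV17	0	
TRBV18	0	
TRBV19	0	
TRBV20	34	TRBV20-3:3;TRBV20-8:26
TRBV21	21	
TRBV22	0	
TRBV23	0	
TRBV24	0	
TRBV25	3	
TRBV26	0	
TRBV27	4	TRBV27-1:1
TRBV28	17	
TRBV29	1	
TRBV30	0	
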