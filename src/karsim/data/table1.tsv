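round	ER	IC	cis	med1	med2	med3	med4	TGN	PGC	departure
1	10	20	0	0	0	0	0	0	0	
2	10	7	13	0	0	0	0	0	0	
3	10	20	4	9	0	0	0	0	0	
4	10	8	16	3	6	0	0	0	0	
5	10	20	6	13	2	4	0	0	0	
6	10	9	17	5	10	1	3	0	0	
7	10	20	7	15	4	7	1	2	0	
8	10	9	18	6	13	3	5	1	1	
9	10	20	8	16	5	11	2	4	1	
10	10	9	19	7	14	4	9	2	3	
11	10	20	9	17	6	12	4	7	3	
12	10	10	19	8	15	5	11	3	7	
13	10	20	9	18	7	13	5	9	7	
14	10	10	19	8	17	6	12	5	11	
15	10	20	9	18	8	15	6	11	11	
16	10	10	19	9	17	7	14	7	15	
17	10	20	9	19	8	16	7	14	15	
18	10	10	19	9	18	8	15	10	19	
19	10	20	10	19	9	17	8	17	19	
20	10	10	20	9	19	8	17	12	24	
21	10	20	10	19	9	18	10	19	24	
22	10	10	20	9	19	9	19	14	29	
23	10	20	10	19	9	19	11	22	29	
24	10	10	20	9	19	10	20	17	34	
25	10	20	10	19	10	19	12	25	34	
26	10	10	20	10	19	11	20	20	39	
27	10	20	10	20	10	20	13	37	39	
28	10	10	20	10	20	11	22	25	51	yes
29	10	20	10	20	10	21	16	31	25	
30	10	10	20	10	20	12	35	19	37	
31	10	20	10	20	11	21	15	29	37	
32	10	10	20	10	21	12	24	22	44	
33	10	20	10	20	11	22	15	31	44	
34	10	10	20	10	21	12	35	25	49	
35	10	20	10	20	11	22	20	40	49	
36	10	10	20	10	21	14	28	29	60	yes
37	10	20	10	20	12	23	16	31	29	
38	10	10	20	11	21	13	26	20	40	
39	10	20	10	31	11	23	15	31	40	
40	10	10	20	14	28	16	32	24	47	
41	10	20	11	23	15	29	25	51	47	
42	10	10	21	13	25	18	36	33	65	yes
43	10	20	11	23	14	29	23	46	33	
44	10	10	21	12	25	17	35	26	53	yes
45	10	20	11	22	14	28	20	41	26	
46	10	10	21	12	24	16	32	22	45	
47	10	20	11	22	13	27	18	36	45	
48	10	10	21	12	23	15	30	27	54	yes
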