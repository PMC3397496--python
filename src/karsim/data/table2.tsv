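round	ER	cis	med1	med2	med3	med4	med5	TGN	PGC
0	10	10	10	10	10	10	10	10	10
1	10	20	7	13	7	13	13	7	10
2	10	7	18	7	13	17	9	11	6
3	10	20	8	17	10	20	13	7	6
4	10	9	19	9	18	22	11	9	4
5	10	20	9	19	13	27	13	7	4
6	10	10	19	11	21	27	13	7	4
7	10	20	10	20	16	32	13	7	4
8	10	10	20	12	24	30	15	7	4
9	10	20	11	21	18	36	15	7	4
10	10	10	21	13	26	34	17	7	4
11	10	20	11	23	20	40	16	8	4
12	10	10	21	14	29	38	18	8	4
13	9	18	12	23	22	45	17	9	4
14	9	10	20	15	30	41	21	9	4
15	8	16	12	23	24	49	20	10	4
16	8	9	19	16	31	46	23	9	5
17	7	14	12	23	26	51	21	11	5
18	7	8	16	16	33	48	24	11	5
19	6	12	14	28	27	54	23	12	5
20	6	9	17	15	30	52	26	11	6
21	5	10	11	21	27	55	25	12	6
22	5	7	14	16	32	53	26	12	6
23	4	8	10	20	28	57	25	13	6
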