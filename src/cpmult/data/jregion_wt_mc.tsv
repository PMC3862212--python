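# J-region CDR3 counts, six melanoma patients (blood)
type	A	B	C	D	E	F
1-1	15	9	9	14	7	16
1-2	8	4	9	13	10	6
1-3	0	6	1	5	5	2
1-4	1	1	1	2	1	2
1-5	5	3	5	8	7	12
1-6	0	1	4	3	9	1
2-1	12	12	14	12	14	13
2-2	13	8	5	5	10	2
2-3	12	9	10	8	7	6
2-4	1	0	2	0	1	1
2-5	3	10	16	2	4	5
2-6	1	1	2	1	2	0
2-7	18	21	13	19	20	12
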