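# J-region CDR3 counts, six melanoma patients (blood)
type	A	B	C	D	E	F
1-1	6	3	3	9	7	4
1-2	3	9	5	8	7	6
1-3	1	0	0	2	2	1
1-4	0	0	6	1	1	0
1-5	3	1	2	0	6	1
1-6	1	3	3	4	7	3
2-1	12	2	4	7	5	18
2-2	6	13	4	1	2	11
2-3	3	2	8	6	9	13
2-4	0	0	0	0	1	0
2-5	5	1	10	4	7	7
2-6	1	0	0	2	1	0
2-7	5	5	10	19	10	5
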