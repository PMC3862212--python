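# J-region CDR3 counts, six melanoma patients (blood)
type	A	B	C	D	E	F
1-1	3	3	3	6	11	1
1-2	2	0	1	1	4	2
1-3	1	0	0	0	0	1
1-4	0	0	1	2	4	1
1-5	0	0	0	2	3	4
1-6	1	1	0	1	1	2
2-1	3	1	3	2	5	4
2-2	1	0	5	1	4	4
2-3	2	2	3	1	4	3
2-4	1	0	0	0	1	1
2-5	3	2	3	1	2	3
2-6	1	0	0	0	0	2
2-7	5	2	0	0	10	4
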