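# J-region CDR3 counts, six melanoma patients (blood)
type	A	B	C	D	E	F
1-1	49	1	71	0	11	0
1-2	0	1	1	2	2	2
1-3	1	3	2	0	1	0
1-4	0	0	0	18	0	6
1-5	2	0	0	0	7	0
1-6	1	0	2	0	0	3
2-1	5	70	0	10	14	22
2-2	4	10	5	1	2	55
2-3	7	0	0	56	14	0
2-4	0	0	0	0	0	0
2-5	7	0	0	1	0	0
2-6	0	0	5	0	0	0
2-7	5	1	6	7	31	19
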