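regulator	target	kind	partner	locked
1	9	linear		0
2	9	linear		0
2	10	linear		0
3	7	linear		0
3	8	linear		0
3	10	linear		0
4	2	linear		0
4	6	linear		0
4	9	linear		0
4	10	linear		0
5	1	linear		0
5	2	linear		0
5	8	linear		0
6	3	linear		0
6	9	linear		0
7	1	linear		0
7	4	linear		0
7	8	linear		0
8	2	linear		0
8	3	linear		0
8	5	linear		0
8	6	linear		0
9	7	linear		0
9	8	linear		0
10	1	linear		0
10	3	linear		0
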