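regulator	target	kind	partner	locked
1	2	linear		0
1	7	linear		0
1	9	linear		0
1	10	linear		0
2	5	linear		0
2	6	linear		0
2	7	linear		0
3	1	linear		0
3	2	linear		0
3	5	linear		0
3	6	linear		0
4	1	linear		0
4	5	linear		0
4	8	linear		0
4	9	linear		0
5	3	linear		0
5	4	linear		0
6	1	linear		0
6	5	linear		0
6	7	linear		0
6	8	linear		0
7	2	linear		0
7	5	linear		0
7	10	linear		0
8	3	linear		0
8	5	linear		0
8	6	linear		0
9	4	linear		0
9	5	linear		0
10	9	linear		0
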