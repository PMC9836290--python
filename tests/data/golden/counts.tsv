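contig	position	C1	C2	C3	T2	T3	T4
chr1	140	10	12	4	16	26	60
chr1	150	2	1	2	0	1	2
chr1	200	7	8	5	12	16	40
chr1	260	5	6	3	15	20	52
chr1	320	20	22	9	30	45	90
chr1	380	15	17	6	8	12	24
chr1	440	4	5	7	2	7	18
chr1	500	6	7	8	11	14	33
chr1	680	9	11	25	5	9	7
chr1	900	30	33	30	25	31	16
chr1	950	12	14	40	6	10	5
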