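clade	strain	phiVPE25	phiVFW
1	D6	sensitive	sensitive
1	JH1	sensitive	sensitive
1	DS5	sensitive	sensitive
1	AR01/DG	sensitive	sensitive
1	T8	sensitive	sensitive
1	ATCC 29212	sensitive	sensitive
1	T2	sensitive	sensitive
1	T1	sensitive	sensitive
1	X98	sensitive	sensitive
1	Fly1	sensitive	sensitive
2	Merz96	sensitive	resistant
3	OG1RF	sensitive	resistant
3	HIP11704	sensitive	resistant
4	V583	sensitive	sensitive
4	T11	sensitive	sensitive
5	T3	resistant	sensitive
5	CH188	resistant	sensitive
5	ATCC 4200	resistant	sensitive
5	E1Sol	resistant	sensitive
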