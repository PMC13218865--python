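# Acceptor (3') splice-site weight matrix, 14-mer: eight pyrimidine-tract
# positions (-12..-5), one weakly constrained position (-4), the -3 C, the
# invariant AG dinucleotide (-2,-1) and two exonic bases (+1,+2).
# Per-position weights follow Shapiro-Senapathy consensus base frequencies
# (percent), with the invariant AG dinucleotide doubly weighted so that
# core-site presence dominates the consensus value.
POS	A	C	G	T
-12	9.0	30.5	12.5	48.0
-11	8.5	31.0	11.0	49.5
-10	7.5	32.5	10.5	49.5
-9	6.5	33.0	10.0	50.5
-8	9.5	37.0	9.0	44.5
-7	7.0	38.5	8.5	46.0
-6	7.5	41.0	6.5	45.0
-5	6.0	40.5	7.5	46.0
-4	23.0	28.0	26.0	23.0
-3	4.0	74.5	1.0	20.5
-2	200.0	0.0	0.0	0.0
-1	0.0	0.0	200.0	0.0
1	25.0	14.0	49.0	12.0
2	27.0	20.0	28.0	25.0
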