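# Donor (5') splice-site weight matrix, 9-mer: exonic -3..-1, intronic +1..+6.
# Per-position weights follow Shapiro-Senapathy consensus base frequencies
# (percent), with the invariant GT dinucleotide doubly weighted so that
# core-site presence dominates the consensus value.  Consensus CAGGTAAGT.
# POS is the biological offset (no position 0).
POS	A	C	G	T
-3	32.8	36.1	18.3	12.8
-2	60.4	12.9	12.5	14.2
-1	9.2	3.3	80.3	7.3
1	0.0	0.0	200.0	0.0
2	0.0	0.0	0.0	200.0
3	52.6	2.8	41.9	2.5
4	71.3	7.6	11.8	9.3
5	7.1	5.5	81.4	6.0
6	16.0	16.5	22.2	45.3
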