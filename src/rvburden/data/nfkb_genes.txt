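# Default curated NF-kB pathway gene set (63 symbols): canonical and
# non-canonical core components plus upstream receptors, adaptors and
# modulators.  Supply your own one-symbol-per-line file to override.
NFKB1
NFKB2
RELA
RELB
REL
NFKBIA
NFKBIB
NFKBIE
CHUK
IKBKB
IKBKE
IKBKG
TBK1
TLR1
TLR2
TLR3
TLR4
TLR5
TLR6
TLR7
TLR8
TLR9
TLR10
TNF
TNFRSF1A
TNFRSF1B
TNFRSF11A
TNFRSF12A
TNFRSF13C
TNFAIP3
TNFSF11
TNFSF12
TNFSF13B
LTA
LTB
LTBR
FAS
FASLG
TRAF1
TRAF2
TRAF3
TRAF5
TRAF6
MYD88
IRAK1
IRAK4
TIRAP
TICAM1
TRADD
RIPK1
MAP3K7
MAP3K14
TAB1
TAB2
CARD11
BCL10
MALT1
CYLD
OTULIN
TNIP1
NLRP3
CASP8
NOD2
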