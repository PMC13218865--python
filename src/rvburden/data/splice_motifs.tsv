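# Default exonic/intronic splicing regulatory motif exemplars.
# ESE: purine-rich SR-protein-style hexamers (RESCUE-ESE-like exemplars).
# ESS: hnRNP-A1-style UAGGG-core hexamers.  ISE/ISS: small intronic exemplars.
# The sets are pluggable; substitute curated databases for production scans.
CLASS	MOTIF
ESE	GAAGAA
ESE	AAGAAG
ESE	GAAGGA
ESE	TGAAGA
ESE	GATGAA
ESE	CAGAAG
ESE	GAAGAT
ESS	TAGGGA
ESS	TAGGGT
ESS	TTAGGG
ESS	GTAGGG
ISE	GGGTGG
ISE	TGGGGG
ISS	CCTCCC
ISS	TCCTCC
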