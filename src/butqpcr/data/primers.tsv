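# Degenerate qPCR primer panel for the but gene, one pair per phylogenetic
# cluster A-F. Sequences 5'->3'; expected product length in nt.
cluster	fwd	rev	expected_len
A	MCTGGGYATYCACACCGAG	GGTGGGCGATGGAGATAA	574
B	GGKCCBATHGARRTTGCAGA	TKTCGTCMASCCABTCATAC	679
C	GBGACTGGSTRGATTAYG	TCVACRTACATYTCSGTGTG	682
D	TGGAAYTCMTGGCATATGTC	VGMRTTGTTRATGGAMATAAA	726
E	TGHAGSABHTSWTTTTACATGGA	SSCTTTGCAATGTCAACAAA	558
F	AAATATGCCTCGHTGCYTWG	ARRTARGCACCYAWAACGAAATC	585
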