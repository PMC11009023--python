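TAGAGTGG
TTAGCACC
TGATTTCG
TTAAGGAT
TAATTTAG
TCACAATG
AGGGCCGG
GGCGAACT
AAATTCAG
GAGTGACC
CCGGTGGT
TAGCGTTT
CCCATGCG
TACACATA
GTGTGAAT
AACGCCAA
CTGTAGTA
AATGAGCA
TGGAAGGT
GTAGACTC
CTTTCGAA
GCTCACTA
AGTTACCA
CGAAGCTA
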