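GCTAGACTC
GAAGGCTACA
ACGTTAAATG
GCGCCTCC
AGTTCGTATT
AACTGGGTCT
GAGTGTACT
CATCGAGATG
ACGTATCAAAG
GGATTACTGTTT
CCTCTTTGAGC
CCTACATCTCA
TCTCAACC
CACCGTGCT
TATGGGGA
TTCTGGCTGCGC
ACGGGCAAG
CTCCTGACCTCG
GAATTTAGAAG
AATTACCGTGC
ACAAATCAC
TTCTCGCAGAG
AAGCATACGCG
CTGCGTTCCCA
GGCCCGGTTTT
GAGGTTACGT
TTTGCAGCGTC
CGGACCGGTGTG
CAAGATTTT
TTTGGAGAT
GGGGACTAACG
CTTTTTAG
ACTTGCCTA
CTTACGGACC
AACTTCCG
GCGGCAGGC
AATAGGACG
TCCGGCGAATAA
TGATTAGGCTCT
CATCATACT
AGATGCTC
AATTTCTT
CTTCTGTTA
GGCTGGTTA
CGGAGTTCA
GAGCCAACCGA
CAAAACCCCG
TCCGAAAAGA
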