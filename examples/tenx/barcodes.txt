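TGACCCTCTCGAGCTG
CCCGTCTCTTAGGGAC
GGAAGGTTCGCAGTAC
CGTAGTTCGTGTGACC
GACGTTAAATTATGTA
AGGCGCCAAACGGGCC
GATTTGACTGAGTTAA
AACACGCAGCTTCCCC
CAGACTTGTTCGAGCG
TAACCCCGGATCGAGA
ACTCGGGAGGGCGGGG
CAAGGAAGATGCCAGC
CCAGTGTACGTCGGGC
ACTAGCCCGTGAGAAA
TATCCAGATTAAGCAG
CAGCCTAGTGCCGGCC
GAGGCAATAGTGAGAC
GTAAGCCAAGCTGGAT
GCGCGAGAACCGACGG
TGTCATCTGGAGATCG
GTATATTAGCCTGGCC
TTGCACGGGTACAACA
TTGTGGTCGGATCGCC
TGGACGGTCTGTCCAA
AGTACTGAGACAGGTT
AGGCGTGCCTAGTGGA
CCGATATCATCAGGCA
GCGCTCGAGTCATGAT
GCGTAGGTGGTTTAAC
GATTGCCAACGACTCA
TGTTAGATACACCGGC
CAAAACAGTTACTGGT
ACTGTGCACCATTCTG
CGGCATACCCACCGGA
GGCCACCTTCACATCG
ATTATGCGGTAAGTCC
CACTGCACAATGCCCG
TGGTGAGGACGCGACA
TCGCATTCTTCTGATA
CAACTACCTGCCTGCG
ACTAGATTGGTTGCGA
TCATCGGCGAACTCTT
TCTGTACAGCTTTCTA
TATCATCGACTTACAT
CGTTCTACCATGGGGG
AACTCCAAAAGCTCCG
CCGCTATTGGTCACGG
TGTACCCATTGTTAAT
TATAAATGTGTAGCGT
GCTCTATGGGTGATAC
TCCTCGGGTACACCTA
ACTTCCGTCGTCCCAT
CCTGCAGTCGGTGTTC
CGGCAGCTGGTCTGCT
GGAAGACATCACTGTC
TTGCTTCATGGTACCC
TGACGCGGGAACGCTA
AGATATGCACGTAGAG
AACTCACTGTATTCCT
TACCTCCGTACATGTT
TGAGAGCGGTAATCCG
AGAGCCAGCTCCCTGC
GAGAACGTAAACATAG
TCAATGAGTGCAGGGC
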