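TAGGAGCA
AAGGAACC
TAGACACT
ATCTTAGG
CGTCGAAT
TTATCATC
GACTAAAC
TATATCGT
GATAGAAT
CGCTAACG
ACATCGGA
CAAGCACG
CCTGGACA
GTGCGAGG
TTTGTATG
AGACTGAG
TGGGGTCC
CGCGTACT
CACACATC
CCCGATAT
TTAGGACC
AATAGCGA
GGGTATGC
AACAATGA
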