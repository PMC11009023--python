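assay_id: toy-indrops
name: Variable-barcode scRNA-seq (synthetic)
modalities:
- rna
seqspec_version: 0.1.0
library_spec:
- region_id: rna
  region_type: rna
  name: rna
  sequence_type: joined
  sequence: GCATGGCCTGGAGAGCAATGAGACGCGTTNNNNNNNNNNNNXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXCAACGCACATCCGGCCAGCGATTT
  min_len: 127
  max_len: 161
  onlist: null
  regions:
  - region_id: p5
    region_type: illumina_p5
    name: p5
    sequence_type: fixed
    sequence: GCATGGCCTGGAGAGCAATGAGACGCGTT
    min_len: 29
    max_len: 29
    onlist: null
    regions: []
  - region_id: read1
    region_type: fastq
    name: Read 1
    sequence_type: joined
    sequence: NNNNNNNNNNNNXXXXXX
    min_len: 14
    max_len: 18
    onlist: null
    regions:
    - region_id: barcode1
      region_type: barcode
      name: variable cell barcode
      sequence_type: onlist
      sequence: ''
      min_len: 8
      max_len: 12
      onlist:
        filename: barcodes_var.txt
        location: local
        md5: f99aa7d30229ed6961d0405bd247ef2d
      regions: []
    - region_id: umi
      region_type: umi
      name: molecular identifier
      sequence_type: random
      sequence: ''
      min_len: 6
      max_len: 6
      onlist: null
      regions: []
  - region_id: read2
    region_type: fastq
    name: Read 2
    sequence_type: joined
    sequence: XXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXX
    min_len: 60
    max_len: 90
    onlist: null
    regions:
    - region_id: cdna
      region_type: cdna
      name: complementary DNA
      sequence_type: random
      sequence: ''
      min_len: 60
      max_len: 90
      onlist: null
      regions: []
  - region_id: p7
    region_type: illumina_p7
    name: p7
    sequence_type: fixed
    sequence: CAACGCACATCCGGCCAGCGATTT
    min_len: 24
    max_len: 24
    onlist: null
    regions: []
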