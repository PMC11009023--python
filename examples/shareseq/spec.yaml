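assay_id: toy-shareseq
name: Two-modality split-pool assay (synthetic)
modalities:
- rna
- atac
seqspec_version: 0.1.0
library_spec:
- region_id: rna
  region_type: rna
  name: rna
  sequence_type: joined
  sequence: TGCTCTCCTGCATTACCGCTTTAAACACGNNNNNNNNNNNNNNNNXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXGTTAGGAATCCCCGGATTTGTCCA
  min_len: 129
  max_len: 129
  onlist: null
  regions:
  - region_id: rna_p5
    region_type: illumina_p5
    name: rna_p5
    sequence_type: fixed
    sequence: TGCTCTCCTGCATTACCGCTTTAAACACG
    min_len: 29
    max_len: 29
    onlist: null
    regions: []
  - region_id: rna_read1
    region_type: fastq
    name: Read 1
    sequence_type: joined
    sequence: NNNNNNNNNNNNNNNNXXXXXXXXXX
    min_len: 26
    max_len: 26
    onlist: null
    regions:
    - region_id: rna_bc_round1
      region_type: barcode
      name: round 1 barcode
      sequence_type: onlist
      sequence: ''
      min_len: 8
      max_len: 8
      onlist:
        filename: round1.txt
        location: local
        md5: d6cbe88c151a15e8ed5adf5c61555e52
      regions: []
    - region_id: rna_bc_round2
      region_type: barcode
      name: round 2 barcode
      sequence_type: onlist
      sequence: ''
      min_len: 8
      max_len: 8
      onlist:
        filename: round2.txt
        location: local
        md5: 2a10d850a431d2fe656c6ee53fa4142d
      regions: []
    - region_id: rna_umi
      region_type: umi
      name: molecular identifier
      sequence_type: random
      sequence: ''
      min_len: 10
      max_len: 10
      onlist: null
      regions: []
  - region_id: rna_read2
    region_type: fastq
    name: Read 2
    sequence_type: joined
    sequence: XXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXX
    min_len: 50
    max_len: 50
    onlist: null
    regions:
    - region_id: rna_insert
      region_type: cdna
      name: biological insert
      sequence_type: random
      sequence: ''
      min_len: 50
      max_len: 50
      onlist: null
      regions: []
  - region_id: rna_p7
    region_type: illumina_p7
    name: rna_p7
    sequence_type: fixed
    sequence: GTTAGGAATCCCCGGATTTGTCCA
    min_len: 24
    max_len: 24
    onlist: null
    regions: []
- region_id: atac
  region_type: atac
  name: atac
  sequence_type: joined
  sequence: AGCCTTGAAGGCCGCCATGCTCAGTTAGGNNNNNNNNNNNNNNNNXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXAGAAAGTTACCATTTAAACGACCA
  min_len: 129
  max_len: 129
  onlist: null
  regions:
  - region_id: atac_p5
    region_type: illumina_p5
    name: atac_p5
    sequence_type: fixed
    sequence: AGCCTTGAAGGCCGCCATGCTCAGTTAGG
    min_len: 29
    max_len: 29
    onlist: null
    regions: []
  - region_id: atac_read1
    region_type: fastq
    name: Read 1
    sequence_type: joined
    sequence: NNNNNNNNNNNNNNNNXXXXXXXXXX
    min_len: 26
    max_len: 26
    onlist: null
    regions:
    - region_id: atac_bc_round1
      region_type: barcode
      name: round 1 barcode
      sequence_type: onlist
      sequence: ''
      min_len: 8
      max_len: 8
      onlist:
        filename: round1.txt
        location: local
        md5: d6cbe88c151a15e8ed5adf5c61555e52
      regions: []
    - region_id: atac_bc_round2
      region_type: barcode
      name: round 2 barcode
      sequence_type: onlist
      sequence: ''
      min_len: 8
      max_len: 8
      onlist:
        filename: round2.txt
        location: local
        md5: 2a10d850a431d2fe656c6ee53fa4142d
      regions: []
    - region_id: atac_umi
      region_type: umi
      name: molecular identifier
      sequence_type: random
      sequence: ''
      min_len: 10
      max_len: 10
      onlist: null
      regions: []
  - region_id: atac_read2
    region_type: fastq
    name: Read 2
    sequence_type: joined
    sequence: XXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXX
    min_len: 50
    max_len: 50
    onlist: null
    regions:
    - region_id: atac_insert
      region_type: gdna
      name: biological insert
      sequence_type: random
      sequence: ''
      min_len: 50
      max_len: 50
      onlist: null
      regions: []
  - region_id: atac_p7
    region_type: illumina_p7
    name: atac_p7
    sequence_type: fixed
    sequence: AGAAAGTTACCATTTAAACGACCA
    min_len: 24
    max_len: 24
    onlist: null
    regions: []
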