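assay_id: toy-tenx
name: Fixed-geometry droplet scRNA-seq (synthetic)
modalities:
- rna
seqspec_version: 0.1.0
library_spec:
- region_id: rna
  region_type: rna
  name: rna
  sequence_type: joined
  sequence: CTTGCGCGTCAATCTTATCTCGGCATATTNNNNNNNNNNNNNNNNXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXCACCGATTGCCCTCCTCAGTACTC
  min_len: 171
  max_len: 171
  onlist: null
  regions:
  - region_id: p5
    region_type: illumina_p5
    name: p5
    sequence_type: fixed
    sequence: CTTGCGCGTCAATCTTATCTCGGCATATT
    min_len: 29
    max_len: 29
    onlist: null
    regions: []
  - region_id: read1
    region_type: fastq
    name: Read 1
    sequence_type: joined
    sequence: NNNNNNNNNNNNNNNNXXXXXXXXXXXX
    min_len: 28
    max_len: 28
    onlist: null
    regions:
    - region_id: barcode
      region_type: barcode
      name: cell barcode
      sequence_type: onlist
      sequence: ''
      min_len: 16
      max_len: 16
      onlist:
        filename: barcodes.txt
        location: local
        md5: 2d93f9fe7056eda39934b5129da4a6a6
      regions: []
    - region_id: umi
      region_type: umi
      name: molecular identifier
      sequence_type: random
      sequence: ''
      min_len: 12
      max_len: 12
      onlist: null
      regions: []
  - region_id: read2
    region_type: fastq
    name: Read 2
    sequence_type: joined
    sequence: XXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXXX
    min_len: 90
    max_len: 90
    onlist: null
    regions:
    - region_id: cdna
      region_type: cdna
      name: complementary DNA
      sequence_type: random
      sequence: ''
      min_len: 90
      max_len: 90
      onlist: null
      regions: []
  - region_id: p7
    region_type: illumina_p7
    name: p7
    sequence_type: fixed
    sequence: CACCGATTGCCCTCCTCAGTACTC
    min_len: 24
    max_len: 24
    onlist: null
    regions: []
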