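# assayspec

Sequenced fragments from genomics assays share a common anatomy — sequencing
adapters flanking an insert of technical elements (cell barcodes, unique
molecular identifiers) and biological sequence (cDNA, genomic DNA) — yet
every assay arranges those elements differently, and the arrangement is
rarely recorded in a form software can use. `assayspec` defines a
machine-readable YAML format for that anatomy and ships a toolkit for
working with it: validation, coordinate extraction, barcode-whitelist
(onlist) handling, human-readable diagrams, and generation of the geometry
strings that single-cell RNA-seq preprocessors need.

It is aimed at people who preprocess sequencing data — pipeline authors who
need barcode/UMI offsets without reverse-engineering each kit, and data
generators who want to deposit an exact description of their library
structure alongside their reads.

## The model

A library molecule is an **ordered tree of regions**. An atomic region
carries sequence and has a `sequence_type` of `fixed` (literal nucleotides),
`onlist` (drawn from a finite list of permissible sequences), or `random`
(UMIs, inserts); a *meta* region has children and `sequence_type: joined` —
its sequence is the 5'→3' concatenation of its children. Every region
carries `min_len`/`max_len` in bases, so variable-length designs are
first-class. Flattening a modality's tree left to right gives the atomic
elements in sequencing order, and cumulative length sums give each element a
0-based half-open interval `[start, stop)`; when an upstream element is
variable, intervals carry min/max endpoints and are flagged non-fixed.
Regions of type `fastq` mark read containers, which is how a single 5'→3'
construct maps onto per-read tool coordinates.

## Worked example

Three small example workspaces ship under `examples/`. For the
fixed-geometry droplet-style spec (16 bp onlist barcode + 12 bp UMI in
read 1, 90 bp cDNA in read 2):

```sh
$ assayspec check examples/tenx/spec.yaml        # silent, exit 0: valid
$ assayspec index -m rna examples/tenx/spec.yaml
p5      0       29
barcode 29      45
umi     45      57
cdna    57      147
p7      147     171
```

Each line is `region_id  start  stop`, 0-based half-open, over the whole
171 bp construct: the barcode occupies bases 29–44 inclusive, right after
the 29 bp P5 adapter. The same layout as per-tool technology strings:

```sh
$ assayspec index -m rna -t kb examples/tenx/spec.yaml
0,0,16:0,16,28:1,0,0
$ assayspec index -m rna -t starsolo examples/tenx/spec.yaml
--soloCBstart 1 --soloCBlen 16 --soloUMIstart 17 --soloUMIlen 12
$ assayspec index -m rna -t simpleaf examples/tenx/spec.yaml
1{b[16]u[12]}2{r}
```

Coordinates are now read-relative: barcode `[0,16)` and UMI `[16,28)` in
read 1 (0-indexed for kb, 1-based for STARsolo), cDNA = the whole of read 2.
The variable-barcode example (`examples/indrops/`) fails these emitters by
design — an 8–12 bp barcode has no fixed offset — with a clear geometry
error, while `check`, `index` and `print` still work:

```sh
$ assayspec print -f ascii examples/indrops/spec.yaml
=== rna ===
        <-------read1-------> <--read2-->
|p5(29)|barcode1(8-12)|umi(6)|cdna(60-90)|p7(24)|
```

Other subcommands: `find` (region metadata), `format` (recompute meta-region
metadata from the leaves), `info` (JSON summary), `init` (build a spec from
a newick string, e.g. `-n "((bc:16,umi:12,cdna:90)rna)root;"`), `modify`
(edit attributes with automatic ancestor updates), `onlist` (resolve
barcode lists, including Cartesian products for split-pool designs),
`split` (one spec per modality), and `version`.

## Library use

```python
from assayspec import load_spec, check, index, emit

assay = load_spec("examples/tenx/spec.yaml")
assert check(assay, base_dir="examples/tenx") == []
print(emit(assay, "rna", "kb").text)   # 0,0,16:0,16,28:1,0,0
```

The `assayspec.fixtures` module generates synthetic specs, onlists, and
simulated FASTQ reads (seeded, byte-deterministic) for testing pipelines
without any downloads.

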