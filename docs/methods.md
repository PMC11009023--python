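# Methods

## The region tree

An assay document is a header plus one top-level region per modality (`rna`,
`atac`, ...); top-level region ids equal the modality names, in order. A
region is atomic (no children) or meta (children, `sequence_type: joined`).
Child order is significant everywhere and is preserved byte-for-byte through
read/write; traversal is pre-order (5'→3'), and ties cannot arise because
children form an ordered list. A meta region may mix atomic and meta
children. Zero-length regions (`min_len = max_len = 0`) are legal and
contribute empty intervals; this supports optional linkers.

Atomic invariants: `min_len <= max_len`; a `fixed` region's sequence is
concrete (no N/X) with `min_len = max_len = len(sequence)`; a `random`
region's sequence is empty or an all-`X` placeholder of `max_len`; an
`onlist` region must reference an onlist. Meta invariants: lengths are the
sums over children and the sequence is the concatenation of resolved child
sequences.

**Placeholder convention.** `resolve_joined` gives random children an
`X * max_len` placeholder so joined sequences have concrete text and round-trip
losslessly. Onlist children with no recorded sequence contribute
`N * max_len`: their realized sequence is data-dependent, and `N` (any base)
expresses that better than `X` (arbitrary filler) while keeping resolution
deterministic.

## Serialization

The canonical dialect is untagged block YAML, fixed key order, 2-space
indent; writes are byte-deterministic and `parse(write(a)) == a`. A tagged
dialect (`!Assay`/`!Region`/`!Onlist` node tags) is accepted on input only.
Unknown top-level keys are preserved in an auxiliary map; region-level
schema errors name the offending key and node path. Onlists are plain text
or gzip (members written with zeroed mtime for determinism), read fully into
memory — they are barcode-whitelist sized, not genome sized. The optional
`md5` covers the raw on-disk bytes, compressed form included.

The newick grammar for `init` is fixed here (the notation itself carries no
length units): leaves are `id:length` with integer base counts and become
random atomic regions; internal nodes are bare `id` meta regions; labels
must be unique; errors carry character offsets. The parser is a small
recursive-descent routine because general phylogenetic parsers neither
enforce integer lengths nor report offsets in this form.

## Validation

`check` collects *all* violations (no early exit), sorted by node path.
Severity is binary: everything is an error except `UNKNOWN_TYPE` — the
region-type vocabulary is deliberately open, so an unrecognised type warns
rather than blocks. The CLI exits nonzero only on error-severity findings.
Onlist length checks use the owning region's `[min_len, max_len]` interval,
accommodating variable-length barcode lists. File-backed checks
(existence, md5, content, lengths) run by default and are skipped with
`--skip-files` for specs that reference remote lists; remote onlists are
represented but never fetched.

## Indexing and tool strings

`index` walks a modality's leaves accumulating `(Σ min_len, Σ max_len)`;
each leaf's interval is `[cum_min, cum_min + min_len)` /
`[cum_max, cum_max + max_len)`, *fixed* iff the leaf and everything upstream
is fixed-length. Consecutive intervals tile the construct with no gaps. A
`subset` filter selects region types after layout, so filtering never shifts
coordinates.

Read containers are regions of `region_type: fastq`; they must be the
containers (usually meta regions) whose atomic descendants are the sequenced
elements, numbered 1..R in 5'→3' order, with offsets restarting at 0 per
read — this is how all supported tools address reads. Emitters require ≥1
barcode, exactly one UMI, and exactly one cDNA/gDNA leaf inside reads, all
barcode/UMI offsets fixed, and a fixed cDNA start within its read; the cDNA
itself may be variable because every dialect encodes it as "rest of read".
Dialect details (fixed by this package; upstream grammars drift across tool
versions): kb uses 0-based `read,start,stop` triplets with `stop = 0` for
"to end of read"; STARsolo uses 1-based starts (exactly kb start + 1) and
folds multiple barcodes into one CB block only when adjacent; simpleaf uses
per-read blocks with `b[]`/`u[]`/`x[]`/`r` tokens, `x[]` for fixed skips
before addressed elements, trailing unaddressed elements omitted. Emitters
live behind a registry so new dialects can be added without touching the
indexer.

## Rendering

The ASCII diagram is a banner per modality over a row of boxes, one per
leaf, labeled `id(len)` or `id(min-max)`; labels are truncated with `..`
beyond 20 characters, rows wrap at the configured width (minimum 40), and a
bracket line above the boxes marks read containers — the "read diagram" is
this annotated variant rather than a fourth format. Markdown emits one table
per modality (order, region_id, region_type, lengths, sequence); HTML wraps
the same tables in a minimal standalone page.

## Synthetic data

The fixture generator emits the canonical adapter-insert-adapter construct:
P5/P7-style fixed adapters flanking barcode/UMI/cDNA leaves (plus linkers at
higher leaf budgets) wrapped in two fastq read containers. Defaults: one
modality, three insert leaves, 16-sequence onlists, all-fixed lengths —
small enough to enumerate exhaustively, rich enough to exercise every code
path. `variable_fraction` makes eligible leaves variable with a range width
of 2–3 bases, chosen so the exhaustive length-assignment oracle stays
tractable while still covering the variable-barcode regime. Defect mode
breaks exactly one named invariant for validator mutation testing. All
randomness flows through one seeded `random.Random`; identical
configurations produce byte-identical workspaces.

The read simulator assumes perfect end-to-end sequencing of a perfectly
constructed library: onlist regions draw uniformly from their list, random
regions are uniform A/C/G/T with length uniform on `[min_len, max_len]`,
fixed regions appear verbatim; molecules are sliced into FASTQ records at
read-container boundaries, with optional independent per-base substitutions
(no indels — substitutions suffice to exercise extraction logic) and
constant `I` (Phred 40) qualities. Real data differ in ways the simulator
deliberately ignores: quality-dependent error profiles, indels, PCR
duplicates, chimeric molecules, and adapter read-through. Passing tests
therefore demonstrate correctness of coordinate bookkeeping and extraction,
not robustness to real-world noise.

With a 16 bp barcode and per-base substitution rate p = 0.01, the probability
a read's barcode leaves its onlist is ≈ 1 − 0.99^16 ≈ 0.149 (exactly so when
no corrupted barcode collides with another list member; with 64 random
16-mers the collision probability is negligible). The simulation checks
measure this fraction over 10,000 molecules and compare within 3 binomial
standard errors.

## Problem sizes and numerical choices

Test and acceptance workloads use 200 random specs for round-trip checks,
100 trees (≤ 8 leaves, per-leaf range width ≤ 3) for the
enumerate-all-assignments indexing oracle, 25 fixtures per defect class for
mutation testing, and 10,000 simulated molecules for recovery — sizes at
which the exhaustive oracles are exact and the whole suite runs in seconds.
Determinism is absolute (seeded generators, no global random state, zeroed
gzip mtimes), so re-runs are byte-identical.

## Known limitations

Single-strand view only (no reverse-complement rendering); no streaming
onlist reads; remote onlists unresolved by design; tool-string grammars
track one fixed dialect per tool rather than historical versions; `modify`
re-runs formatting after every edit — deliberate, since silently
inconsistent ancestors are worse than implicit recomputation.
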