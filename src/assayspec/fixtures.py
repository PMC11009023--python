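"""Synthetic assay specs, onlists, and simulated reads.

Everything other modules need for testing is generated here, with no
downloads: the canonical adapter-insert-adapter construct (sequencing
adapters flanking an insert of barcode/UMI/cDNA elements wrapped in fastq
read containers), barcode onlists, and idealized reads — perfect end-to-end
sequencing of a perfectly constructed library, optionally perturbed by
independent per-base substitutions.

Three representative hand-built specs are exposed:

* :func:`build_tenx_like` — fixed-length geometry (16 bp onlist barcode +
  12 bp UMI in read 1, 90 bp cDNA in read 2), the TOY1 workhorse;
* :func:`build_indrops_like` — a variable-length (8-12 bp) barcode, which
  fixed-offset technology strings cannot express;
* :func:`build_shareseq_like` — two modalities (rna + atac) with split-pool
  adjacent barcodes, each with its own onlist.

All randomness flows through a single seeded ``random.Random``; identical
seed + config produce byte-identical workspaces (gzip members are written
with a zeroed mtime).
"""

from __future__ import annotations

import copy
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import io as _io
from .exceptions import ConfigError, OnlistError
from .model import (
    Assay,
    Onlist,
    Region,
    SequenceType,
    get_modality,
    leaves,
    walk,
)
from .ops import format_assay
from .validate import DEFECT_CODES

_BASES = "ACGT"
_MODALITY_NAMES = ("rna", "atac", "tag")


def _random_seq(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(_BASES) for _ in range(length))


def _unique_seqs(rng: random.Random, n: int, min_len: int, max_len: int) -> list[str]:
    out: list[str] = []
    seen = set()
    while len(out) < n:
        s = _random_seq(rng, rng.randint(min_len, max_len))
        if s not in seen:
            seen.add(s)
            out.append(s)
    return out


# ---------------------------------------------------------------------------
# Hand-built representative specs
# ---------------------------------------------------------------------------


def _adapter(rid: str, rtype: str, seq: str) -> Region:
    return Region(
        region_id=rid,
        region_type=rtype,
        name=rid,
        sequence_type=SequenceType.FIXED,
        sequence=seq,
        min_len=len(seq),
        max_len=len(seq),
    )


def build_tenx_like(workspace: Union[str, Path]) -> Assay:
    """Fixed-geometry droplet-style spec (TOY1) with its onlist on disk.

    rna = p5 adapter, read1 = barcode(16, onlist barcodes.txt) + umi(12),
    read2 = cdna(90), p7 adapter.
    """
    workspace = Path(workspace)
    workspace.mkdir(parents=True, exist_ok=True)
    rng = random.Random(20240)
    onlist = _io.write_onlist(
        _unique_seqs(rng, 64, 16, 16), workspace / "barcodes.txt"
    )
    barcode = Region(
        region_id="barcode",
        region_type="barcode",
        name="cell barcode",
        sequence_type=SequenceType.ONLIST,
        min_len=16,
        max_len=16,
        onlist=onlist,
    )
    umi = Region(
        region_id="umi",
        region_type="umi",
        name="molecular identifier",
        sequence_type=SequenceType.RANDOM,
        min_len=12,
        max_len=12,
    )
    cdna = Region(
        region_id="cdna",
        region_type="cdna",
        name="complementary DNA",
        sequence_type=SequenceType.RANDOM,
        min_len=90,
        max_len=90,
    )
    read1 = Region(
        region_id="read1",
        region_type="fastq",
        name="Read 1",
        sequence_type=SequenceType.JOINED,
        regions=[barcode, umi],
    )
    read2 = Region(
        region_id="read2",
        region_type="fastq",
        name="Read 2",
        sequence_type=SequenceType.JOINED,
        regions=[cdna],
    )
    rna = Region(
        region_id="rna",
        region_type="rna",
        name="rna",
        sequence_type=SequenceType.JOINED,
        regions=[
            _adapter("p5", "illumina_p5", _random_seq(rng, 29)),
            read1,
            read2,
            _adapter("p7", "illumina_p7", _random_seq(rng, 24)),
        ],
    )
    assay = format_assay(
        Assay(
            assay_id="toy-tenx",
            name="Fixed-geometry droplet scRNA-seq (synthetic)",
            modalities=["rna"],
            seqspec_version="0.1.0",
            library_spec=[rna],
        )
    )
    _io.save_spec(assay, workspace / "spec.yaml")
    return assay


def build_indrops_like(workspace: Union[str, Path]) -> Assay:
    """Variable-barcode spec (TOY2): barcode 8-12 bp, so downstream offsets
    are not fixed — the design fixed-offset technology strings reject."""
    workspace = Path(workspace)
    workspace.mkdir(parents=True, exist_ok=True)
    rng = random.Random(20241)
    onlist = _io.write_onlist(
        _unique_seqs(rng, 48, 8, 12), workspace / "barcodes_var.txt"
    )
    barcode1 = Region(
        region_id="barcode1",
        region_type="barcode",
        name="variable cell barcode",
        sequence_type=SequenceType.ONLIST,
        min_len=8,
        max_len=12,
        onlist=onlist,
    )
    umi = Region(
        region_id="umi",
        region_type="umi",
        name="molecular identifier",
        sequence_type=SequenceType.RANDOM,
        min_len=6,
        max_len=6,
    )
    cdna = Region(
        region_id="cdna",
        region_type="cdna",
        name="complementary DNA",
        sequence_type=SequenceType.RANDOM,
        min_len=60,
        max_len=90,
    )
    read1 = Region(
        region_id="read1",
        region_type="fastq",
        name="Read 1",
        sequence_type=SequenceType.JOINED,
        regions=[barcode1, umi],
    )
    read2 = Region(
        region_id="read2",
        region_type="fastq",
        name="Read 2",
        sequence_type=SequenceType.JOINED,
        regions=[cdna],
    )
    rna = Region(
        region_id="rna",
        region_type="rna",
        name="rna",
        sequence_type=SequenceType.JOINED,
        regions=[
            _adapter("p5", "illumina_p5", _random_seq(rng, 29)),
            read1,
            read2,
            _adapter("p7", "illumina_p7", _random_seq(rng, 24)),
        ],
    )
    assay = format_assay(
        Assay(
            assay_id="toy-indrops",
            name="Variable-barcode scRNA-seq (synthetic)",
            modalities=["rna"],
            seqspec_version="0.1.0",
            library_spec=[rna],
        )
    )
    _io.save_spec(assay, workspace / "spec.yaml")
    return assay


def build_shareseq_like(workspace: Union[str, Path]) -> Assay:
    """Two-modality split-pool spec (TOY3): rna + atac, each with two
    adjacent onlist barcodes sharing the split-pool round lists."""
    workspace = Path(workspace)
    workspace.mkdir(parents=True, exist_ok=True)
    rng = random.Random(20242)
    round1 = _io.write_onlist(_unique_seqs(rng, 24, 8, 8), workspace / "round1.txt")
    round2 = _io.write_onlist(_unique_seqs(rng, 24, 8, 8), workspace / "round2.txt")

    def modality_tree(m: str, insert_type: str) -> Region:
        bc1 = Region(
            region_id=f"{m}_bc_round1",
            region_type="barcode",
            name="round 1 barcode",
            sequence_type=SequenceType.ONLIST,
            min_len=8,
            max_len=8,
            onlist=copy.deepcopy(round1),
        )
        bc2 = Region(
            region_id=f"{m}_bc_round2",
            region_type="barcode",
            name="round 2 barcode",
            sequence_type=SequenceType.ONLIST,
            min_len=8,
            max_len=8,
            onlist=copy.deepcopy(round2),
        )
        umi = Region(
            region_id=f"{m}_umi",
            region_type="umi",
            name="molecular identifier",
            sequence_type=SequenceType.RANDOM,
            min_len=10,
            max_len=10,
        )
        insert = Region(
            region_id=f"{m}_insert",
            region_type=insert_type,
            name="biological insert",
            sequence_type=SequenceType.RANDOM,
            min_len=50,
            max_len=50,
        )
        read1 = Region(
            region_id=f"{m}_read1",
            region_type="fastq",
            name="Read 1",
            sequence_type=SequenceType.JOINED,
            regions=[bc1, bc2, umi],
        )
        read2 = Region(
            region_id=f"{m}_read2",
            region_type="fastq",
            name="Read 2",
            sequence_type=SequenceType.JOINED,
            regions=[insert],
        )
        return Region(
            region_id=m,
            region_type=m,
            name=m,
            sequence_type=SequenceType.JOINED,
            regions=[
                _adapter(f"{m}_p5", "illumina_p5", _random_seq(rng, 29)),
                read1,
                read2,
                _adapter(f"{m}_p7", "illumina_p7", _random_seq(rng, 24)),
            ],
        )

    assay = format_assay(
        Assay(
            assay_id="toy-shareseq",
            name="Two-modality split-pool assay (synthetic)",
            modalities=["rna", "atac"],
            seqspec_version="0.1.0",
            library_spec=[modality_tree("rna", "cdna"), modality_tree("atac", "gdna")],
        )
    )
    _io.save_spec(assay, workspace / "spec.yaml")
    return assay


# ---------------------------------------------------------------------------
# Random fixture generator
# ---------------------------------------------------------------------------


@dataclass
class FixtureConfig:
    """Parameters of the random spec generator.

    ``leaves_per_modality`` counts insert leaves (barcode/umi/cdna plus
    linkers); flanking adapters are added on top. ``variable_fraction`` is
    the probability that an eligible insert leaf gets a variable length
    (range width 2-3). ``defect``, when set to one of the validation codes,
    breaks exactly that invariant in the emitted spec.
    """

    seed: int = 0
    n_modalities: int = 1
    leaves_per_modality: int = 3
    variable_fraction: float = 0.0
    onlist_size: int = 16
    defect: Optional[str] = None
    gzip_onlists: bool = False

    def validate(self) -> None:
        if not 1 <= self.n_modalities <= 3:
            raise ConfigError("n_modalities must be in 1..3")
        if not 2 <= self.leaves_per_modality <= 8:
            raise ConfigError("leaves_per_modality must be in 2..8")
        if not 0.0 <= self.variable_fraction <= 1.0:
            raise ConfigError("variable_fraction must be a probability")
        if self.onlist_size < 1:
            raise ConfigError("onlist_size must be positive")
        if self.defect is not None and self.defect not in DEFECT_CODES:
            raise ConfigError(
                f"unknown defect {self.defect!r}; have {DEFECT_CODES}"
            )


@dataclass
class Fixture:
    assay: Assay
    workspace: Path
    onlists: dict = field(default_factory=dict)  # region_id -> Path


def _insert_roles(n: int) -> list[str]:
    """Insert leaf roles for a budget of n leaves, 5'->3'."""
    base = ["barcode", "umi", "cdna"] if n >= 3 else ["barcode", "cdna"]
    extras = ["linker" if i % 2 == 0 else "barcode" for i in range(n - len(base))]
    return ["barcode"] + extras + base[1:] if extras else base


def _make_leaf(
    rng: random.Random,
    rid: str,
    role: str,
    variable_fraction: float,
) -> Region:
    variable = rng.random() < variable_fraction
    if role == "barcode":
        length = rng.choice([8, 10, 12, 16])
        delta = rng.randint(1, 2) if variable else 0
        return Region(
            region_id=rid,
            region_type="barcode",
            name=rid,
            sequence_type=SequenceType.ONLIST,
            min_len=length - delta,
            max_len=length,
        )
    if role == "umi":
        length = rng.choice([8, 10, 12])
        delta = rng.randint(1, 2) if variable else 0
        return Region(
            region_id=rid,
            region_type="umi",
            name=rid,
            sequence_type=SequenceType.RANDOM,
            sequence="X" * length,
            min_len=length - delta,
            max_len=length,
        )
    if role == "linker":
        seq = _random_seq(rng, rng.randint(4, 8))
        return _adapter(rid, "linker", seq)
    # cdna
    length = rng.randint(60, 100)
    delta = rng.randint(1, 2) if variable else 0
    return Region(
        region_id=rid,
        region_type="cdna",
        name=rid,
        sequence_type=SequenceType.RANDOM,
        min_len=length - delta,
        max_len=length,
    )


def make_fixture(cfg: FixtureConfig, out_dir: Union[str, Path]) -> Fixture:
    """Generate a workspace: spec.yaml plus onlist files, valid by
    construction unless ``cfg.defect`` asks for a specific broken invariant.
    """
    cfg.validate()
    rng = random.Random(cfg.seed)
    workspace = Path(out_dir)
    workspace.mkdir(parents=True, exist_ok=True)

    onlists: dict[str, Path] = {}
    tops: list[Region] = []
    modalities = list(_MODALITY_NAMES[: cfg.n_modalities])
    for m in modalities:
        roles = _insert_roles(cfg.leaves_per_modality)
        counts: dict[str, int] = {}
        insert: list[Region] = []
        for role in roles:
            counts[role] = counts.get(role, 0) + 1
            rid = f"{m}_{role}_{counts[role]}"
            insert.append(_make_leaf(rng, rid, role, cfg.variable_fraction))
        for leaf in insert:
            if leaf.sequence_type is SequenceType.ONLIST:
                suffix = ".txt.gz" if cfg.gzip_onlists else ".txt"
                path = workspace / f"{leaf.region_id}_onlist{suffix}"
                leaf.onlist = _io.write_onlist(
                    _unique_seqs(rng, cfg.onlist_size, leaf.min_len, leaf.max_len),
                    path,
                    compress=cfg.gzip_onlists,
                )
                onlists[leaf.region_id] = path
        read1 = Region(
            region_id=f"{m}_read1",
            region_type="fastq",
            name="Read 1",
            sequence_type=SequenceType.JOINED,
            regions=insert[:-1],
        )
        read2 = Region(
            region_id=f"{m}_read2",
            region_type="fastq",
            name="Read 2",
            sequence_type=SequenceType.JOINED,
            regions=[insert[-1]],
        )
        tops.append(
            Region(
                region_id=m,
                region_type=m if m in ("rna", "atac", "tag") else "custom",
                name=m,
                sequence_type=SequenceType.JOINED,
                regions=[
                    _adapter(f"{m}_p5", "illumina_p5", _random_seq(rng, 29)),
                    read1,
                    read2,
                    _adapter(f"{m}_p7", "illumina_p7", _random_seq(rng, 24)),
                ],
            )
        )
    assay = format_assay(
        Assay(
            assay_id=f"fixture-{cfg.seed}",
            name=f"synthetic fixture (seed {cfg.seed})",
            modalities=modalities,
            seqspec_version="0.1.0",
            library_spec=tops,
        )
    )

    if cfg.defect is not None:
        _inject_defect(assay, cfg.defect, workspace)

    _io.save_spec(assay, workspace / "spec.yaml")
    return Fixture(assay=assay, workspace=workspace, onlists=onlists)


def _inject_defect(assay: Assay, defect: str, workspace: Path) -> None:
    """Break exactly one invariant of an otherwise valid document."""
    top = assay.library_spec[0]
    lvs = leaves(top)
    barcodes = [l for l in lvs if l.region_type == "barcode"]
    adapters = [l for l in lvs if l.sequence_type is SequenceType.FIXED]
    if defect == "DUP_ID":
        lvs[-1].region_id = lvs[0].region_id
    elif defect == "LEN_ORDER":
        leaf = barcodes[0]
        leaf.min_len = leaf.max_len + 1
    elif defect == "FIXED_SEQ_LEN":
        adapters[0].sequence += "A"
    elif defect == "JOIN_MISMATCH":
        top.min_len += 1
    elif defect == "ONLIST_MISSING":
        barcodes[0].onlist = None
    elif defect == "ONLIST_LEN":
        ref = barcodes[0].onlist
        assert ref is not None
        seqs = _io.read_onlist(ref, base_dir=workspace)
        seqs.append("A" * (barcodes[0].max_len + 3))
        compress = ref.filename.endswith(".gz")
        barcodes[0].onlist = _io.write_onlist(
            seqs, workspace / ref.filename, compress=compress
        )
    elif defect == "MODALITY_MAP":
        top.region_id = top.region_id + "_x"
    elif defect == "UNKNOWN_TYPE":
        barcodes[0].region_type = "mystery_element"
    else:  # pragma: no cover - guarded by FixtureConfig.validate
        raise ConfigError(f"unknown defect {defect!r}")


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------


def simulate_reads(
    assay: Assay,
    modality: str,
    n: int,
    seed: int = 0,
    error_rate: float = 0.0,
    base_dir: Union[str, Path] = ".",
) -> dict[str, list[SeqRecord]]:
    """Simulate ``n`` molecules and slice them into per-read FASTQ records.

    Each molecule realizes every atomic region of the modality 5'->3':
    onlist regions draw uniformly from their list, random regions are uniform
    A/C/G/T with length uniform on [min_len, max_len], fixed regions are
    verbatim. The concatenated molecule is cut at fastq read-container
    boundaries; independent per-base substitutions are applied at
    ``error_rate``; qualities are constant 'I' (Phred 40).

    Returns ``{read_container_id: [SeqRecord, ...]}``.
    """
    rng = random.Random(seed)
    top = get_modality(assay, modality)
    containers = [r for r in walk(top) if r.region_type == "fastq"]
    owner: dict[int, str] = {}
    for c in containers:
        for leaf in leaves(c):
            if leaf is not c:
                owner[id(leaf)] = c.region_id
    lvs = leaves(top)
    onlist_cache: dict[int, list[str]] = {}
    for leaf in lvs:
        if leaf.sequence_type is SequenceType.ONLIST:
            if leaf.onlist is None:
                raise OnlistError(
                    f"region {leaf.region_id!r} needs a local onlist to simulate"
                )
            onlist_cache[id(leaf)] = _io.read_onlist(leaf.onlist, base_dir=base_dir)

    out: dict[str, list[SeqRecord]] = {c.region_id: [] for c in containers}
    for i in range(n):
        per_read: dict[str, list[str]] = {c.region_id: [] for c in containers}
        for leaf in lvs:
            if leaf.sequence_type is SequenceType.FIXED:
                seq = leaf.sequence
            elif leaf.sequence_type is SequenceType.ONLIST:
                seq = rng.choice(onlist_cache[id(leaf)])
            else:
                seq = _random_seq(rng, rng.randint(leaf.min_len, leaf.max_len))
            cid = owner.get(id(leaf))
            if cid is not None:
                per_read[cid].append(seq)
        for cid, chunks in per_read.items():
            seq = "".join(chunks)
            if error_rate > 0:
                chars = list(seq)
                for k in range(len(chars)):
                    if rng.random() < error_rate:
                        chars[k] = rng.choice(
                            [b for b in _BASES if b != chars[k]]
                        )
                seq = "".join(chars)
            rec = SeqRecord(
                Seq(seq),
                id=f"mol{i}",
                description=cid,
                letter_annotations={"phred_quality": [40] * len(seq)},
            )
            out[cid].append(rec)
    return out


def write_fastq(records: list[SeqRecord], path: Union[str, Path]) -> None:
    """Write records as 4-line Phred+33 FASTQ."""
    from Bio import SeqIO

    with open(path, "w", encoding="utf-8") as fh:
        SeqIO.write(records, fh, "fastq")
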