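"""Ordered-tree data model for sequencing-library structure.

A library molecule is described as an ordered tree of *regions*. An atomic
region carries sequence (a fixed adapter, a barcode drawn from an onlist, a
random UMI or cDNA insert); a *meta* region groups child regions whose
concatenation, in 5'->3' order, forms its own sequence. Child order is
significant everywhere: flattening the tree left to right yields the atomic
elements in the order they appear on the sequenced strand.

Coordinates derived from the tree are 0-based half-open intervals over the
concatenation of a modality's atomic regions.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator, Optional

from .exceptions import NotFoundError, StructureError

#: region_type values recognised without a validation warning. The vocabulary
#: is open: unknown values are legal but flagged as warnings so that new assay
#: designs remain expressible.
REGION_TYPES = frozenset(
    {
        "barcode",
        "umi",
        "cdna",
        "gdna",
        "illumina_p5",
        "illumina_p7",
        "truseq_read1",
        "truseq_read2",
        "index5",
        "index7",
        "fastq",
        "linker",
        "poly_A",
        "named_adapter",
        "custom",
        # modality roots
        "rna",
        "atac",
        "protein",
        "tag",
        "crispr",
    }
)


class SequenceType(str, Enum):
    """How an atomic region's sequence is determined.

    ``fixed``   -- the literal nucleotides are known (adapters, linkers).
    ``onlist``  -- drawn from a finite list of permissible sequences
                   (cell barcodes with a whitelist).
    ``random``  -- arbitrary nucleotides (UMIs, cDNA inserts).
    ``joined``  -- a meta region; the concatenation of its children.
    """

    FIXED = "fixed"
    ONLIST = "onlist"
    RANDOM = "random"
    JOINED = "joined"


@dataclass
class Onlist:
    """Reference to a file of permissible sequences, one per line.

    ``location`` is ``local`` (a path relative to the spec document) or
    ``remote`` (recorded but never fetched by this package). ``md5`` is an
    optional hex digest of the file's raw bytes.
    """

    filename: str
    location: str = "local"
    md5: Optional[str] = None


@dataclass
class Region:
    """One node of the library-structure tree.

    An atomic region has an empty ``regions`` list and a concrete
    ``sequence_type`` (fixed/onlist/random); a meta region has children and
    ``sequence_type`` joined. ``min_len``/``max_len`` are in bases;
    ``sequence`` uses A/C/G/T plus the placeholders N (onlist) and X (random).
    """

    region_id: str
    region_type: str = "custom"
    name: str = ""
    sequence_type: SequenceType = SequenceType.RANDOM
    sequence: str = ""
    min_len: int = 0
    max_len: int = 0
    onlist: Optional[Onlist] = None
    regions: list["Region"] = field(default_factory=list)

    @property
    def is_atomic(self) -> bool:
        return not self.regions

    @property
    def is_fixed_length(self) -> bool:
        return self.min_len == self.max_len


@dataclass
class Assay:
    """Document root: header metadata plus one top-level region per modality.

    Top-level region ids equal the modality names, in the same order.
    ``extra`` holds unknown top-level YAML keys so documents round-trip
    losslessly.
    """

    assay_id: str
    name: str = ""
    modalities: list[str] = field(default_factory=list)
    seqspec_version: str = "0.1.0"
    doi: Optional[str] = None
    date: Optional[str] = None
    description: Optional[str] = None
    library_spec: list[Region] = field(default_factory=list)
    extra: dict = field(default_factory=dict)


@dataclass
class Interval:
    """0-based half-open coordinate range of a region within its modality.

    Because upstream regions may have variable length, both endpoints carry a
    min and a max over all concrete length assignments; ``fixed`` is true iff
    the interval is the same in every realization (start_min == start_max and
    stop_min == stop_max).
    """

    region_id: str
    start_min: int
    start_max: int
    stop_min: int
    stop_max: int
    fixed: bool

    @property
    def min_width(self) -> int:
        return self.stop_min - self.start_min

    @property
    def max_width(self) -> int:
        return self.stop_max - self.start_max


# ---------------------------------------------------------------------------
# Pure tree operations
# ---------------------------------------------------------------------------


def walk(region: Region) -> Iterator[Region]:
    """Pre-order (5'->3') traversal of ``region`` and all descendants."""
    yield region
    for child in region.regions:
        yield from walk(child)


def walk_with_paths(region: Region, prefix: str = "") -> Iterator[tuple[str, Region]]:
    """Pre-order traversal yielding (slash-separated id path, region)."""
    path = f"{prefix}/{region.region_id}" if prefix else region.region_id
    yield path, region
    for child in region.regions:
        yield from walk_with_paths(child, path)


def leaves(region: Region) -> list[Region]:
    """All childless descendants in 5'->3' (left-to-right pre-order) order.

    A childless input region is its own single leaf.
    """
    if region.is_atomic:
        return [region]
    out: list[Region] = []
    for child in region.regions:
        out.extend(leaves(child))
    return out


def iter_regions(assay: Assay) -> Iterator[tuple[str, Region]]:
    """All regions in the document with their paths, modality by modality."""
    for top in assay.library_spec:
        yield from walk_with_paths(top)


def get_modality(assay: Assay, modality: str) -> Region:
    """The top-level region for ``modality``; raises if unknown."""
    if modality not in assay.modalities:
        raise NotFoundError(
            f"unknown modality {modality!r}; have {assay.modalities}"
        )
    for top in assay.library_spec:
        if top.region_id == modality:
            return top
    raise NotFoundError(f"modality {modality!r} has no top-level region")


def find_by_id(assay: Assay, region_id: str) -> Optional[Region]:
    """The unique region with ``region_id``, or None if absent."""
    for _, region in iter_regions(assay):
        if region.region_id == region_id:
            return region
    return None


def find_by_type(assay: Assay, modality: str, region_type: str) -> list[Region]:
    """All regions of ``region_type`` under ``modality`` in 5'->3' pre-order."""
    top = get_modality(assay, modality)
    return [r for r in walk(top) if r.region_type == region_type]


def _resolved_sequence(region: Region) -> str:
    """Concrete-or-placeholder sequence contributed to a joined parent."""
    if region.sequence:
        return region.sequence
    if region.sequence_type is SequenceType.RANDOM:
        return "X" * region.max_len
    if region.sequence_type is SequenceType.ONLIST:
        return "N" * region.max_len
    return region.sequence


def resolve_joined(region: Region) -> Region:
    """Recompute every meta region's sequence and lengths from its leaves.

    Returns a deep copy in which each meta region has sequence_type joined,
    sequence equal to the concatenation of its (resolved) children's
    sequences — random children contribute all-X, onlist children all-N
    placeholders of max_len — and min/max lengths equal to the sums over
    children. Leaves are untouched. Idempotent.
    """
    if region.is_atomic:
        if region.sequence_type is SequenceType.JOINED:
            raise StructureError(
                f"region {region.region_id!r}: sequence_type joined requires children"
            )
        return copy.deepcopy(region)
    resolved_children = [resolve_joined(c) for c in region.regions]
    out = copy.deepcopy(region)
    out.regions = resolved_children
    out.sequence_type = SequenceType.JOINED
    out.sequence = "".join(_resolved_sequence(c) for c in resolved_children)
    out.min_len = sum(c.min_len for c in resolved_children)
    out.max_len = sum(c.max_len for c in resolved_children)
    return out
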