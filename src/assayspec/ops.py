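"""Document operations: coordinate indexing, formatting, editing, splitting,
onlist resolution, and summaries.

Coordinates are 0-based half-open throughout. Because upstream regions may be
variable-length (e.g. inDropsv3-style barcodes), every interval carries both
the minimal and maximal realized endpoints; an interval is *fixed* only when
nothing upstream of it (nor the region itself) varies, which is what
downstream preprocessors need to rely on absolute offsets.
"""

from __future__ import annotations

import copy
import itertools
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

from . import __version__
from . import io as _io
from .exceptions import (
    NotFoundError,
    OnlistError,
    SchemaError,
    StructureError,
    UpdateRejectedError,
)
from .model import (
    Assay,
    Interval,
    Region,
    SequenceType,
    find_by_id,
    find_by_type,
    get_modality,
    leaves,
    resolve_joined,
)
from .validate import ERROR, check as _check


@dataclass
class IndexResult:
    """The 0-indexed layout of one modality's atomic regions, 5'->3'."""

    modality: str
    intervals: list[Interval] = field(default_factory=list)


def index(
    assay: Assay, modality: str, subset: Optional[list[str]] = None
) -> IndexResult:
    """Extract the 0-indexed position of every atomic region in a modality.

    Walks the leaves in 5'->3' order accumulating cumulative (min, max)
    offsets; each leaf's interval is ``[cum_min, cum_min + min_len)`` /
    ``[cum_max, cum_max + max_len)``, and is *fixed* iff the leaf and all
    upstream leaves have min_len == max_len. With ``subset``, only intervals
    whose region_type is listed are returned — coordinates are still computed
    against the full layout, so filtering never shifts positions.
    """
    top = get_modality(assay, modality)
    if not top.regions and top.sequence_type is SequenceType.JOINED:
        raise StructureError(f"modality {modality!r} has an empty region tree")
    result = IndexResult(modality=modality)
    cum_min = cum_max = 0
    upstream_fixed = True
    for leaf in leaves(top):
        fixed = upstream_fixed and leaf.is_fixed_length
        result.intervals.append(
            Interval(
                region_id=leaf.region_id,
                start_min=cum_min,
                start_max=cum_max,
                stop_min=cum_min + leaf.min_len,
                stop_max=cum_max + leaf.max_len,
                fixed=fixed,
            )
        )
        cum_min += leaf.min_len
        cum_max += leaf.max_len
        upstream_fixed = fixed
    if subset is not None:
        wanted = set(subset)
        by_id = {leaf.region_id: leaf for leaf in leaves(top)}
        result.intervals = [
            iv for iv in result.intervals if by_id[iv.region_id].region_type in wanted
        ]
    return result


def format_assay(assay: Assay) -> Assay:
    """Auto-populate meta-region metadata from the leaves (idempotent).

    Applies :func:`~assayspec.model.resolve_joined` to every top-level
    region; the header is untouched.
    """
    out = copy.deepcopy(assay)
    out.library_spec = [resolve_joined(t) for t in assay.library_spec]
    return out


_REGION_FIELDS = frozenset(
    {
        "region_id",
        "region_type",
        "name",
        "sequence_type",
        "sequence",
        "min_len",
        "max_len",
        "onlist",
    }
)


def modify(assay: Assay, region_id: str, updates: dict) -> Assay:
    """Return a new assay with one region's fields replaced.

    Meta-region metadata is recomputed afterwards (format is re-applied) so
    ancestors stay consistent; the input assay is never mutated. Updates that
    would break a document invariant are rejected with the corresponding
    violation code (DUP_ID, FIXED_SEQ_LEN, ...).
    """
    if find_by_id(assay, region_id) is None:
        raise NotFoundError(f"no region with id {region_id!r}")
    unknown = set(updates) - _REGION_FIELDS
    if unknown:
        raise SchemaError(f"unknown region field(s): {sorted(unknown)}")
    out = copy.deepcopy(assay)
    target = find_by_id(out, region_id)
    assert target is not None
    for key, value in updates.items():
        if key == "sequence_type" and not isinstance(value, SequenceType):
            value = SequenceType(value)
        setattr(target, key, value)
    out = format_assay(out)
    problems = [
        v for v in _check(out, resolve_files=False) if v.severity == ERROR
    ]
    if problems:
        first = problems[0]
        raise UpdateRejectedError(first.code, f"update rejected: {first}")
    return out


def split(assay: Assay) -> list[Assay]:
    """One single-modality assay per modality, header fields copied.

    Concatenating the outputs' library trees in the original modality order
    reconstructs the input document.
    """
    out = []
    for m in assay.modalities:
        sub = copy.deepcopy(assay)
        sub.modalities = [m]
        sub.library_spec = [copy.deepcopy(get_modality(assay, m))]
        out.append(sub)
    return out


def merge(assays: list[Assay]) -> Assay:
    """Inverse of :func:`split`: recombine single-modality assays."""
    if not assays:
        raise StructureError("nothing to merge")
    out = copy.deepcopy(assays[0])
    out.modalities = [m for a in assays for m in a.modalities]
    out.library_spec = [copy.deepcopy(t) for a in assays for t in a.library_spec]
    return out


def onlist_resolve(
    assay: Assay,
    modality: str,
    region_type: str,
    combine: str = "multifile",
    base_dir: Union[str, Path] = ".",
) -> Union[str, list[str]]:
    """Resolve the onlist(s) for all regions of a type under a modality.

    One matching region: its onlist path, verbatim. Several (split-pool
    designs): ``combine='multifile'`` returns the paths in 5'->3' order;
    ``combine='product'`` materializes the Cartesian concatenation — every
    ordered join of one sequence from each list, row-major in 5'->3' region
    order — into a new file next to the inputs and returns its path.
    """
    regions = [
        r for r in find_by_type(assay, modality, region_type) if r.onlist is not None
    ]
    if not regions:
        raise NotFoundError(
            f"no {region_type!r} region with an onlist under modality {modality!r}"
        )
    if len(regions) == 1:
        return regions[0].onlist.filename
    if combine == "multifile":
        return [r.onlist.filename for r in regions]
    if combine != "product":
        raise SchemaError(f"combine must be 'product' or 'multifile', got {combine!r}")
    if any(r.onlist.location != "local" for r in regions):
        raise OnlistError("cannot build a product onlist from remote lists")
    lists = [_io.read_onlist(r.onlist, base_dir=base_dir) for r in regions]
    out_path = Path(base_dir) / f"onlist_product_{modality}_{region_type}.txt"
    with open(out_path, "w", encoding="utf-8") as fh:
        for combo in itertools.product(*lists):
            fh.write("".join(combo) + "\n")
    return str(out_path)


@dataclass
class ModalityInfo:
    modality: str
    leaf_count: int
    min_len: int
    max_len: int


@dataclass
class AssayInfo:
    assay_id: str
    name: str
    modalities: list[str]
    seqspec_version: str
    description: Optional[str]
    per_modality: list[ModalityInfo]

    def to_dict(self) -> dict:
        d = {
            "assay_id": self.assay_id,
            "name": self.name,
            "modalities": self.modalities,
            "seqspec_version": self.seqspec_version,
            "per_modality": [vars(m) for m in self.per_modality],
        }
        if self.description is not None:
            d["description"] = self.description
        return d


def info(assay: Assay) -> AssayInfo:
    """Summary of the document: header fields plus per-modality leaf counts
    and total min/max lengths. An absent description stays absent (None),
    never the empty string."""
    per = []
    for m in assay.modalities:
        top = get_modality(assay, m)
        lvs = leaves(top)
        per.append(
            ModalityInfo(
                modality=m,
                leaf_count=len(lvs),
                min_len=sum(l.min_len for l in lvs),
                max_len=sum(l.max_len for l in lvs),
            )
        )
    return AssayInfo(
        assay_id=assay.assay_id,
        name=assay.name,
        modalities=list(assay.modalities),
        seqspec_version=assay.seqspec_version,
        description=assay.description or None,
        per_modality=per,
    )


_SEMVER_RE = re.compile(r"^\d+\.\d+\.\d+$")


def version(assay: Optional[Assay] = None) -> dict:
    """Tool version, plus the document's format version when one is given.

    A malformed document version is echoed verbatim with a warning rather
    than rejected."""
    out: dict = {"tool_version": __version__}
    if assay is not None:
        out["spec_version"] = assay.seqspec_version
        if not _SEMVER_RE.match(assay.seqspec_version):
            out["warnings"] = [
                f"seqspec_version {assay.seqspec_version!r} is not a semantic version"
            ]
    return out
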