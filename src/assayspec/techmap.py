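"""Technology-string emitters for read preprocessors.

A spec describes the whole 5'->3' library construct; preprocessing tools
address *reads*. Regions of type ``fastq`` act as read containers, numbered
1..R in 5'->3' order, and element offsets are computed relative to their
containing read (coordinates restart at 0 at each read boundary).

Three dialects are supported:

``kb``        colon-separated ``read,start,stop`` triplets (0-based,
              half-open), barcode group(s) first, then UMI, then cDNA with
              ``stop = 0`` meaning "to the end of the read".
``starsolo``  ``--soloCBstart/--soloCBlen/--soloUMIstart/--soloUMIlen`` flags
              with 1-based starts; multiple barcodes fold into one CB block
              only when adjacent.
``simpleaf``  per-read blocks ``N{...}`` holding ``b[len]`` (barcode),
              ``u[len]`` (UMI), ``x[len]`` (skip) and ``r`` (rest of read,
              the biological sequence).

All three demand fixed offsets for barcodes and UMIs: a variable-length
barcode design (inDropsv3-style) has no representation in these grammars and
raises :class:`~assayspec.exceptions.GeometryError`. New emitters register
via :func:`register_emitter` without touching the indexing code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

from .exceptions import GeometryError, StructureError
from .model import Assay, Interval, Region, get_modality, leaves, walk

TOOLS = ("kb", "starsolo", "simpleaf")

_BIOLOGICAL = {"cdna", "gdna"}


@dataclass
class ToolGeometry:
    tool: str
    text: str
    warnings: list[str] = field(default_factory=list)


@dataclass
class _Element:
    """One atomic region placed inside a read container."""

    read_index: int  # 0-based
    region: Region
    start_min: int
    start_max: int
    stop_min: int
    stop_max: int
    fixed: bool

    @property
    def start(self) -> int:
        return self.start_min

    @property
    def length(self) -> int:
        return self.stop_min - self.start_min


def _read_layout(assay: Assay, modality: str) -> list[list[_Element]]:
    """Per-read element layouts with read-relative 0-based coordinates."""
    top = get_modality(assay, modality)
    containers = [r for r in walk(top) if r.region_type == "fastq"]
    if not containers:
        raise StructureError(
            f"modality {modality!r} has no fastq read containers; "
            "tool strings need per-read coordinates"
        )
    out: list[list[_Element]] = []
    for ridx, container in enumerate(containers):
        cum_min = cum_max = 0
        upstream_fixed = True
        row: list[_Element] = []
        for leaf in leaves(container):
            if leaf is container:
                break  # an atomic fastq container holds no elements
            fixed = upstream_fixed and leaf.is_fixed_length
            row.append(
                _Element(
                    read_index=ridx,
                    region=leaf,
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
        out.append(row)
    return out


def _classify(layout: list[list[_Element]]):
    barcodes = [e for row in layout for e in row if e.region.region_type == "barcode"]
    umis = [e for row in layout for e in row if e.region.region_type == "umi"]
    cdnas = [e for row in layout for e in row if e.region.region_type in _BIOLOGICAL]
    found = sorted({e.region.region_type for row in layout for e in row})
    if not barcodes or len(umis) != 1 or len(cdnas) != 1:
        raise StructureError(
            "tool strings need >=1 barcode, exactly 1 umi and exactly 1 "
            f"cdna/gdna region inside sequenced reads; found types {found} "
            f"({len(barcodes)} barcode, {len(umis)} umi, {len(cdnas)} cdna/gdna)"
        )
    for e in barcodes + umis:
        if not e.fixed:
            raise GeometryError(
                f"region {e.region.region_id!r} has a variable read offset or "
                "length (inDropsv3-style variable barcodes cannot be expressed "
                "in fixed-offset technology strings)"
            )
    cdna = cdnas[0]
    # everything upstream of the cDNA inside its read must be fixed so the
    # cDNA start is well defined
    if cdna.start_min != cdna.start_max:
        raise GeometryError(
            f"cdna region {cdna.region.region_id!r} has a variable start "
            "within its read"
        )
    return barcodes, umis[0], cdna


def _emit_kb(layout: list[list[_Element]]) -> ToolGeometry:
    barcodes, umi, cdna = _classify(layout)
    groups = [f"{e.read_index},{e.start},{e.start + e.length}" for e in barcodes]
    groups.append(f"{umi.read_index},{umi.start},{umi.start + umi.length}")
    groups.append(f"{cdna.read_index},{cdna.start},0")
    return ToolGeometry(tool="kb", text=":".join(groups))


def _emit_starsolo(layout: list[list[_Element]]) -> ToolGeometry:
    barcodes, umi, cdna = _classify(layout)
    warnings: list[str] = []
    first = barcodes[0]
    for prev, nxt in zip(barcodes, barcodes[1:]):
        adjacent = (
            prev.read_index == nxt.read_index and prev.start + prev.length == nxt.start
        )
        if not adjacent:
            raise GeometryError(
                "starsolo concatenates multiple barcodes into one CB block "
                f"only when adjacent; {prev.region.region_id!r} and "
                f"{nxt.region.region_id!r} are not"
            )
    cb_len = sum(e.length for e in barcodes)
    if umi.read_index != first.read_index:
        warnings.append("umi and barcode lie in different reads")
    text = (
        f"--soloCBstart {first.start + 1} --soloCBlen {cb_len} "
        f"--soloUMIstart {umi.start + 1} --soloUMIlen {umi.length}"
    )
    return ToolGeometry(tool="starsolo", text=text, warnings=warnings)


def _emit_simpleaf(layout: list[list[_Element]]) -> ToolGeometry:
    _classify(layout)  # shared structural/fixedness checks
    warnings: list[str] = []
    blocks: list[str] = []
    for ridx, row in enumerate(layout):
        # drop trailing irrelevant elements: simpleaf ignores the rest of a
        # read after the last addressed element
        relevant = [
            i
            for i, e in enumerate(row)
            if e.region.region_type in ({"barcode", "umi"} | _BIOLOGICAL)
        ]
        if not relevant:
            if row:
                warnings.append(
                    f"read {ridx + 1} holds no barcode/umi/cdna element; omitted"
                )
            continue
        tokens: list[str] = []
        for e in row[: relevant[-1] + 1]:
            rt = e.region.region_type
            if rt == "barcode":
                tokens.append(f"b[{e.length}]")
            elif rt == "umi":
                tokens.append(f"u[{e.length}]")
            elif rt in _BIOLOGICAL:
                tokens.append("r")
                break  # rest of read
            else:
                if not e.fixed:
                    raise GeometryError(
                        f"skip region {e.region.region_id!r} preceding an "
                        "addressed element must have a fixed length"
                    )
                tokens.append(f"x[{e.length}]")
        blocks.append(f"{ridx + 1}{{{''.join(tokens)}}}")
    return ToolGeometry(tool="simpleaf", text="".join(blocks), warnings=warnings)


_EMITTERS: dict[str, Callable[[list[list[_Element]]], ToolGeometry]] = {
    "kb": _emit_kb,
    "starsolo": _emit_starsolo,
    "simpleaf": _emit_simpleaf,
}


def register_emitter(
    name: str, fn: Callable[[list[list[_Element]]], ToolGeometry]
) -> None:
    """Register a new tool dialect without touching the indexing code."""
    _EMITTERS[name] = fn


def emit(assay: Assay, modality: str, tool: str) -> ToolGeometry:
    """Emit the technology string for ``tool`` from a modality's read layout.

    Deterministic and pure; see the module docstring for the dialects.
    """
    if tool not in _EMITTERS:
        raise StructureError(f"unknown tool {tool!r}; have {sorted(_EMITTERS)}")
    layout = _read_layout(assay, modality)
    return _EMITTERS[tool](layout)
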