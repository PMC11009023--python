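"""Human-readable views of an assay: ASCII read diagram, markdown, HTML.

The ASCII diagram draws one banner per modality followed by a row of boxes,
one per atomic region in 5'->3' order, labeled ``region_id(len)`` (or
``id(min-max)`` when variable). Box widths are proportional to their labels
but bounded (labels longer than 20 characters are truncated with ``..``);
rows wrap so no line exceeds the configured width. When ``fastq`` read
containers exist, a bracket line above the boxes marks which elements are
sequenced together — the "read diagram" variant of the ASCII format.
"""

from __future__ import annotations

from dataclasses import dataclass

from .exceptions import RenderError, SchemaError
from .model import Assay, Region, get_modality, leaves, walk

FORMATS = ("ascii", "markdown", "html")
_MAX_LABEL = 20


@dataclass
class RenderSpec:
    format: str = "ascii"
    width: int = 80


def _label(region: Region) -> str:
    if region.is_fixed_length:
        suffix = f"({region.min_len})"
    else:
        suffix = f"({region.min_len}-{region.max_len})"
    label = region.region_id + suffix
    if len(label) > _MAX_LABEL:
        keep = _MAX_LABEL - len(suffix) - 2
        label = region.region_id[: max(keep, 1)] + ".." + suffix
    return label


def _container_of(top: Region) -> dict[int, str]:
    """Map id(leaf) -> enclosing fastq read-container id."""
    out: dict[int, str] = {}
    for node in walk(top):
        if node.region_type == "fastq":
            for leaf in leaves(node):
                out[id(leaf)] = node.region_id
    return out


def _bracket_line(spans: list[tuple[int, int, str]], width: int) -> str:
    """Draw <--id--> brackets over the given (start, stop, container) spans."""
    line = [" "] * width
    for start, stop, cid in spans:
        w = stop - start
        if w < 2:
            continue
        text = cid[: w - 2]
        pad = w - 2 - len(text)
        inner = "-" * (pad // 2) + text + "-" * (pad - pad // 2)
        line[start] = "<"
        line[start + 1 : stop - 1] = list(inner)
        line[stop - 1] = ">"
    return "".join(line).rstrip()


def _ascii(assay: Assay, width: int) -> str:
    lines: list[str] = []
    for m in assay.modalities:
        top = get_modality(assay, m)
        lines.append(f"=== {m} ===")
        owner = _container_of(top)
        lvs = leaves(top)
        labels = [_label(l) for l in lvs]
        for label in labels:
            if len(label) + 2 > width:
                raise RenderError(
                    f"label {label!r} does not fit in width {width}; "
                    "use a larger width"
                )
        i = 0
        while i < len(lvs):
            row_text = "|"
            spans: list[tuple[int, int, str]] = []
            open_span = None  # (start_col, container_id)
            j = i
            while j < len(lvs):
                candidate = row_text + labels[j] + "|"
                if len(candidate) > width and j > i:
                    break
                start_col = len(row_text)
                row_text = candidate
                cid = owner.get(id(lvs[j]))
                if open_span and (cid != open_span[1]):
                    # close at the separator before this label
                    spans.append((open_span[0], start_col - 1, open_span[1]))
                    open_span = None
                if cid and not open_span:
                    open_span = (start_col, cid)
                j += 1
            if open_span:
                spans.append((open_span[0], len(row_text) - 1, open_span[1]))
            if spans:
                lines.append(_bracket_line(spans, len(row_text)))
            lines.append(row_text)
            i = j
        lines.append("")
    return "\n".join(lines)


def _table_rows(assay: Assay) -> list[tuple[str, list[list[str]]]]:
    out = []
    for m in assay.modalities:
        rows = []
        for order, leaf in enumerate(leaves(get_modality(assay, m))):
            length = (
                str(leaf.min_len)
                if leaf.is_fixed_length
                else f"{leaf.min_len}-{leaf.max_len}"
            )
            seq = leaf.sequence
            if len(seq) > 24:
                seq = seq[:22] + ".."
            rows.append(
                [str(order), leaf.region_id, leaf.region_type, length, seq or "-"]
            )
        out.append((m, rows))
    return out


_COLUMNS = ["order", "region_id", "region_type", "lengths", "sequence"]


def _markdown(assay: Assay) -> str:
    lines: list[str] = []
    for m, rows in _table_rows(assay):
        lines.append(f"## {m}")
        lines.append("")
        lines.append("| " + " | ".join(_COLUMNS) + " |")
        lines.append("|" + "---|" * len(_COLUMNS))
        for row in rows:
            lines.append("| " + " | ".join(row) + " |")
        lines.append("")
    return "\n".join(lines)


def _html(assay: Assay) -> str:
    parts = [
        "<!DOCTYPE html>",
        "<html>",
        "<head>",
        '<meta charset="utf-8">',
        f"<title>{assay.assay_id}</title>",
        "</head>",
        "<body>",
        f"<h1>{assay.name or assay.assay_id}</h1>",
    ]
    for m, rows in _table_rows(assay):
        parts.append(f"<h2>{m}</h2>")
        parts.append("<table>")
        parts.append(
            "<tr>" + "".join(f"<th>{c}</th>" for c in _COLUMNS) + "</tr>"
        )
        for row in rows:
            parts.append("<tr>" + "".join(f"<td>{c}</td>" for c in row) + "</tr>")
        parts.append("</table>")
    parts.extend(["</body>", "</html>"])
    return "\n".join(parts) + "\n"


def render(assay: Assay, spec: RenderSpec | None = None, **kwargs) -> str:
    """Render ``assay`` per ``spec`` (or keyword shortcuts format=/width=)."""
    if spec is None:
        spec = RenderSpec(**kwargs)
    if spec.format == "ascii":
        if spec.width < 40:
            raise RenderError("ascii rendering needs width >= 40")
        return _ascii(assay, spec.width)
    if spec.format == "markdown":
        return _markdown(assay)
    if spec.format == "html":
        return _html(assay)
    raise SchemaError(f"unknown render format {spec.format!r}; have {FORMATS}")
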