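"""Serialization: YAML documents, onlist files, newick initialization strings.

The canonical on-disk form (dialect A) is untagged block-style YAML with a
fixed key order and 2-space indentation; writes are byte-deterministic and
``parse_spec(write_spec(a)) == a`` for every well-formed assay. A tagged-node
dialect (dialect B, nodes prefixed with ``!Assay``/``!Region``/``!Onlist``
document tags) is accepted on input for compatibility but never emitted.
Onlists are read fully into memory (documented limit; not suitable for
multi-gigabyte lists).
"""

from __future__ import annotations

import datetime
import gzip
import hashlib
import re
from pathlib import Path
from typing import Optional, Union

import yaml

from .exceptions import (
    ContentError,
    IntegrityError,
    OnlistError,
    ParseError,
    SchemaError,
)
from .model import Assay, Onlist, Region, SequenceType

_HEADER_REQUIRED = ("assay_id", "name", "modalities", "seqspec_version", "library_spec")
_HEADER_OPTIONAL = ("doi", "date", "description")
_HEADER_ORDER = (
    "assay_id",
    "name",
    "doi",
    "date",
    "description",
    "modalities",
    "seqspec_version",
    "library_spec",
)
_REGION_REQUIRED = ("region_id", "region_type", "sequence_type", "min_len", "max_len")
_REGION_KEYS = (
    "region_id",
    "region_type",
    "name",
    "sequence_type",
    "sequence",
    "min_len",
    "max_len",
    "onlist",
    "regions",
)
_ONLIST_KEYS = ("filename", "location", "md5")


class _TaggedLoader(yaml.SafeLoader):
    """SafeLoader that strips application tags (!Assay, !Region, ...)."""


def _construct_tagged(loader, tag_suffix, node):
    if isinstance(node, yaml.MappingNode):
        return loader.construct_mapping(node, deep=True)
    if isinstance(node, yaml.SequenceNode):
        return loader.construct_sequence(node, deep=True)
    return loader.construct_scalar(node)


_TaggedLoader.add_multi_constructor("!", _construct_tagged)


# ---------------------------------------------------------------------------
# YAML documents
# ---------------------------------------------------------------------------


def _parse_region(node, path: str) -> Region:
    if not isinstance(node, dict):
        raise SchemaError(f"{path}: region must be a mapping, got {type(node).__name__}")
    rid = node.get("region_id")
    here = f"{path}/{rid}" if rid else f"{path}/?"
    for key in _REGION_REQUIRED:
        if key not in node or node[key] is None:
            raise SchemaError(f"missing required key {key!r} at {here}")
    st_raw = node["sequence_type"]
    try:
        st = SequenceType(st_raw)
    except ValueError:
        raise SchemaError(
            f"{here}: sequence_type must be one of fixed/onlist/random/joined, got {st_raw!r}"
        ) from None
    for key in ("min_len", "max_len"):
        if not isinstance(node[key], int) or isinstance(node[key], bool):
            raise SchemaError(f"{here}: {key} must be an integer, got {node[key]!r}")
    onlist = None
    if node.get("onlist") is not None:
        od = node["onlist"]
        if not isinstance(od, dict) or "filename" not in od:
            raise SchemaError(f"{here}: onlist must be a mapping with a filename")
        onlist = Onlist(
            filename=str(od["filename"]),
            location=str(od.get("location", "local")),
            md5=od.get("md5"),
        )
    children = [
        _parse_region(c, here) for c in (node.get("regions") or [])
    ]
    return Region(
        region_id=str(rid),
        region_type=str(node["region_type"]),
        name=str(node.get("name") or ""),
        sequence_type=st,
        sequence=str(node.get("sequence") or ""),
        min_len=node["min_len"],
        max_len=node["max_len"],
        onlist=onlist,
        regions=children,
    )


def parse_spec(text: str) -> Assay:
    """Parse a YAML assay document into an :class:`Assay`.

    Accepts both the canonical untagged dialect and the tagged-node dialect.
    Performs schema-level checks only (required keys, basic types); semantic
    validation is :func:`assayspec.validate.check`'s job. Unknown top-level
    keys are preserved in ``Assay.extra`` for lossless round-trip.
    """
    try:
        doc = yaml.load(text, Loader=_TaggedLoader)
    except yaml.YAMLError as e:
        mark = getattr(e, "problem_mark", None)
        where = f" at line {mark.line + 1}" if mark is not None else ""
        raise ParseError(f"YAML syntax error{where}: {e}") from None
    if not isinstance(doc, dict):
        raise SchemaError("document root must be a mapping")
    for key in _HEADER_REQUIRED:
        if key not in doc:
            raise SchemaError(f"missing required header key {key!r}")
    date = doc.get("date")
    if isinstance(date, (datetime.date, datetime.datetime)):
        date = date.isoformat()
    modalities = doc.get("modalities") or []
    if not isinstance(modalities, list):
        raise SchemaError("modalities must be a list of strings")
    tops = [
        _parse_region(node, "") for node in (doc.get("library_spec") or [])
    ]
    extra = {
        k: v
        for k, v in doc.items()
        if k not in _HEADER_REQUIRED and k not in _HEADER_OPTIONAL
    }
    return Assay(
        assay_id=str(doc["assay_id"]),
        name=str(doc.get("name") or ""),
        modalities=[str(m) for m in modalities],
        seqspec_version=str(doc["seqspec_version"]),
        doi=doc.get("doi"),
        date=date,
        description=doc.get("description"),
        library_spec=tops,
        extra=extra,
    )


def _region_to_dict(region: Region) -> dict:
    d: dict = {
        "region_id": region.region_id,
        "region_type": region.region_type,
        "name": region.name,
        "sequence_type": region.sequence_type.value,
        "sequence": region.sequence,
        "min_len": region.min_len,
        "max_len": region.max_len,
    }
    if region.onlist is None:
        d["onlist"] = None
    else:
        od = {"filename": region.onlist.filename, "location": region.onlist.location}
        if region.onlist.md5 is not None:
            od["md5"] = region.onlist.md5
        d["onlist"] = od
    d["regions"] = [_region_to_dict(c) for c in region.regions]
    return d


def write_spec(assay: Assay) -> str:
    """Emit the canonical untagged YAML form of ``assay``.

    Block style, fixed key order, 2-space indentation; deterministic byte
    for byte, and the inverse of :func:`parse_spec` on well-formed assays.
    """
    d: dict = {}
    for key in _HEADER_ORDER:
        if key == "library_spec":
            d[key] = [_region_to_dict(t) for t in assay.library_spec]
        elif key == "modalities":
            d[key] = list(assay.modalities)
        else:
            value = getattr(assay, key)
            if key in _HEADER_OPTIONAL and value is None:
                continue
            d[key] = value
    d.update(assay.extra)
    return yaml.safe_dump(
        d,
        sort_keys=False,
        default_flow_style=False,
        indent=2,
        width=2**16,
        allow_unicode=True,
    )


def load_spec(path: Union[str, Path]) -> Assay:
    """Read and parse a spec file."""
    return parse_spec(Path(path).read_text(encoding="utf-8"))


def save_spec(assay: Assay, path: Union[str, Path]) -> None:
    Path(path).write_text(write_spec(assay), encoding="utf-8")


# ---------------------------------------------------------------------------
# Onlist files
# ---------------------------------------------------------------------------

_SEQ_RE = re.compile(r"^[ACGT]+$")


def read_onlist(ref: Onlist, base_dir: Union[str, Path] = ".") -> list[str]:
    """Read an onlist file: one sequence per non-empty line, uppercased.

    Transparently decompresses ``.gz`` files; verifies ``ref.md5`` against the
    raw on-disk bytes when present. CRLF endings and trailing blank lines are
    tolerated; any other deviation (missing file, checksum mismatch, a line
    with characters outside A/C/G/T) raises.
    """
    if ref.location != "local":
        raise OnlistError(f"onlist {ref.filename!r} is {ref.location}, not local")
    path = Path(ref.filename)
    if not path.is_absolute():
        path = Path(base_dir) / path
    if not path.exists():
        raise OnlistError(f"onlist file not found: {path}")
    raw = path.read_bytes()
    if ref.md5 is not None:
        digest = hashlib.md5(raw).hexdigest()
        if digest != ref.md5.lower():
            raise IntegrityError(
                f"onlist {path}: md5 mismatch (expected {ref.md5}, got {digest})"
            )
    if path.suffix == ".gz":
        raw = gzip.decompress(raw)
    out: list[str] = []
    for lineno, line in enumerate(raw.decode("utf-8").splitlines(), start=1):
        seq = line.strip().upper()
        if not seq:
            continue
        if not _SEQ_RE.match(seq):
            raise ContentError(
                f"onlist {path}: line {lineno} is not an A/C/G/T sequence: {line!r}"
            )
        out.append(seq)
    return out


def write_onlist(
    sequences: list[str], path: Union[str, Path], compress: bool = False
) -> Onlist:
    """Write sequences one per line; returns a local Onlist with md5 filled in.

    Gzip output is written with a zeroed mtime so identical inputs produce
    byte-identical files.
    """
    path = Path(path)
    data = ("\n".join(sequences) + "\n").encode("utf-8")
    if compress:
        import io as _io

        buf = _io.BytesIO()
        with gzip.GzipFile(fileobj=buf, mode="wb", mtime=0) as fh:
            fh.write(data)
        data = buf.getvalue()
    path.write_bytes(data)
    return Onlist(
        filename=path.name, location="local", md5=hashlib.md5(data).hexdigest()
    )


# ---------------------------------------------------------------------------
# Newick initialization strings
# ---------------------------------------------------------------------------

_LABEL_RE = re.compile(r"[A-Za-z0-9_.\-]+")


def parse_newick(s: str) -> Region:
    """Parse a rooted newick string into a region tree.

    Grammar (fixed by this package; branch lengths are integer base counts):
    leaves are ``id:length`` and become atomic random regions of that fixed
    length; internal nodes carry a bare ``id`` and become meta regions; child
    order is preserved. The tree must end with ``;`` and labels must be
    unique. Errors report the character offset.
    """
    text = s.strip()
    pos = 0

    def err(msg: str) -> ParseError:
        return ParseError(f"newick: {msg} at position {pos}")

    def parse_label() -> str:
        nonlocal pos
        m = _LABEL_RE.match(text, pos)
        if not m:
            raise err("expected a label")
        pos = m.end()
        return m.group(0)

    def parse_node() -> Region:
        nonlocal pos
        if pos < len(text) and text[pos] == "(":
            pos += 1
            children = [parse_node()]
            while pos < len(text) and text[pos] == ",":
                pos += 1
                children.append(parse_node())
            if pos >= len(text) or text[pos] != ")":
                raise err("unbalanced parentheses: expected ')'")
            pos += 1
            label = parse_label()
            return Region(
                region_id=label,
                region_type="custom",
                sequence_type=SequenceType.JOINED,
                regions=children,
            )
        label = parse_label()
        if pos >= len(text) or text[pos] != ":":
            raise err(f"leaf {label!r} must carry ':<length>'")
        pos += 1
        m = re.match(r"\d+", text[pos:])
        if not m:
            raise err(f"leaf {label!r} has a non-integer length")
        length = int(m.group(0))
        pos += m.end()
        return Region(
            region_id=label,
            region_type="custom",
            sequence_type=SequenceType.RANDOM,
            min_len=length,
            max_len=length,
        )

    root = parse_node()
    if pos >= len(text) or text[pos] != ";":
        raise err("expected terminating ';'")
    pos += 1
    if pos != len(text):
        raise err("trailing characters after ';'")
    seen: dict[str, int] = {}
    from .model import walk

    for node in walk(root):
        seen[node.region_id] = seen.get(node.region_id, 0) + 1
    dupes = sorted(k for k, v in seen.items() if v > 1)
    if dupes:
        raise ParseError(f"newick: duplicate labels {dupes}")
    return root
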