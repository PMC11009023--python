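"""Semantic validation of assay documents.

:func:`check` never raises on an invalid document: every problem is collected
into a :class:`Violation` and the complete list, ordered by node path, is
returned. An empty list means the document is valid. All codes are
error-severity except ``UNKNOWN_TYPE`` (the region_type vocabulary is
deliberately open-ended, so an unrecognised type is only a warning).

Codes
-----
DUP_ID          duplicate region_id within the document
LEN_ORDER       min_len > max_len
FIXED_SEQ_LEN   fixed-sequence region whose sequence is empty, contains
                placeholders, or disagrees with min/max lengths
RANDOM_SEQ      random region whose sequence is neither empty nor all-X of
                max_len
JOIN_MISMATCH   meta/atomic sequence_type misuse, or a meta region whose
                sequence/lengths disagree with the resolved concatenation of
                its children
ONLIST_MISSING  onlist-type region without an onlist, or (with file
                resolution) a local onlist file that does not exist
ONLIST_MD5      onlist file fails its recorded checksum
ONLIST_LEN      onlist file with a line outside [min_len, max_len] of the
                owning region, or with non-A/C/G/T content
MODALITY_MAP    modalities and top-level regions are not in bijection
UNKNOWN_TYPE    region_type outside the recognised vocabulary (warning)
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Union

from . import io as _io
from .exceptions import ContentError, IntegrityError, OnlistError
from .model import (
    REGION_TYPES,
    Assay,
    Region,
    SequenceType,
    resolve_joined,
    walk_with_paths,
)

ERROR = "error"
WARNING = "warning"

#: defect codes exercised by the fixture generator's mutation mode
DEFECT_CODES = (
    "DUP_ID",
    "LEN_ORDER",
    "FIXED_SEQ_LEN",
    "JOIN_MISMATCH",
    "ONLIST_MISSING",
    "ONLIST_LEN",
    "MODALITY_MAP",
    "UNKNOWN_TYPE",
)


@dataclass
class Violation:
    code: str
    path: str
    message: str
    severity: str = ERROR

    def __str__(self) -> str:
        return f"{self.code}\t{self.path}\t{self.message}"


def _check_region(path: str, region: Region, out: list[Violation]) -> None:
    if region.min_len > region.max_len:
        out.append(
            Violation(
                "LEN_ORDER",
                path,
                f"min_len {region.min_len} exceeds max_len {region.max_len}",
            )
        )
    st = region.sequence_type
    if region.is_atomic:
        if st is SequenceType.JOINED:
            out.append(
                Violation(
                    "JOIN_MISMATCH", path, "sequence_type joined requires children"
                )
            )
        if st is SequenceType.FIXED:
            seq = region.sequence
            if not seq or any(c in "NX" for c in seq):
                out.append(
                    Violation(
                        "FIXED_SEQ_LEN",
                        path,
                        "fixed region must carry a concrete non-empty sequence",
                    )
                )
            elif not (region.min_len == region.max_len == len(seq)):
                out.append(
                    Violation(
                        "FIXED_SEQ_LEN",
                        path,
                        f"fixed sequence length {len(seq)} disagrees with "
                        f"min_len {region.min_len}/max_len {region.max_len}",
                    )
                )
        if st is SequenceType.RANDOM and region.sequence:
            if region.sequence != "X" * region.max_len:
                out.append(
                    Violation(
                        "RANDOM_SEQ",
                        path,
                        "random region sequence must be empty or all-X of max_len",
                    )
                )
        if st is SequenceType.ONLIST and region.onlist is None:
            out.append(
                Violation(
                    "ONLIST_MISSING", path, "onlist-type region carries no onlist"
                )
            )
    else:
        if st is not SequenceType.JOINED:
            out.append(
                Violation(
                    "JOIN_MISMATCH",
                    path,
                    f"meta region must have sequence_type joined, got {st.value}",
                )
            )
        else:
            try:
                resolved = resolve_joined(region)
            except Exception as e:  # a malformed descendant; reported there too
                out.append(Violation("JOIN_MISMATCH", path, str(e)))
                return
            if (region.min_len, region.max_len) != (resolved.min_len, resolved.max_len):
                out.append(
                    Violation(
                        "JOIN_MISMATCH",
                        path,
                        f"recorded lengths {region.min_len}/{region.max_len} disagree "
                        f"with child sums {resolved.min_len}/{resolved.max_len}",
                    )
                )
            elif region.sequence and region.sequence != resolved.sequence:
                out.append(
                    Violation(
                        "JOIN_MISMATCH",
                        path,
                        "recorded sequence disagrees with child concatenation",
                    )
                )
    if region.region_type not in REGION_TYPES:
        out.append(
            Violation(
                "UNKNOWN_TYPE",
                path,
                f"region_type {region.region_type!r} is outside the recognised "
                "vocabulary",
                severity=WARNING,
            )
        )


def _check_onlist_file(
    path: str, region: Region, base_dir: Union[str, Path], out: list[Violation]
) -> None:
    ref = region.onlist
    if ref is None or ref.location != "local":
        return
    try:
        seqs = _io.read_onlist(ref, base_dir=base_dir)
    except IntegrityError as e:
        out.append(Violation("ONLIST_MD5", path, str(e)))
        return
    except ContentError as e:
        out.append(Violation("ONLIST_LEN", path, str(e)))
        return
    except OnlistError as e:
        out.append(Violation("ONLIST_MISSING", path, str(e)))
        return
    bad = [s for s in seqs if not (region.min_len <= len(s) <= region.max_len)]
    if bad:
        out.append(
            Violation(
                "ONLIST_LEN",
                path,
                f"{len(bad)} onlist sequence(s) outside length range "
                f"[{region.min_len}, {region.max_len}] (e.g. {bad[0]!r})",
            )
        )


def check(
    assay: Assay,
    resolve_files: bool = True,
    base_dir: Union[str, Path] = ".",
) -> list[Violation]:
    """Verify every semantic invariant; return ALL violations, ordered by path.

    With ``resolve_files`` true, local onlist files are additionally opened:
    they must exist, match their recorded md5, and contain only A/C/G/T lines
    with lengths inside the owning region's [min_len, max_len].
    """
    out: list[Violation] = []

    mods = assay.modalities
    if not mods:
        out.append(Violation("MODALITY_MAP", "/", "modalities list is empty"))
    if len(set(mods)) != len(mods):
        out.append(Violation("MODALITY_MAP", "/", f"duplicate modalities in {mods}"))
    top_ids = [t.region_id for t in assay.library_spec]
    if top_ids != mods:
        out.append(
            Violation(
                "MODALITY_MAP",
                "/",
                f"top-level region ids {top_ids} do not match modalities {mods}",
            )
        )

    id_paths: dict[str, list[str]] = {}
    for top in assay.library_spec:
        for path, region in walk_with_paths(top):
            id_paths.setdefault(region.region_id, []).append(path)
            _check_region(path, region, out)
            if resolve_files:
                _check_onlist_file(path, region, base_dir, out)

    for rid in sorted(id_paths):
        paths = id_paths[rid]
        if len(paths) > 1:
            out.append(
                Violation(
                    "DUP_ID",
                    paths[0],
                    f"region_id {rid!r} occurs {len(paths)} times: "
                    + ", ".join(paths),
                )
            )

    out.sort(key=lambda v: (v.path, v.code))
    return out


def has_errors(violations: list[Violation]) -> bool:
    return any(v.severity == ERROR for v in violations)
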