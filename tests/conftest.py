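"""Shared fixtures and independent oracles.

The oracles here are deliberately naive re-implementations (exhaustive
enumeration, brute-force traversal) kept separate from the library code they
check.
"""

from __future__ import annotations

import itertools

import pytest

from assayspec import fixtures as fx
from assayspec.model import Interval, Region


@pytest.fixture(scope="session")
def toy1_ws(tmp_path_factory):
    """Fixed-geometry droplet-style workspace (TOY1)."""
    ws = tmp_path_factory.mktemp("toy1")
    assay = fx.build_tenx_like(ws)
    return assay, ws


@pytest.fixture(scope="session")
def toy2_ws(tmp_path_factory):
    """Variable-barcode workspace (TOY2)."""
    ws = tmp_path_factory.mktemp("toy2")
    assay = fx.build_indrops_like(ws)
    return assay, ws


@pytest.fixture(scope="session")
def toy3_ws(tmp_path_factory):
    """Two-modality split-pool workspace (TOY3)."""
    ws = tmp_path_factory.mktemp("toy3")
    assay = fx.build_shareseq_like(ws)
    return assay, ws


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------


def flatten_oracle(region: Region) -> list[Region]:
    """Brute-force recursive flatten, independent of model.leaves."""
    if not region.regions:
        return [region]
    out = []
    stack = [region]
    # explicit-stack pre-order, distinct from the library's recursion
    while stack:
        node = stack.pop()
        if not node.regions:
            out.append(node)
        else:
            stack.extend(reversed(node.regions))
    return out


def enumerate_intervals_oracle(leaf_specs: list[tuple[str, int, int]]) -> list[Interval]:
    """Materialize every concrete length assignment and read off offsets.

    ``leaf_specs`` is a 5'->3' list of (region_id, min_len, max_len).
    """
    starts: dict[str, set[int]] = {rid: set() for rid, _, _ in leaf_specs}
    stops: dict[str, set[int]] = {rid: set() for rid, _, _ in leaf_specs}
    ranges = [range(mn, mx + 1) for _, mn, mx in leaf_specs]
    for lengths in itertools.product(*ranges):
        pos = 0
        for (rid, _, _), length in zip(leaf_specs, lengths):
            starts[rid].add(pos)
            stops[rid].add(pos + length)
            pos += length
    out = []
    for rid, _, _ in leaf_specs:
        s, e = starts[rid], stops[rid]
        out.append(
            Interval(
                region_id=rid,
                start_min=min(s),
                start_max=max(s),
                stop_min=min(e),
                stop_max=max(e),
                fixed=len(s) == 1 and len(e) == 1,
            )
        )
    return out
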