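"""Document operations: indexing, formatting, modify, split, onlists, info."""

import copy
import itertools

import pytest

from assayspec import fixtures as fx
from assayspec.exceptions import (
    NotFoundError,
    SchemaError,
    UpdateRejectedError,
)
from assayspec.io import read_onlist
from assayspec.model import Onlist, find_by_id, get_modality, leaves
from assayspec.ops import (
    format_assay,
    index,
    info,
    merge,
    modify,
    onlist_resolve,
    split,
    version,
)

from conftest import enumerate_intervals_oracle


def leaf_specs(assay, modality):
    return [
        (l.region_id, l.min_len, l.max_len)
        for l in leaves(get_modality(assay, modality))
    ]


class TestIndex:
    def test_fixed_layout_is_cumulative_sums(self, toy1_ws):
        toy1, _ = toy1_ws
        got = {
            iv.region_id: (iv.start_min, iv.stop_min, iv.fixed)
            for iv in index(toy1, "rna").intervals
        }
        # p5(29) precedes the insert; all offsets fixed
        assert got["barcode"] == (29, 45, True)
        assert got["umi"] == (45, 57, True)
        assert got["cdna"] == (57, 147, True)

    def test_variable_upstream_propagates(self, toy2_ws):
        toy2, _ = toy2_ws
        by_id = {iv.region_id: iv for iv in index(toy2, "rna").intervals}
        umi = by_id["umi"]
        # barcode1 spans 8-12 after a 29 bp adapter
        assert (umi.start_min, umi.start_max, umi.fixed) == (37, 41, False)
        assert by_id["barcode1"].fixed is False

    def test_matches_exhaustive_enumeration_oracle(self, toy2_ws):
        toy2, _ = toy2_ws
        assert index(toy2, "rna").intervals == enumerate_intervals_oracle(
            leaf_specs(toy2, "rna")
        )

    def test_subset_does_not_shift_coordinates(self, toy1_ws):
        toy1, _ = toy1_ws
        only_umi = index(toy1, "rna", subset=["umi"]).intervals
        assert [(iv.region_id, iv.start_min, iv.stop_min) for iv in only_umi] == [
            ("umi", 45, 57)
        ]

    def test_unknown_modality_raises(self, toy1_ws):
        toy1, _ = toy1_ws
        with pytest.raises(NotFoundError):
            index(toy1, "protein")

    @pytest.mark.parametrize("seed", range(10))
    def test_contiguity_on_random_fixtures(self, tmp_path, seed):
        f = fx.make_fixture(
            fx.FixtureConfig(
                seed=seed, leaves_per_modality=2 + seed % 7, variable_fraction=0.5
            ),
            tmp_path,
        )
        ivs = index(f.assay, "rna").intervals
        assert ivs[0].start_min == ivs[0].start_max == 0
        for prev, nxt in zip(ivs, ivs[1:]):
            assert nxt.start_min == prev.stop_min
            assert nxt.start_max == prev.stop_max


class TestFormat:
    def test_blanked_meta_fields_are_reconstructed(self, toy1_ws):
        toy1, _ = toy1_ws
        blanked = copy.deepcopy(toy1)
        for top in blanked.library_spec:
            top.sequence = ""
            top.min_len = top.max_len = 0
        assert format_assay(blanked) == toy1

    @pytest.mark.parametrize("seed", range(5))
    def test_idempotent(self, tmp_path, seed):
        f = fx.make_fixture(
            fx.FixtureConfig(seed=seed, variable_fraction=0.4), tmp_path
        )
        once = format_assay(f.assay)
        assert format_assay(once) == once

    def test_variable_meta_lengths_are_sums(self, toy2_ws):
        toy2, _ = toy2_ws
        read1 = find_by_id(format_assay(toy2), "read1")
        # independent sum: barcode1 8-12 plus umi 6
        assert (read1.min_len, read1.max_len) == (14, 18)


class TestModify:
    def test_length_change_propagates_to_ancestors(self, toy1_ws):
        toy1, _ = toy1_ws
        out = modify(toy1, "barcode", {"min_len": 18, "max_len": 18})
        rna = out.library_spec[0]
        assert rna.max_len == toy1.library_spec[0].max_len + 2
        # value semantics: the input document is untouched
        assert toy1.library_spec[0].max_len == rna.max_len - 2

    def test_fixed_sequence_length_mismatch_rejected(self, toy1_ws):
        toy1, _ = toy1_ws
        with pytest.raises(UpdateRejectedError) as exc:
            modify(toy1, "p5", {"sequence": "ACGT"})
        assert exc.value.code == "FIXED_SEQ_LEN"

    def test_rename_to_existing_id_rejected(self, toy1_ws):
        toy1, _ = toy1_ws
        with pytest.raises(UpdateRejectedError) as exc:
            modify(toy1, "umi", {"region_id": "barcode"})
        assert exc.value.code == "DUP_ID"

    def test_unknown_region_and_field(self, toy1_ws):
        toy1, _ = toy1_ws
        with pytest.raises(NotFoundError):
            modify(toy1, "ghost", {"name": "x"})
        with pytest.raises(SchemaError):
            modify(toy1, "umi", {"frobs": 1})

    def test_invertible(self, toy1_ws):
        toy1, _ = toy1_ws
        there = modify(toy1, "umi", {"min_len": 10, "max_len": 10})
        back = modify(there, "umi", {"min_len": 12, "max_len": 12})
        assert back == format_assay(toy1)


class TestSplitMerge:
    def test_two_modalities_partition(self, toy3_ws):
        toy3, _ = toy3_ws
        parts = split(toy3)
        assert [p.modalities for p in parts] == [["rna"], ["atac"]]
        assert merge(parts) == toy3

    def test_single_modality_is_identity(self, toy1_ws):
        toy1, _ = toy1_ws
        (only,) = split(toy1)
        assert only == toy1

    @pytest.mark.parametrize("seed", range(4))
    def test_round_trip_preserves_ids_and_leaf_count(self, tmp_path, seed):
        f = fx.make_fixture(
            fx.FixtureConfig(seed=seed, n_modalities=1 + seed % 3), tmp_path
        )
        parts = split(f.assay)
        assert merge(parts) == f.assay
        ids = [l.region_id for p in parts for t in p.library_spec for l in leaves(t)]
        assert ids == [
            l.region_id for t in f.assay.library_spec for l in leaves(t)
        ]


class TestOnlistResolve:
    def test_single_onlist_path_verbatim(self, toy1_ws):
        toy1, _ = toy1_ws
        assert onlist_resolve(toy1, "rna", "barcode") == "barcodes.txt"

    def test_multifile_in_five_prime_order(self, toy3_ws):
        toy3, _ = toy3_ws
        assert onlist_resolve(toy3, "rna", "barcode", combine="multifile") == [
            "round1.txt",
            "round2.txt",
        ]

    def test_product_matches_double_loop(self, tmp_path, toy3_ws):
        toy3, ws = toy3_ws
        path = onlist_resolve(
            toy3, "rna", "barcode", combine="product", base_dir=ws
        )
        got = [l.strip() for l in open(path, encoding="utf-8")]
        first = read_onlist(Onlist("round1.txt"), base_dir=ws)
        second = read_onlist(Onlist("round2.txt"), base_dir=ws)
        expected = [a + b for a in first for b in second]
        assert got == expected
        assert len(got) == len(first) * len(second)

    def test_no_match_raises(self, toy1_ws):
        toy1, _ = toy1_ws
        with pytest.raises(NotFoundError):
            onlist_resolve(toy1, "rna", "umi")


class TestInfo:
    def test_toy1_summary(self, toy1_ws):
        toy1, _ = toy1_ws
        summary = info(toy1)
        (rna,) = summary.per_modality
        assert rna.leaf_count == 5  # p5, barcode, umi, cdna, p7
        # independent sum over the leaves
        total = sum(l.min_len for l in leaves(toy1.library_spec[0]))
        assert rna.min_len == rna.max_len == total

    def test_variable_totals(self, toy2_ws):
        toy2, _ = toy2_ws
        (rna,) = info(toy2).per_modality
        spans = [(l.min_len, l.max_len) for l in leaves(toy2.library_spec[0])]
        assert rna.min_len == sum(a for a, _ in spans)
        assert rna.max_len == sum(b for _, b in spans)
        assert rna.min_len < rna.max_len

    def test_absent_description_stays_absent(self, toy1_ws):
        toy1, _ = toy1_ws
        summary = info(toy1)
        assert summary.description is None
        assert "description" not in summary.to_dict()


class TestVersion:
    def test_tool_only(self):
        out = version()
        assert set(out) == {"tool_version"}

    def test_echoes_document_version(self, toy1_ws):
        toy1, _ = toy1_ws
        assert version(toy1)["spec_version"] == "0.1.0"

    def test_malformed_version_warns_but_echoes(self, toy1_ws):
        toy1, _ = toy1_ws
        odd = copy.deepcopy(toy1)
        odd.seqspec_version = "v2-draft"
        out = version(odd)
        assert out["spec_version"] == "v2-draft"
        assert out["warnings"]
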