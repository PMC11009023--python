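"""Fixture generator and read simulator."""

import math

import pytest

from assayspec import fixtures as fx
from assayspec.exceptions import ConfigError
from assayspec.io import read_onlist
from assayspec.model import find_by_id, get_modality, leaves, walk
from assayspec.ops import index
from assayspec.validate import check


class TestGenerator:
    def test_valid_mode_passes_check(self, tmp_path):
        f = fx.make_fixture(fx.FixtureConfig(seed=1), tmp_path)
        assert check(f.assay, base_dir=f.workspace) == []

    def test_identical_seed_gives_identical_bytes(self, tmp_path):
        cfg = fx.FixtureConfig(
            seed=1, n_modalities=2, leaves_per_modality=6, variable_fraction=0.5
        )
        a = fx.make_fixture(cfg, tmp_path / "a")
        b = fx.make_fixture(cfg, tmp_path / "b")
        spec_a = (a.workspace / "spec.yaml").read_bytes()
        assert spec_a == (b.workspace / "spec.yaml").read_bytes()
        for rid, path in a.onlists.items():
            assert path.read_bytes() == b.onlists[rid].read_bytes()

    def test_gzip_onlists_deterministic_and_readable(self, tmp_path):
        cfg = fx.FixtureConfig(seed=2, gzip_onlists=True)
        a = fx.make_fixture(cfg, tmp_path / "a")
        b = fx.make_fixture(cfg, tmp_path / "b")
        for rid, path in a.onlists.items():
            assert path.suffix == ".gz"
            assert path.read_bytes() == b.onlists[rid].read_bytes()
        assert check(a.assay, base_dir=a.workspace) == []

    def test_defect_mode_breaks_exactly_that_invariant(self, tmp_path):
        f = fx.make_fixture(fx.FixtureConfig(seed=1, defect="DUP_ID"), tmp_path)
        codes = {v.code for v in check(f.assay, base_dir=f.workspace)}
        assert "DUP_ID" in codes

    def test_contradictory_config_rejected(self, tmp_path):
        with pytest.raises(ConfigError):
            fx.make_fixture(fx.FixtureConfig(seed=0, leaves_per_modality=1), tmp_path)
        with pytest.raises(ConfigError):
            fx.make_fixture(fx.FixtureConfig(seed=0, defect="NOT_A_CODE"), tmp_path)

    def test_construct_is_adapter_insert_adapter(self, tmp_path):
        f = fx.make_fixture(fx.FixtureConfig(seed=3, leaves_per_modality=5), tmp_path)
        lvs = leaves(get_modality(f.assay, "rna"))
        assert lvs[0].region_type == "illumina_p5"
        assert lvs[-1].region_type == "illumina_p7"
        inner_types = {l.region_type for l in lvs[1:-1]}
        assert {"barcode", "cdna"} <= inner_types
        assert any(
            r.region_type == "fastq" for r in walk(get_modality(f.assay, "rna"))
        )


class TestSimulation:
    def test_error_free_barcodes_are_onlist_members(self, toy1_ws):
        toy1, ws = toy1_ws
        reads = fx.simulate_reads(toy1, "rna", 100, seed=7, error_rate=0.0, base_dir=ws)
        onlist = set(read_onlist(find_by_id(toy1, "barcode").onlist, base_dir=ws))
        assert all(str(r.seq)[:16] in onlist for r in reads["read1"])

    def test_umi_slice_has_indexed_length(self, toy1_ws):
        toy1, ws = toy1_ws
        reads = fx.simulate_reads(toy1, "rna", 100, seed=8, error_rate=0.0, base_dir=ws)
        # read-relative umi interval from index: full-layout minus read offset
        full = {iv.region_id: iv for iv in index(toy1, "rna").intervals}
        offset = full["barcode"].start_min  # read1 starts at the barcode
        lo = full["umi"].start_min - offset
        hi = full["umi"].stop_min - offset
        assert all(len(str(r.seq)[lo:hi]) == 12 for r in reads["read1"])

    def test_fixed_regions_appear_verbatim(self, tmp_path):
        # a fixture whose read 1 contains a fixed linker between barcodes
        f = fx.make_fixture(fx.FixtureConfig(seed=5, leaves_per_modality=5), tmp_path)
        linkers = [
            l
            for l in leaves(get_modality(f.assay, "rna"))
            if l.region_type == "linker"
        ]
        assert linkers
        reads = fx.simulate_reads(
            f.assay, "rna", 50, seed=9, error_rate=0.0, base_dir=f.workspace
        )
        full = {iv.region_id: iv for iv in index(f.assay, "rna").intervals}
        read1_leaves = leaves(find_by_id(f.assay, "rna_read1"))
        offset = full[read1_leaves[0].region_id].start_min
        for linker in linkers:
            iv = full[linker.region_id]
            if not iv.fixed:
                continue
            lo, hi = iv.start_min - offset, iv.stop_min - offset
            assert all(
                str(r.seq)[lo:hi] == linker.sequence for r in reads["rna_read1"]
            )

    def test_read_lengths_lie_in_modality_bounds(self, toy2_ws):
        toy2, ws = toy2_ws
        reads = fx.simulate_reads(toy2, "rna", 200, seed=3, error_rate=0.0, base_dir=ws)
        for cid, recs in reads.items():
            container = find_by_id(toy2, cid)
            lo = sum(l.min_len for l in leaves(container))
            hi = sum(l.max_len for l in leaves(container))
            assert all(lo <= len(r.seq) <= hi for r in recs)

    def test_substitution_rate_matches_binomial_expectation(self, toy1_ws):
        """With per-base error p, a 16 bp barcode misses its onlist at a rate
        close to 1 - (1-p)^16 (within 5 standard errors at n=2000; the
        acceptance suite runs the tighter 3-SE check at n=10000)."""
        toy1, ws = toy1_ws
        n, p = 2000, 0.01
        reads = fx.simulate_reads(toy1, "rna", n, seed=11, error_rate=p, base_dir=ws)
        onlist = set(read_onlist(find_by_id(toy1, "barcode").onlist, base_dir=ws))
        miss = sum(str(r.seq)[:16] not in onlist for r in reads["read1"]) / n
        expected = 1 - (1 - p) ** 16
        se = math.sqrt(expected * (1 - expected) / n)
        assert abs(miss - expected) < 5 * se

    def test_fastq_round_trip(self, toy1_ws, tmp_path):
        from Bio import SeqIO

        toy1, ws = toy1_ws
        reads = fx.simulate_reads(toy1, "rna", 10, seed=2, error_rate=0.0, base_dir=ws)
        out = tmp_path / "r1.fastq"
        fx.write_fastq(reads["read1"], out)
        back = list(SeqIO.parse(str(out), "fastq"))
        assert [str(r.seq) for r in back] == [str(r.seq) for r in reads["read1"]]
        assert all(q == 40 for q in back[0].letter_annotations["phred_quality"])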