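import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rohmap import (MISSING, apply_qc, hwe_exact_test, read_bedset,
                    read_pedmap, write_bedset, write_pedmap)
from rohmap.genotype_io import FormatError

from conftest import make_matrix
from oracles import hwe_exact_enumeration


def write_text(path, content):
    path.write_text(content)
    return path


class TestPedMap:
    def test_dosage_counts_allele_b(self, tmp_path):
        write_text(tmp_path / "x.map",
                   "1 v1 0 1000\n1 v2 0 2000\n1 v3 0 3000\n")
        write_text(tmp_path / "x.ped",
                   "F1 I1 0 0 1 -9 A A A G G G\n")
        ref = {"v1": "A", "v2": "A", "v3": "A"}
        g = read_pedmap(tmp_path / "x.ped", tmp_path / "x.map", ref_alleles=ref)
        assert g.samples == ["I1"]
        assert g.calls.tolist() == [[0, 1, 2]]

    def test_zero_zero_is_missing(self, tmp_path):
        write_text(tmp_path / "x.map",
                   "1 v1 0 1000\n1 v2 0 2000\n1 v3 0 3000\n")
        write_text(tmp_path / "x.ped",
                   "F1 I1 0 0 1 -9 A A 0 0 G G\n")
        ref = {"v1": "A", "v2": "A", "v3": "A"}
        g = read_pedmap(tmp_path / "x.ped", tmp_path / "x.map", ref_alleles=ref)
        assert g.calls.tolist() == [[0, MISSING, 2]]

    def test_sex_chromosome_loaded_not_dropped(self, tmp_path):
        write_text(tmp_path / "x.map", "30 vX 0 1000\n1 v1 0 2000\n")
        write_text(tmp_path / "x.ped", "F1 I1 0 0 1 -9 A A C C\n")
        g = read_pedmap(tmp_path / "x.ped", tmp_path / "x.map")
        assert set(g.variants["chrom"]) == {1, 30}

    def test_column_mismatch_names_line(self, tmp_path):
        write_text(tmp_path / "x.map", "1 v1 0 1000\n1 v2 0 2000\n")
        write_text(tmp_path / "x.ped",
                   "F1 I1 0 0 1 -9 A A C C\nF1 I2 0 0 1 -9 A A\n")
        with pytest.raises(FormatError, match="x.ped:2"):
            read_pedmap(tmp_path / "x.ped", tmp_path / "x.map")

    def test_duplicate_variant_id_rejected(self, tmp_path):
        write_text(tmp_path / "x.map", "1 v1 0 1000\n1 v1 0 2000\n")
        write_text(tmp_path / "x.ped", "F1 I1 0 0 1 -9 A A C C\n")
        with pytest.raises(FormatError, match="duplicate"):
            read_pedmap(tmp_path / "x.ped", tmp_path / "x.map")

    def test_variants_sorted_by_position(self, tmp_path):
        write_text(tmp_path / "x.map",
                   "2 v1 0 500\n1 v2 0 9000\n1 v3 0 100\n")
        write_text(tmp_path / "x.ped", "F1 I1 0 0 1 -9 A A C C T T\n")
        ref = {"v1": "A", "v2": "G", "v3": "T"}
        g = read_pedmap(tmp_path / "x.ped", tmp_path / "x.map", ref_alleles=ref)
        assert g.variants["id"].tolist() == ["v3", "v2", "v1"]
        assert g.calls.tolist() == [[0, 2, 0]]  # columns follow sorted map


class TestBedRoundTrip:
    @pytest.mark.parametrize("seed", range(5))
    def test_pedmap_bed_equivalence(self, tmp_path, seed):
        rng = np.random.default_rng(seed)
        n, m = rng.integers(1, 9, size=2)
        calls = rng.choice([0, 1, 2, MISSING], size=(n, m)).astype(np.int8)
        calls[0] = 1  # both alleles observed in every column
        g = make_matrix(calls)
        write_pedmap(g, tmp_path / "a.ped", tmp_path / "a.map")
        g_ped = read_pedmap(tmp_path / "a.ped", tmp_path / "a.map")
        write_bedset(g, tmp_path / "a.bed", tmp_path / "a.bim", tmp_path / "a.fam")
        g_bed = read_bedset(tmp_path / "a.bed", tmp_path / "a.bim", tmp_path / "a.fam")
        np.testing.assert_array_equal(g_bed.calls, g.calls)
        np.testing.assert_array_equal(g_ped.calls, g.calls)
        assert g_ped.samples == g_bed.samples == g.samples

    def test_bad_magic_rejected(self, tmp_path):
        g = make_matrix([[0, 1, 2]])
        write_bedset(g, tmp_path / "a.bed", tmp_path / "a.bim", tmp_path / "a.fam")
        raw = (tmp_path / "a.bed").read_bytes()
        (tmp_path / "a.bed").write_bytes(b"\x00" + raw[1:])
        with pytest.raises(FormatError, match="magic"):
            read_bedset(tmp_path / "a.bed", tmp_path / "a.bim", tmp_path / "a.fam")

    def test_truncated_bed_rejected(self, tmp_path):
        g = make_matrix(np.zeros((5, 8), dtype=np.int8))
        write_bedset(g, tmp_path / "a.bed", tmp_path / "a.bim", tmp_path / "a.fam")
        raw = (tmp_path / "a.bed").read_bytes()
        (tmp_path / "a.bed").write_bytes(raw[:-1])
        with pytest.raises(FormatError, match="size"):
            read_bedset(tmp_path / "a.bed", tmp_path / "a.bim", tmp_path / "a.fam")


class TestQC:
    def _matrix(self):
        rng = np.random.default_rng(0)
        calls = rng.binomial(2, 0.4, size=(40, 30)).astype(np.int8)
        return calls

    def test_call_rate_boundary_strict(self):
        calls = self._matrix()
        calls[0, :2] = MISSING   # call rate 28/30 = 0.933 -> removed
        calls[1, 0] = MISSING    # 29/30 = 0.967 -> kept
        g = make_matrix(calls)
        filtered, report = apply_qc(g, max_variant_missing=1.1, min_maf=0.0,
                                    hwe_p_floor=0.0)
        assert "S0" not in filtered.samples and "S1" in filtered.samples
        assert report.removed["sample_call_rate"] == 1

    def test_maf_boundary_strict(self):
        # 50 samples: column with exactly MAF 0.05 removed, 0.06 kept
        calls = np.ones((50, 3), dtype=np.int8)  # het everywhere: MAF 0.5
        calls[:, 1] = 0
        calls[:5, 1] = 1    # freq 5/100 = 0.05 -> removed
        calls[:, 2] = 0
        calls[:6, 2] = 1    # 0.06 -> kept
        g = make_matrix(calls)
        filtered, report = apply_qc(g, sample_call_rate=0.0,
                                    max_variant_missing=1.1, hwe_p_floor=0.0)
        assert filtered.variants["id"].tolist() == ["v0", "v2"]
        assert report.removed["maf"] == 1

    def test_monomorphic_removed(self):
        calls = np.ones((20, 2), dtype=np.int8)
        calls[:, 1] = 0  # monomorphic
        g = make_matrix(calls)
        filtered, _ = apply_qc(g, sample_call_rate=0.0, max_variant_missing=1.1,
                               hwe_p_floor=0.0)
        assert filtered.variants["id"].tolist() == ["v0"]

    def test_non_autosomal_removed_first(self):
        calls = np.tile([0, 1, 2, 1], (4, 1)).T.astype(np.int8)
        g = make_matrix(calls)
        g.variants.loc[0, "chrom"] = 30
        filtered, report = apply_qc(g, sample_call_rate=0.0,
                                    max_variant_missing=1.1, min_maf=0.0,
                                    hwe_p_floor=0.0)
        assert report.removed["non_autosomal"] == 1
        assert 30 not in set(filtered.variants["chrom"])

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        calls = rng.binomial(2, rng.uniform(0.1, 0.5, size=40),
                             size=(60, 40)).astype(np.int8)
        calls[rng.random(calls.shape) < 0.02] = MISSING
        g = make_matrix(calls)
        g1, _ = apply_qc(g)
        g2, report2 = apply_qc(g1)
        np.testing.assert_array_equal(g1.calls, g2.calls)
        assert sum(report2.removed.values()) == 0

    def test_all_removed_is_error(self):
        calls = np.ones((10, 4), dtype=np.int8)
        calls[:, :] = 0  # all monomorphic
        with pytest.raises(ValueError, match="dominant filter"):
            apply_qc(make_matrix(calls), sample_call_rate=0.0)


class TestHWE:
    @given(st.integers(0, 40), st.integers(0, 40), st.integers(0, 40))
    @settings(deadline=None, max_examples=150, derandomize=True)
    def test_symmetry_range_and_oracle(self, hom_a, het, hom_b):
        """p is allele-label symmetric, lies in (0, 1], and matches the
        exact-rational enumeration."""
        if hom_a + het + hom_b == 0:
            return
        p = hwe_exact_test(hom_a, het, hom_b)
        assert 0.0 < p <= 1.0
        assert p == pytest.approx(hwe_exact_test(hom_b, het, hom_a), rel=1e-9)
        assert p == pytest.approx(hwe_exact_enumeration(hom_a, het, hom_b),
                                  rel=1e-9)

    @pytest.mark.parametrize("counts", [(5, 0, 5), (25, 50, 25), (100, 0, 0),
                                        (3, 7, 2), (0, 10, 0), (1, 1, 1)])
    def test_matches_enumeration(self, counts):
        assert hwe_exact_test(*counts) == pytest.approx(
            hwe_exact_enumeration(*counts), rel=1e-9)

    def test_exhaustive_small_totals(self):
        """Agreement with the exact-rational enumeration for all genotype
        configurations with up to 20 individuals."""
        for n in range(1, 21):
            for het in range(n + 1):
                for hom_a in range(n - het + 1):
                    hom_b = n - het - hom_a
                    assert hwe_exact_test(hom_a, het, hom_b) == pytest.approx(
                        hwe_exact_enumeration(hom_a, het, hom_b), rel=1e-9), \
                        (hom_a, het, hom_b)

    def test_monomorphic_is_one(self):
        assert hwe_exact_test(100, 0, 0) == 1.0

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 0, 5)
        with pytest.raises(ValueError):
            hwe_exact_test(0, 0, 0)
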