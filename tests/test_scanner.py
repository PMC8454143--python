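import numpy as np
import pytest

from rohmap import (MISSING, ROHSegment, ScannerParams, call_roh,
                    classify_size, detect_roh_population, window_hit_rates)

from conftest import make_matrix
from oracles import brute_roh, brute_window_rates

DEFAULT = ScannerParams()


def run_oracle(calls, positions, params):
    return brute_roh(
        list(calls), list(positions),
        window_snps=params.window_snps, window_max_het=params.window_max_het,
        window_max_missing=params.window_max_missing,
        window_hit_threshold=params.window_hit_threshold,
        min_length_bp=params.min_length_bp, min_snps=params.min_snps,
        min_density_bp_per_snp=params.min_density_bp_per_snp,
        max_gap_bp=params.max_gap_bp, roh_max_het=params.roh_max_het,
        roh_max_missing=params.roh_max_missing)


def segments_as_tuples(segments):
    return [(s.start_bp, s.end_bp, s.n_snps, s.n_het, s.n_missing)
            for s in segments]


class TestWindowRates:
    def test_all_homozygous_rate_one(self):
        rates = window_hit_rates(np.zeros(250, dtype=np.int8))
        assert np.all(rates == 1.0)

    def test_all_heterozygous_rate_zero(self):
        rates = window_hit_rates(np.ones(250, dtype=np.int8))
        assert np.all(rates == 0.0)

    def test_short_chromosome_no_candidates(self):
        rates = window_hit_rates(np.zeros(49, dtype=np.int8))
        assert rates.shape == (49,) and np.all(rates == 0.0)

    def test_two_hets_dip_matches_brute_force(self):
        calls = np.zeros(200, dtype=np.int8)
        calls[[90, 110]] = 1  # two hets inside one 50-SNP span
        rates = window_hit_rates(calls)
        expected = brute_window_rates(list(calls))
        np.testing.assert_allclose(rates, expected)
        assert rates[100] < 1.0  # windows holding both hets fail

    @pytest.mark.parametrize("seed", range(10))
    def test_fuzz_equals_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(10, 400))
        calls = rng.choice([0, 1, 2, MISSING], size=m,
                           p=[0.45, 0.08, 0.45, 0.02]).astype(np.int8)
        np.testing.assert_allclose(window_hit_rates(calls),
                                   brute_window_rates(list(calls)))


class TestCallROH:
    def test_uniform_homozygous_run(self):
        """250 homozygous SNPs spaced 10 kb form a single ROH covering the
        first-to-last SNP span."""
        g = make_matrix(np.zeros(250, dtype=np.int8), spacing_bp=10_000)
        segs = call_roh(g.calls[0], g.variants, DEFAULT, "S0")
        assert len(segs) == 1
        s = segs[0]
        assert s.n_snps == 250
        assert s.length_bp == 249 * 10_000 + 1
        assert s.n_het == 0 and s.n_missing == 0

    def test_min_snps_criterion(self):
        """99 consecutive homozygous SNPs over >1 Mb flanked by hets fail
        the 100-SNP minimum."""
        calls = np.ones(300, dtype=np.int8)
        calls[100:199] = 0  # 99 hom SNPs spanning 98*13kb = 1.27 Mb
        g = make_matrix(calls, spacing_bp=13_000)
        assert call_roh(g.calls[0], g.variants, DEFAULT, "S0") == []

    def test_gap_splits_run(self):
        """An internal gap of 150 kb splits a homozygous run into two
        candidates, each evaluated independently."""
        pos = np.concatenate([100_000 + 4_000 * np.arange(150),
                              100_000 + 4_000 * 150 + 150_000
                              + 4_000 * np.arange(150)])
        g = make_matrix(np.zeros(300, dtype=np.int8))
        g.variants["pos"] = pos
        segs = call_roh(g.calls[0], g.variants, DEFAULT, "S0")
        assert len(segs) == 2
        assert segs[0].end_bp < segs[1].start_bp
        assert segs[1].start_bp - segs[0].end_bp == 150_000 + 4_000

    def test_single_het_tolerated_two_rejected_in_segment(self, tight_params):
        calls = np.zeros(60, dtype=np.int8)
        calls[30] = 1
        g = make_matrix(calls, spacing_bp=5_000)
        segs = call_roh(g.calls[0], g.variants, tight_params, "S0")
        assert len(segs) == 1 and segs[0].n_het == 1

    def test_misaligned_inputs_rejected(self):
        g = make_matrix(np.zeros(50, dtype=np.int8))
        with pytest.raises(ValueError, match="does not match"):
            call_roh(g.calls[0][:-1], g.variants)

    @pytest.mark.parametrize("seed", range(30))
    def test_fuzz_matches_oracle(self, seed):
        """Scanner output is identical to the loop-based reference on random
        genotype vectors, across several parameterisations."""
        rng = np.random.default_rng(seed)
        m = int(rng.integers(30, 600))
        p_hom = rng.uniform(0.7, 0.98)
        rest = 1 - p_hom
        calls = rng.choice([0, 1, 2, MISSING], size=m,
                           p=[p_hom / 2, rest * 0.6, p_hom / 2, rest * 0.4]
                           ).astype(np.int8)
        pos = np.cumsum(rng.integers(500, 60_000, size=m)) + 1
        params = ScannerParams(
            window_snps=int(rng.integers(5, 30)),
            window_max_het=int(rng.integers(0, 3)),
            window_max_missing=int(rng.integers(0, 4)),
            window_hit_threshold=float(rng.uniform(0.05, 0.9)),
            min_length_bp=int(rng.integers(10_000, 400_000)),
            min_snps=int(rng.integers(3, 60)),
            min_density_bp_per_snp=int(rng.integers(20_000, 80_000)),
            max_gap_bp=int(rng.integers(30_000, 150_000)),
            roh_max_het=int(rng.integers(0, 3)),
            roh_max_missing=int(rng.integers(0, 4)))
        g = make_matrix(calls)
        g.variants["pos"] = pos
        got = segments_as_tuples(call_roh(g.calls[0], g.variants, params, "S0"))
        assert got == run_oracle(calls, pos, params)


class TestClassify:
    @pytest.mark.parametrize("length,expected", [
        (750_000, "Small"), (999_999, "Small"), (1_000_000, "Medium"),
        (5_000_000, "Medium"), (5_000_001, "Large"), (6_000_000, "Large")])
    def test_boundaries(self, length, expected):
        assert classify_size(length) == expected

    def test_below_minimum_rejected(self):
        with pytest.raises(ValueError, match="below the minimum"):
            classify_size(499_999)


class TestPopulation:
    def test_single_planted_segment_found_once(self):
        calls = np.ones((3, 400), dtype=np.int8)  # all-het background
        calls[1, 100:320] = 0
        g = make_matrix(calls, spacing_bp=4_000)
        segs = detect_roh_population(g)
        assert len(segs) == 1 and segs[0].sample_id == "S1"

    def test_sample_permutation_preserves_segment_set(self):
        rng = np.random.default_rng(5)
        calls = rng.choice([0, 1, 2], size=(4, 500),
                           p=[0.48, 0.04, 0.48]).astype(np.int8)
        g = make_matrix(calls, spacing_bp=4_000)
        perm = [2, 0, 3, 1]
        g_perm = g.subset(sample_idx=perm)
        a = {(s.sample_id, s.chrom, s.start_bp, s.end_bp)
             for s in detect_roh_population(g)}
        b = {(s.sample_id, s.chrom, s.start_bp, s.end_bp)
             for s in detect_roh_population(g_perm)}
        assert a == b

    def test_emitted_segments_satisfy_all_invariants(self):
        rng = np.random.default_rng(17)
        calls = rng.choice([0, 1, 2, MISSING], size=(5, 2000),
                           p=[0.47, 0.04, 0.47, 0.02]).astype(np.int8)
        g = make_matrix(calls, spacing_bp=4_000)
        p = DEFAULT
        for s in detect_roh_population(g, p):
            assert s.start_bp <= s.end_bp
            assert s.n_het <= p.roh_max_het
            assert s.n_missing <= p.roh_max_missing
            assert s.length_bp >= p.min_length_bp
            assert s.n_snps >= p.min_snps
            assert s.length_bp / s.n_snps <= p.min_density_bp_per_snp

    def test_monotonic_in_thresholds(self):
        rng = np.random.default_rng(23)
        calls = rng.choice([0, 1, 2], size=(3, 1500),
                           p=[0.485, 0.03, 0.485]).astype(np.int8)
        g = make_matrix(calls, spacing_bp=4_000)
        base = len(detect_roh_population(g, DEFAULT))
        stricter_len = len(detect_roh_population(
            g, ScannerParams(min_length_bp=1_000_000)))
        stricter_snps = len(detect_roh_population(
            g, ScannerParams(min_snps=200)))
        looser_thresh = len(detect_roh_population(
            g, ScannerParams(window_hit_threshold=0.01)))
        assert stricter_len <= base
        assert stricter_snps <= base
        assert looser_thresh >= base

    def test_fully_homozygous_genome_tiles_covered_span(self):
        g = make_matrix(np.zeros((1, 1000), dtype=np.int8), spacing_bp=4_000)
        segs = detect_roh_population(g)
        pos = g.variants["pos"].to_numpy()
        assert len(segs) == 1
        assert segs[0].start_bp == pos[0] and segs[0].end_bp == pos[-1]
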