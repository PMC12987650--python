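"""Selection statistics against naive textbook-formula references."""

import math

import numpy as np
import pytest

from lncevo.popgen import (HaplotypePanel, allele_freqs, faywu_h,
                           genome_background, integrated_fst,
                           joint_selection_call, ld_r2, snp_density, tajima_d,
                           tile_windows, weighted_fst)

from conftest import random_panel
from refimpl import naive_faywu_h, naive_pi, naive_r2, naive_tajima_d, naive_wc_fst


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(20))
    def test_tajima_d_matches_direct_formula(self, seed):
        rng = np.random.default_rng(seed)
        p = random_panel(rng, n=int(rng.integers(4, 20)), s=int(rng.integers(1, 30)))
        got = tajima_d(p).tajima_D
        want = naive_tajima_d(p.matrix)
        assert got == pytest.approx(want, abs=1e-9)

    @pytest.mark.parametrize("seed", range(20))
    def test_faywu_h_matches_direct_formula(self, seed):
        rng = np.random.default_rng(100 + seed)
        p = random_panel(rng, n=int(rng.integers(2, 20)), s=int(rng.integers(1, 30)),
                         unknown_frac=0.2)
        got = faywu_h(p).faywu_H
        want = naive_faywu_h(p.matrix, p.ancestral)
        assert got == pytest.approx(want, abs=1e-9)

    @pytest.mark.parametrize("seed", range(20))
    def test_weighted_fst_matches_naive_weir_cockerham(self, seed):
        rng = np.random.default_rng(200 + seed)
        s = int(rng.integers(1, 30))
        pa = random_panel(rng, n=2 * int(rng.integers(3, 10)), s=s, pop="A")
        pb = random_panel(rng, n=2 * int(rng.integers(3, 10)), s=s, pop="B")
        got = weighted_fst(pa, pb).weighted_fst
        want = naive_wc_fst(pa.matrix[0::2] + pa.matrix[1::2],
                            pb.matrix[0::2] + pb.matrix[1::2])
        assert got == pytest.approx(want, abs=1e-9)

    @pytest.mark.parametrize("seed", range(20))
    def test_r2_matches_haplotype_frequency_formula(self, seed):
        rng = np.random.default_rng(300 + seed)
        p = random_panel(rng, n=20, s=2)
        got = ld_r2(p, 0, 1)
        assert got == pytest.approx(naive_r2(p.matrix[:, 0], p.matrix[:, 1]),
                                    abs=1e-9)

    def test_pi_matches_pairwise_count(self, rng):
        p = random_panel(rng, n=12, s=15)
        assert tajima_d(p).pi == pytest.approx(naive_pi(p.matrix), abs=1e-9)


class TestStatisticProperties:
    def test_d_zero_when_pi_equals_watterson(self):
        # n=4, one singleton at every site: pi = 2S*... arrange pi == S/a1?
        # use the numerator directly: windows where pi == theta_w give D == 0
        mat = np.array([[1, 0], [0, 1], [0, 0], [0, 0]], dtype=np.int8)
        p = HaplotypePanel(mat, np.array([0, 1]), np.zeros(2, dtype=np.int8))
        st = tajima_d(p)
        if st.pi == pytest.approx(st.theta_w):
            assert st.tajima_D == pytest.approx(0.0)

    def test_d_undefined_when_no_segregating_sites(self):
        mat = np.zeros((6, 3), dtype=np.int8)
        p = HaplotypePanel(mat, np.arange(3), np.zeros(3, dtype=np.int8))
        st = tajima_d(p)
        assert st.S == 0 and math.isnan(st.tajima_D)

    def test_h_zero_for_n2_singleton_and_negative_for_high_freq_derived(self):
        mat = np.array([[1], [0]], dtype=np.int8)
        p = HaplotypePanel(mat, np.array([0]), np.zeros(1, dtype=np.int8))
        st = faywu_h(p)
        assert st.faywu_H == pytest.approx(0.0)
        # all derived alleles at count n-1
        mat = np.ones((10, 5), dtype=np.int8)
        mat[0] = 0
        p = HaplotypePanel(mat, np.arange(5), np.zeros(5, dtype=np.int8))
        assert faywu_h(p).faywu_H < 0

    def test_h_zero_when_no_derived_alleles(self):
        mat = np.zeros((8, 4), dtype=np.int8)
        p = HaplotypePanel(mat, np.arange(4), np.zeros(4, dtype=np.int8))
        assert faywu_h(p).faywu_H == 0.0

    def test_fst_is_one_for_fixed_difference(self):
        pa = HaplotypePanel(np.zeros((10, 1), dtype=np.int8), np.array([0]),
                            np.zeros(1, dtype=np.int8), "A")
        pb = HaplotypePanel(np.ones((10, 1), dtype=np.int8), np.array([0]),
                            np.zeros(1, dtype=np.int8), "B")
        assert weighted_fst(pa, pb).weighted_fst == pytest.approx(1.0)

    def test_fst_near_zero_for_identical_frequencies(self, rng):
        vals = []
        for seed in range(30):
            r = np.random.default_rng(seed)
            col = (r.random((40, 8)) < 0.4).astype(np.int8)
            pa = HaplotypePanel(col[:20], np.arange(8), np.zeros(8, dtype=np.int8), "A")
            pb = HaplotypePanel(col[20:], np.arange(8), np.zeros(8, dtype=np.int8), "B")
            vals.append(weighted_fst(pa, pb).weighted_fst)
        assert abs(np.mean(vals)) < 0.05

    def test_r2_identical_and_complementary_columns(self):
        col = np.array([1, 1, 0, 0, 1, 0, 1, 0], dtype=np.int8)
        mat = np.stack([col, col, 1 - col], axis=1)
        p = HaplotypePanel(mat, np.arange(3), np.zeros(3, dtype=np.int8))
        assert ld_r2(p, 0, 1) == pytest.approx(1.0)
        assert ld_r2(p, 0, 2) == pytest.approx(1.0)

    def test_r2_shuffled_columns_mean_near_null(self):
        rng = np.random.default_rng(5)
        n = 40
        vals = []
        for _ in range(300):
            a = np.zeros(n, dtype=np.int8)
            a[rng.choice(n, 20, replace=False)] = 1
            b = np.zeros(n, dtype=np.int8)
            b[rng.choice(n, 20, replace=False)] = 1
            p = HaplotypePanel(np.stack([a, b], axis=1), np.arange(2),
                               np.zeros(2, dtype=np.int8))
            vals.append(ld_r2(p, 0, 1))
        assert np.mean(vals) == pytest.approx(1 / (n - 1), abs=0.01)


class TestFreqsDensityBackground:
    def test_maf_and_daf(self):
        mat = np.zeros((10, 2), dtype=np.int8)
        mat[:3, 0] = 1
        mat[:3, 1] = 1
        p = HaplotypePanel(mat, np.array([5, 15]), np.array([0, 1], dtype=np.int8))
        f = allele_freqs(p)
        assert f.maf.tolist() == [0.3, 0.3]
        assert f.daf.tolist() == [0.3, 0.7]

    def test_monomorphic_column_maf_zero(self):
        p = HaplotypePanel(np.zeros((10, 1), dtype=np.int8), np.array([0]),
                           np.zeros(1, dtype=np.int8))
        f = allele_freqs(p)
        assert f.maf.iloc[0] == 0.0 and f.daf.iloc[0] == 0.0

    def test_unknown_ancestral_daf_missing(self):
        p = HaplotypePanel(np.zeros((4, 1), dtype=np.int8), np.array([0]),
                           np.full(1, -1, dtype=np.int8))
        assert math.isnan(allele_freqs(p).daf.iloc[0])

    def test_snp_density_counts_and_threshold(self):
        mat = np.zeros((10, 3), dtype=np.int8)
        mat[:3, 0] = 1   # MAF 0.3
        mat[:1, 1] = 1   # MAF 0.1
        mat[:4, 2] = 1   # MAF 0.4 but outside window
        p = HaplotypePanel(mat, np.array([10, 50, 500]), np.zeros(3, dtype=np.int8))
        count, per_base = snp_density(p, (0, 147), maf_min=0.1)
        assert count == 2
        assert per_base == pytest.approx(2 / 147)
        assert snp_density(p, (0, 147), maf_min=0.11)[0] == 1

    def test_background_percentile_uniform_and_constant(self):
        rng = np.random.default_rng(8)
        thr, n = genome_background(rng.random(10000), 10.0, "upper")
        assert n == 10000
        assert thr == pytest.approx(0.9, abs=0.02)
        thr, _ = genome_background(np.full(200, 3.14), 10.0, "lower")
        assert thr == pytest.approx(3.14)

    def test_background_needs_enough_windows(self):
        with pytest.raises(ValueError):
            genome_background(np.arange(50), 10.0, "lower")


class TestIntegratedFstAndJointCall:
    def test_mean_of_focal_pairs(self):
        pw = {"CEU-YRI": 0.2, "CHB-YRI": 0.9, "CHB-CEU": 0.4}
        assert integrated_fst(pw, "CEU") == pytest.approx(0.3)
        assert integrated_fst(pw, "CEU", "max") == pytest.approx(0.4)
        assert integrated_fst({"A-B": 0.0, "A-C": 0.0, "B-C": 0.0}, "A") == 0.0

    def test_undefined_component_propagates(self):
        pw = {"CEU-YRI": float("nan"), "CHB-YRI": 0.9, "CHB-CEU": 0.4}
        assert math.isnan(integrated_fst(pw, "CEU"))

    def _call(self, d, fst):
        thr = {"CEU": -0.97, "CHB": -0.96, "YRI": -0.97}
        calls = joint_selection_call("x", d, fst, thr, 0.22)
        return {c.population: c.is_positive for c in calls}

    def test_joint_rule_fires_only_with_all_clauses(self):
        d = {"CEU": -1.2, "CHB": 0.5, "YRI": 0.3}
        assert self._call(d, 0.3) == {"CEU": True, "CHB": False, "YRI": False}
        # other-population D <= 0 blocks the call
        assert self._call({"CEU": -1.2, "CHB": -0.1, "YRI": 0.3}, 0.3)["CEU"] is False
        # insufficient integrated Fst blocks regardless of D
        assert self._call(d, 0.1)["CEU"] is False
        # undefined D yields no positive call
        assert self._call({"CEU": float("nan"), "CHB": 0.5, "YRI": 0.3},
                          0.3)["CEU"] is False


def test_tile_windows_keeps_half_full_terminal():
    assert tile_windows(0, 300, 147) == [(0, 147), (147, 294)]
    assert tile_windows(0, 380, 147) == [(0, 147), (147, 294), (294, 380)]
    assert tile_windows(0, 360, 147) == [(0, 147), (147, 294)]
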