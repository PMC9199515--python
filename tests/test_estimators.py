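"""Causal estimators: closed-form oracles, symmetries, scale transforms."""

import numpy as np
import pytest

from mrtea import HarmonizedSet, egger, ivw, to_odds_ratio, wald_ratio, weighted_median, weighted_mode
from oracles import ivw_oracle, mode_grid_oracle, weighted_median_oracle
from conftest import random_harmonized


def hset(bx, by, seby, sebx=None):
    bx = np.asarray(bx, dtype=float)
    sebx = np.full_like(bx, 0.01) if sebx is None else np.asarray(sebx, dtype=float)
    return HarmonizedSet.from_arrays(bx, sebx, by, seby)


class TestWaldRatio:
    def test_first_order_delta(self):
        e = wald_ratio(0.1, 0.01, -0.0139, 0.02)
        assert e.beta == pytest.approx(-0.139)
        assert e.se == pytest.approx(0.2)

    def test_zero_outcome_effect(self):
        assert wald_ratio(0.1, 0.01, 0.0, 0.02).beta == 0.0

    def test_allele_recode_symmetry(self):
        assert wald_ratio(0.1, 0.01, 0.05, 0.02).beta == wald_ratio(-0.1, 0.01, -0.05, 0.02).beta

    def test_zero_bx_is_hard_error(self):
        with pytest.raises(ValueError):
            wald_ratio(0.0, 0.01, 0.05, 0.02)

    def test_second_order_se_is_larger(self):
        first = wald_ratio(0.1, 0.05, 0.02, 0.02)
        second = wald_ratio(0.1, 0.05, 0.02, 0.02, second_order=True)
        assert second.se > first.se


class TestIVW:
    def test_two_snp_hand_wls(self):
        e = ivw(hset([0.1, 0.2], [0.02, 0.03], [0.01, 0.015]), effects_model="fixed")
        assert e.beta == pytest.approx(0.168, abs=1e-3)
        assert e.se == pytest.approx(0.060, abs=1e-3)
        beta_o, se_o = ivw_oracle([0.1, 0.2], [0.02, 0.03], [0.01, 0.015])
        assert e.beta == pytest.approx(beta_o, rel=1e-12)
        assert e.se == pytest.approx(se_o, rel=1e-12)

    def test_single_snp_fixed_equals_wald_ratio(self):
        e = ivw(hset([0.1], [-0.0139], [0.02]), effects_model="fixed")
        w = wald_ratio(0.1, 0.01, -0.0139, 0.02)
        assert e.beta == pytest.approx(w.beta, rel=1e-14)
        assert e.se == pytest.approx(w.se, rel=1e-14)

    def test_identical_ratios_random_equals_fixed(self, homogeneous_set):
        fe = ivw(homogeneous_set, effects_model="fixed")
        re = ivw(homogeneous_set)
        assert re.beta == pytest.approx(0.25, rel=1e-12)
        assert re.se == pytest.approx(fe.se, rel=1e-12)  # Q = 0 limit

    def test_random_effects_se_never_below_fixed(self, rng):
        for _ in range(50):
            h = random_harmonized(rng, j=int(rng.integers(2, 15)), pleiotropy_sd=0.1)
            assert ivw(h).se >= ivw(h, effects_model="fixed").se

    def test_all_zero_bx_is_hard_error(self):
        with pytest.raises(ValueError):
            ivw(hset([0.0, 0.0], [0.01, 0.02], [0.01, 0.01]))


class TestEgger:
    def test_exact_linear_data_recovers_intercept_and_slope(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        by = 0.01 + 0.3 * bx
        e = egger(hset(bx, by, np.full(5, 0.02)))
        assert e.intercept == pytest.approx(0.01, abs=1e-12)
        assert e.beta == pytest.approx(0.3, abs=1e-12)

    def test_orientation_makes_slope_recode_invariant(self, rng):
        h = random_harmonized(rng, j=12)
        sign = np.where(rng.random(12) < 0.5, -1.0, 1.0)
        h2 = HarmonizedSet.from_arrays(h.bx * sign, h.sebx, h.by * sign, h.seby)
        assert egger(h).beta == pytest.approx(egger(h2).beta, rel=1e-10)

    def test_needs_three_snps(self):
        with pytest.raises(ValueError):
            egger(hset([0.1, 0.2], [0.01, 0.02], [0.01, 0.01]))

    def test_intercept_near_zero_without_pleiotropy(self, rng):
        """Mean Egger intercept over replicates is within 2 MC-SE of 0."""
        intercepts = []
        for _ in range(300):
            h = random_harmonized(rng, j=15, theta=0.2)
            h = HarmonizedSet.from_arrays(np.abs(h.bx), h.sebx, h.by * np.sign(h.bx), h.seby)
            intercepts.append(egger(h).intercept)
        intercepts = np.asarray(intercepts)
        mcse = intercepts.std(ddof=1) / np.sqrt(len(intercepts))
        assert abs(intercepts.mean()) < 2 * mcse
        # and the intercept test rarely rejects: homogeneous-data contract
        rej = np.mean([egger(random_harmonized(rng, j=15)).intercept_p < 0.05 for _ in range(100)])
        assert rej <= 0.12


class TestWeightedMedian:
    def test_equal_weight_odd_ratio_set(self):
        e = weighted_median(hset([0.1, 0.1, 0.1], [0.01, 0.02, 0.09], [0.02, 0.02, 0.02]),
                            n_boot=100, seed=1)
        assert e.beta == pytest.approx(0.2, rel=1e-12)

    def test_degenerate_distribution(self):
        bx = np.array([0.1, 0.2, 0.3, 0.15])
        e = weighted_median(hset(bx, 0.5 * bx, np.full(4, 0.02)), n_boot=200, seed=1)
        assert e.beta == pytest.approx(0.5, rel=1e-12)
        assert e.se < 0.2

    def test_matches_explicit_cdf_oracle(self, rng):
        for _ in range(30):
            j = int(rng.integers(3, 12))
            h = random_harmonized(rng, j=j, pleiotropy_sd=0.2)
            r = h.by / h.bx
            w = h.bx**2 / h.seby**2
            expected = weighted_median_oracle(r, w)
            got = weighted_median(h, n_boot=100, seed=2).beta
            assert got == pytest.approx(expected, rel=1e-10)

    def test_zero_bx_snp_dropped_with_warning(self):
        bx = np.array([0.0, 0.1, 0.1, 0.1])
        with pytest.warns(UserWarning):
            e = weighted_median(hset(bx, [0.5, 0.01, 0.02, 0.09], np.full(4, 0.02)),
                                n_boot=100, seed=1)
        assert e.n_snps == 3


class TestWeightedMode:
    def test_majority_cluster_wins(self):
        e = weighted_mode(hset([0.1] * 4, [0.02, 0.02, 0.02, 0.09], np.full(4, 0.02)),
                          n_boot=100, seed=1)
        assert e.beta == pytest.approx(0.2, abs=0.05)

    def test_tight_cluster_center(self):
        bx = np.full(5, 0.1)
        by = np.array([0.0299, 0.03, 0.0301, 0.03, 0.0302])
        e = weighted_mode(hset(bx, by, np.full(5, 0.02)), n_boot=100, seed=1)
        assert e.beta == pytest.approx(0.3, abs=0.01)

    def test_matches_density_grid_oracle(self, rng):
        from mrtea.estimators import _mode_bandwidth
        for _ in range(10):
            h = random_harmonized(rng, j=10, pleiotropy_sd=0.3)
            r = h.by / h.bx
            w = h.bx**2 / h.seby**2
            bw = _mode_bandwidth(r, 1.0)
            expected = mode_grid_oracle(r, w, bw)
            got = weighted_mode(h, n_boot=100, seed=3).beta
            assert got == pytest.approx(expected, abs=max(0.02, bw / 2))


class TestOddsRatioScale:
    def test_null_effect(self):
        e = to_odds_ratio(ivw(hset([0.1], [0.0], [0.01]), effects_model="fixed"))
        orr, lo, hi = e.or_scale
        assert orr == pytest.approx(1.0)
        assert lo == pytest.approx(0.822, abs=1e-3)
        assert hi == pytest.approx(1.216, abs=1e-3)

    def test_printed_result_shape(self):
        """log-OR -0.139 (se 0.0381) prints as OR 0.87, CI 0.81-0.94."""
        e = wald_ratio(1.0, 0.01, -0.139, 0.0381)
        orr, lo, hi = to_odds_ratio(e).or_scale
        assert round(orr, 2) == 0.87
        assert round(lo, 2) == 0.81
        assert round(hi, 2) == 0.94

    def test_monotone_in_beta(self):
        lo = to_odds_ratio(wald_ratio(1, 0.01, -0.1, 0.05)).or_scale[0]
        hi = to_odds_ratio(wald_ratio(1, 0.01, 0.1, 0.05)).or_scale[0]
        assert lo < 1 < hi


class TestOrderAndRecodeInvariance:
    def test_snp_order_invariance(self, rng):
        h = random_harmonized(rng, j=10, pleiotropy_sd=0.1)
        perm = rng.permutation(10)
        hp = HarmonizedSet.from_arrays(h.bx[perm], h.sebx[perm], h.by[perm], h.seby[perm])
        assert ivw(h).beta == pytest.approx(ivw(hp).beta, rel=1e-12)
        assert ivw(h).se == pytest.approx(ivw(hp).se, rel=1e-12)
        assert weighted_median(h, n_boot=50, seed=4).beta == pytest.approx(
            weighted_median(hp, n_boot=50, seed=4).beta, rel=1e-12)
        assert egger(h).beta == pytest.approx(egger(hp).beta, rel=1e-9)

    def test_subset_sign_flip_invariance(self, rng):
        h = random_harmonized(rng, j=10, pleiotropy_sd=0.1)
        sign = np.where(rng.random(10) < 0.5, -1.0, 1.0)
        hf = HarmonizedSet.from_arrays(h.bx * sign, h.sebx, h.by * sign, h.seby)
        assert ivw(h).beta == pytest.approx(ivw(hf).beta, rel=1e-12)
        assert weighted_median(h, n_boot=50, seed=5).beta == pytest.approx(
            weighted_median(hf, n_boot=50, seed=5).beta, rel=1e-12)
        assert weighted_mode(h, n_boot=50, seed=5).beta == pytest.approx(
            weighted_mode(hf, n_boot=50, seed=5).beta, rel=1e-9)
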