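import numpy as np
import pytest
from scipy import stats as sps

from spanfold import (BinaryConfusion, density_log_ratio, log_relative, mcc,
                      positional_profile, rank_sum_z, roc_auc, signed_rank_z)
from spanfold.stats import MetricError, TestResult


class TestMcc:
    @pytest.mark.parametrize(
        "conf,expected",
        [((10, 10, 0, 0), 1.0),
         ((1, 1, 1, 1), 0.0),
         ((2, 3, 1, 1), (2 * 3 - 1 * 1) / np.sqrt(3 * 3 * 4 * 4))],
    )
    def test_closed_form_values(self, conf, expected):
        assert mcc(BinaryConfusion(*conf)) == pytest.approx(expected)

    def test_zero_margin_rejected(self):
        with pytest.raises(MetricError):
            mcc(BinaryConfusion(0, 5, 0, 0))

    def test_negative_count_rejected(self):
        with pytest.raises(MetricError):
            BinaryConfusion(-1, 1, 1, 1)


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_ties_give_half(self):
        assert roc_auc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == 0.5

    def test_four_point_example(self):
        # 4 positive-negative score comparisons, 3 concordant -> 0.75
        assert roc_auc([0.9, 0.8, 0.4, 0.3], [1, 0, 1, 0]) == 0.75

    def test_single_class_rejected(self):
        with pytest.raises(MetricError):
            roc_auc([0.1, 0.2], [1, 1])

    def test_score_negation_symmetry(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=50)
        labels = rng.integers(0, 2, size=50)
        labels[0], labels[1] = 0, 1
        assert roc_auc(scores, labels) == pytest.approx(1 - roc_auc(-scores, labels))

    def test_matches_pair_counting(self):
        rng = np.random.default_rng(1)
        scores = np.round(rng.normal(size=40), 1)  # force some ties
        labels = rng.integers(0, 2, size=40)
        labels[:2] = [0, 1]
        pos, neg = scores[labels == 1], scores[labels == 0]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        assert roc_auc(scores, labels) == pytest.approx(wins / (pos.size * neg.size))


class TestRankSum:
    def test_complete_separation_small_case(self):
        # all of a > all of b with n_a = n_b = 5: U = 25, textbook normal approx
        res = rank_sum_z(np.arange(10, 15), np.arange(5))
        u, mean_u = 25.0, 12.5
        var_u = 5 * 5 * 11 / 12.0
        assert res.z == pytest.approx((u - mean_u) / np.sqrt(var_u))

    def test_antisymmetry_under_sample_swap(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=30), rng.normal(0.3, 1, size=40)
        assert rank_sum_z(a, b).z == pytest.approx(-rank_sum_z(b, a).z)

    def test_binned_input_reproduces_raw_input(self):
        rng = np.random.default_rng(3)
        a = rng.integers(0, 12, size=500).astype(float)
        b = rng.integers(3, 15, size=700).astype(float)
        raw = rank_sum_z(a, b)
        va, ca = np.unique(a, return_counts=True)
        vb, cb = np.unique(b, return_counts=True)
        binned = rank_sum_z(va, vb, counts_a=ca, counts_b=cb)
        assert binned.z == pytest.approx(raw.z, abs=1e-12)
        assert (binned.n_a, binned.n_b) == (raw.n_a, raw.n_b)

    def test_agrees_with_scipy_mannwhitney(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            a = np.round(rng.normal(size=25), 1)
            b = np.round(rng.normal(0.4, 1.2, size=35), 1)
            res = rank_sum_z(a, b)
            ref = sps.mannwhitneyu(a, b, use_continuity=False, alternative="greater",
                                   method="asymptotic")
            z_ref = sps.norm.isf(ref.pvalue)
            assert res.z == pytest.approx(z_ref, abs=1e-6)

    def test_null_calibration(self):
        """Same-distribution samples at n = 10^4: |Z| < 3 in >= 99/100 seeds."""
        ok = 0
        for seed in range(100):
            rng = np.random.default_rng(10_000 + seed)
            a = rng.normal(size=10_000)
            b = rng.normal(size=10_000)
            if abs(rank_sum_z(a, b).z) < 3:
                ok += 1
        assert ok >= 99

    def test_all_tied_rejected(self):
        with pytest.raises(MetricError):
            rank_sum_z([1.0, 1.0], [1.0, 1.0])


class TestSignedRank:
    def test_symmetric_pairs_give_zero(self):
        d = np.array([0.5, -0.5, 1.2, -1.2, 0.3, -0.3])
        assert signed_rank_z(d).z == pytest.approx(0.0)

    def test_all_positive_small_case(self):
        # n = 10, all positive: W = 55, Z = (55 - 27.5)/sqrt(96.25)
        d = np.arange(1.0, 11.0)
        assert signed_rank_z(d).z == pytest.approx((55 - 27.5) / np.sqrt(96.25))

    def test_zeros_dropped(self):
        d = np.array([0.0, 0.0, 1.0, 2.0, 3.0])
        assert signed_rank_z(d).n_a == 3

    def test_all_zero_rejected(self):
        with pytest.raises(MetricError):
            signed_rank_z(np.zeros(5))

    def test_agrees_with_scipy_wilcoxon(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            d = np.round(rng.normal(0.2, 1, size=40), 1)
            d = d[d != 0]
            res = signed_rank_z(d)
            ref = sps.wilcoxon(d, correction=False, alternative="greater",
                               method="approx")
            z_ref = sps.norm.isf(ref.pvalue)
            assert res.z == pytest.approx(z_ref, abs=1e-6)

    def test_bonferroni_threshold(self):
        z = TestResult.bonferroni_z(0.05, 100)
        assert sps.norm.sf(z) == pytest.approx(0.05 / 100)


class TestPositionalProfile:
    def test_single_series_is_identity(self):
        s = np.linspace(0, 1, 11)
        agg = positional_profile([s], anchor=5)
        assert np.allclose(agg.mu, s)

    def test_mean_of_two_series(self):
        agg = positional_profile([np.full(10, 0.2), np.full(10, 0.4)])
        assert np.allclose(agg.mu, 0.3)

    def test_missing_positions_ignored(self):
        a = np.array([0.1, 0.2, np.nan])
        b = np.array([0.3])
        agg = positional_profile([a, b])
        assert agg.mu[0] == pytest.approx(0.2)
        assert agg.mu[1] == pytest.approx(0.2)
        assert np.isnan(agg.mu[2])

    def test_constant_profile_has_zero_log_ratio(self):
        agg = positional_profile([np.full(700, 0.4)], anchor=350)
        lr = log_relative(agg, half_span=300)
        assert np.allclose(lr, 0.0, atol=1e-12)


class TestDensityLogRatio:
    def test_identical_samples_give_zero(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=5000)
        _, lr = density_log_ratio(x, x.copy(), bins=20)
        assert np.abs(lr).max() < 1e-12

    def test_concentrated_vs_uniform_shape(self):
        rng = np.random.default_rng(7)
        a = rng.normal(0, 0.3, size=20_000)
        b = rng.uniform(-3, 3, size=20_000)
        centres, lr = density_log_ratio(a, b, bins=30)
        mid = np.abs(centres) < 0.3
        tail = np.abs(centres) > 2.0
        assert lr[mid].mean() > 0 and lr[tail].mean() < 0

    def test_densities_are_normalised(self):
        rng = np.random.default_rng(8)
        a = rng.normal(size=100)
        b = rng.normal(1, 2, size=300)
        centres, lr = density_log_ratio(a, b, bins=15)
        assert centres.size == lr.size == 15
        assert np.all(np.isfinite(lr))
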