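"""Evaluation criteria, logistic mapping, and the significance machinery."""

import math

import numpy as np
import pytest
from scipy import stats

from enmiqa import (
    ScorePair,
    evaluate_scores,
    fit_logistic,
    jarque_bera,
    krcc,
    plcc,
    residual_f_test,
    rmse,
    srcc,
)


class TestCriteria:
    def test_plcc_hand_value(self):
        assert plcc([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8, abs=1e-12)

    def test_plcc_extremes_and_errors(self):
        mos = np.array([1.0, 2.0, 3.5, 4.0])
        assert plcc(mos, mos) == pytest.approx(1.0)
        assert plcc(-2 * mos + 9, mos) == pytest.approx(-1.0)
        with pytest.raises(ValueError):
            plcc(np.ones(4), mos)

    def test_srcc_hand_value(self):
        # d = (0, 1, 1, 0): 1 - 6*2/(4*15) = 0.8
        assert srcc([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8, abs=1e-12)

    def test_srcc_extremes(self):
        assert srcc([1, 5, 9], [2, 4, 8]) == pytest.approx(1.0)
        assert srcc([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_srcc_closed_form_equals_pearson_on_ranks(self):
        rng = np.random.default_rng(99)
        for _ in range(100):
            m = int(rng.integers(5, 40))
            q = rng.permutation(m).astype(float)  # tie-free by construction
            mos = rng.permutation(m).astype(float)
            closed = srcc(q, mos)
            on_ranks = plcc(stats.rankdata(q), stats.rankdata(mos))
            assert closed == pytest.approx(on_ranks, abs=1e-12)

    def test_srcc_with_ties_matches_scipy(self):
        q = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 4.0])
        mos = np.array([1.0, 1.0, 2.0, 3.0, 3.0, 5.0])
        assert srcc(q, mos) == pytest.approx(stats.spearmanr(q, mos).statistic, abs=1e-12)

    def test_krcc_hand_value(self):
        # 6 pairs: 5 concordant, 1 discordant -> 4/6
        assert krcc([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(4 / 6, abs=1e-12)

    def test_krcc_extremes(self):
        assert krcc([1, 2, 3], [10, 20, 30]) == pytest.approx(1.0)
        assert krcc([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_krcc_enumeration_equals_closed_form_tie_free(self):
        # on tie-free data tau-a equals 2*(n_swaps difference)/... i.e. the
        # scipy tau-b statistic (no tie corrections apply)
        rng = np.random.default_rng(5)
        for _ in range(50):
            m = int(rng.integers(4, 25))
            q = rng.permutation(m).astype(float)
            mos = rng.permutation(m).astype(float)
            assert krcc(q, mos) == pytest.approx(
                stats.kendalltau(q, mos).statistic, abs=1e-12
            )

    def test_krcc_ties_excluded_from_both(self):
        # pair (1,2) tied in Q: only pairs (1,3),(2,3) count, both concordant
        assert krcc([1.0, 1.0, 2.0], [1.0, 2.0, 3.0]) == pytest.approx(2 / 3)

    def test_rmse_hand_values(self):
        mos = np.array([1.0, 2.0, 3.0, 4.0])
        assert rmse(mos, mos) == 0.0
        assert rmse(mos + np.array([1, -1, 1, -1]), mos) == pytest.approx(1.0)
        assert rmse([1.0, 2.0], [2.0, 4.0]) == pytest.approx(math.sqrt(2.5), abs=1e-12)

    def test_rank_criteria_invariant_under_monotone_reparameterization(self):
        rng = np.random.default_rng(17)
        q = rng.uniform(0, 3, 30)
        mos = np.clip(1 + q + rng.normal(0, 0.4, 30), 1, 5)
        g = np.exp(2 * q) + 5 * q  # strictly increasing transform
        assert srcc(g, mos) == pytest.approx(srcc(q, mos), abs=1e-12)
        assert krcc(g, mos) == pytest.approx(krcc(q, mos), abs=1e-12)


class TestLogisticFit:
    def mos_vec(self):
        return np.array([1.0, 1.5, 2.2, 3.0, 3.8, 4.5, 5.0, 2.7])

    def test_identity_recovered_exactly(self):
        mos = self.mos_vec()
        pair = ScorePair(Q=mos.copy(), MOS=mos)
        mapping = fit_logistic(pair)
        assert rmse(mapping(pair.Q), mos) == pytest.approx(0.0, abs=1e-7)

    def test_sign_flip_absorbed(self):
        mos = self.mos_vec()
        pair = ScorePair(Q=-mos, MOS=mos)
        mapping = fit_logistic(pair)
        assert rmse(mapping(pair.Q), mos) == pytest.approx(0.0, abs=1e-7)
        assert plcc(mapping(pair.Q), mos) == pytest.approx(1.0, abs=1e-9)

    def test_constant_q_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fit_logistic(ScorePair(Q=np.ones(8), MOS=self.mos_vec()))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic(ScorePair(Q=np.arange(4.0), MOS=np.array([1.0, 2, 3, 4])))

    def test_recovery_from_known_sigmoid(self):
        rng = np.random.default_rng(42)
        q = rng.uniform(0, 6, 50)
        mos_clean = 2.0 / (1.0 + np.exp(-1.5 * (q - 3.0))) + 1.0
        mos = np.clip(mos_clean + rng.normal(0, 0.05, 50), 1, 5)
        pair = ScorePair(Q=q, MOS=mos)
        mapping = fit_logistic(pair)
        fitted_plcc = plcc(mapping(q), mos)
        noise_free_plcc = plcc(mos_clean, mos)
        assert abs(fitted_plcc - noise_free_plcc) < 0.02

    def test_never_worse_than_linear_fit(self):
        # the linear family (b1 = 0) is nested in the logistic model
        rng = np.random.default_rng(8)
        for _ in range(10):
            q = rng.uniform(0, 10, 25)
            mos = np.clip(1 + 0.35 * q + rng.normal(0, 0.5, 25), 1, 5)
            pair = ScorePair(Q=q, MOS=mos)
            mapping = fit_logistic(pair)
            slope, intercept = np.polyfit(q, mos, 1)
            linear_rmse = rmse(slope * q + intercept, mos)
            assert rmse(mapping(q), mos) <= linear_rmse + 1e-9


class TestSignificance:
    def test_jb_symmetric_residuals_have_zero_skew_term(self):
        x = np.tile([1.0, -1.0], 50)
        res = jarque_bera(x)
        # kurtosis of a two-point symmetric distribution is 1, so
        # JB = n/6 * (1-3)^2/4 = n/6
        assert res.statistic == pytest.approx(len(x) / 6, rel=1e-12)

    def test_jb_normal_sample_retained(self):
        x = np.random.default_rng(1).standard_normal(1000)
        res = jarque_bera(x)
        assert res.is_normal
        # statistic itself matches the scipy implementation
        assert res.statistic == pytest.approx(stats.jarque_bera(x).statistic, rel=1e-10)

    def test_jb_exponential_sample_rejected(self):
        x = np.random.default_rng(2).exponential(size=1000)
        assert not jarque_bera(x).is_normal

    def test_jb_constant_rejected(self):
        with pytest.raises(ValueError):
            jarque_bera(np.ones(100))

    def test_f_test_identical_residuals(self):
        x = np.random.default_rng(3).standard_normal(2000)
        res = residual_f_test(x, x.copy(), seed=0)
        assert res.variance_ratio == pytest.approx(1.0, abs=0.2)
        assert not res.reject_two_sided

    def test_f_test_detects_variance_difference(self):
        rng = np.random.default_rng(4)
        a = rng.standard_normal(5000)
        b = 2.0 * rng.standard_normal(5000)  # var 4
        res = residual_f_test(a, b, seed=1)
        assert res.variance_ratio == pytest.approx(0.25, rel=0.15)
        assert res.reject_two_sided
        assert res.reject_one_sided_less

    def test_f_test_refuses_non_gaussian_residuals(self):
        rng = np.random.default_rng(5)
        a = rng.exponential(size=2000)
        b = rng.standard_normal(2000)
        with pytest.raises(ValueError, match="Jarque-Bera"):
            residual_f_test(a, b, seed=0)

    def test_f_test_seed_reproducibility(self):
        rng = np.random.default_rng(6)
        a = rng.standard_normal(2000)
        b = rng.standard_normal(2000)
        r1 = residual_f_test(a, b, seed=7)
        r2 = residual_f_test(a, b, seed=7)
        assert r1.variance_ratio == r2.variance_ratio


class TestEvaluateScores:
    def test_full_report_on_monotone_data(self):
        rng = np.random.default_rng(12)
        q = rng.uniform(0, 4, 40)
        mos = np.clip(1 + q + rng.normal(0, 0.2, 40), 1, 5)
        report = evaluate_scores(ScorePair(Q=q, MOS=mos))
        assert report.plcc > 0.9
        assert report.srcc > 0.9
        assert report.rmse < 0.5
        assert report.jb is not None
        d = report.to_dict()
        assert set(d) >= {"plcc", "srcc", "krcc", "rmse", "beta"}

    def test_mos_range_validated(self):
        with pytest.raises(ValueError, match=r"\[1, 5\]"):
            ScorePair(Q=np.arange(6.0), MOS=np.array([0.5, 1, 2, 3, 4, 5]))
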