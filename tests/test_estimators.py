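"""Estimator battery: closed forms, oracles, equivariances, bootstraps."""

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st
from scipy import stats

from mrscreen.estimators import (MethodUnavailable, egger, ivw,
                                 ratio_estimates, wald_ratio, weighted_median,
                                 weighted_mode, _weighted_median)
from tests.conftest import make_hset, random_hset


def wls_oracle(pairs, with_intercept):
    """Extended-precision normal-equations WLS, independent of the package."""
    g = pairs.gamma.astype(np.longdouble)
    G = pairs.Gamma.astype(np.longdouble)
    w = pairs.se_Gamma.astype(np.longdouble) ** -2
    if with_intercept:
        s = np.where(g < 0, -1.0, 1.0)
        g, G = s * g, s * G
        X = np.column_stack([np.ones_like(g), g])
    else:
        X = g[:, None]
    XtWX = X.T @ (w[:, None] * X)
    XtWy = X.T @ (w * G)
    coef = np.linalg.solve(XtWX.astype(float), XtWy.astype(float))
    resid = G.astype(float) - X.astype(float) @ coef
    q = float(np.sum(w.astype(float) * resid ** 2))
    cov_fixed = np.linalg.inv(XtWX.astype(float))
    return coef, cov_fixed, q


class TestRatioEstimates:
    def test_unit_ratio(self):
        # exposure and outcome effects both +0.04 => ratio exactly 1
        h = make_hset([0.04], [9.2e-3], [0.04], [0.014])
        r, se = ratio_estimates(h)
        assert r[0] == 1.0 and se[0] == pytest.approx(0.014 / 0.04)

    def test_zero_outcome_gives_zero(self):
        h = make_hset([0.1], [0.02], [0.0], [0.01])
        r, _ = ratio_estimates(h)
        assert r[0] == 0.0

    def test_zero_gamma_names_variant(self):
        h = make_hset([0.1, 0.0], [0.02], [0.1, 0.1], [0.01])
        with pytest.raises(ValueError, match="rs1"):
            ratio_estimates(h)

    def test_second_order_close_for_strong_instruments(self, rng):
        # |gamma|/se_gamma > 20: both delta formulas agree within 1%
        gamma = rng.uniform(0.21, 0.5, 50)
        h = make_hset(gamma, 0.01, 0.2 * gamma, 0.02)
        _, se1 = ratio_estimates(h)
        _, se2 = ratio_estimates(h, second_order=True)
        assert np.all(np.abs(se2 - se1) / se1 < 0.01)


class TestWaldRatio:
    def test_single_pair(self):
        h = make_hset([0.04], [9.2e-3], [0.04], [0.014])
        res = wald_ratio(h)
        assert res.beta == 1.0 and res.n_snp == 1

    def test_multiple_pairs_rejected(self):
        h = make_hset([0.1, 0.2], [0.02], [0.1, 0.1], [0.01])
        with pytest.raises(ValueError, match="ivw"):
            wald_ratio(h)

    def test_linearity(self):
        h1 = make_hset([0.1], [0.02], [0.05], [0.01])
        h2 = make_hset([0.1], [0.02], [0.10], [0.01])
        assert wald_ratio(h2).beta == pytest.approx(2 * wald_ratio(h1).beta)

    def test_p_at_z_1p96(self):
        h = make_hset([1.0], [0.02], [1.96], [1.0])
        assert wald_ratio(h).pvalue == pytest.approx(0.05, abs=1e-3)


class TestIVW:
    def test_single_pair_delegates_to_wald(self):
        h = make_hset([0.04], [9.2e-3], [0.04], [0.014])
        w = wald_ratio(h)
        for mode in ("fixed", "multiplicative_random"):
            r = ivw(h, mode=mode)
            assert (r.beta, r.se, r.pvalue) == (w.beta, w.se, w.pvalue)

    def test_perfect_fit(self, rng):
        gamma = rng.uniform(0.05, 0.3, 6)
        h = make_hset(gamma, 0.01, 0.2 * gamma, 0.01)
        res = ivw(h)
        assert res.beta == pytest.approx(0.2, abs=1e-12)
        assert res.extras["q"] == pytest.approx(0.0, abs=1e-20)
        assert res.extras["phi"] == 1.0

    def test_matches_wls_oracle(self, rng):
        for trial in range(20):
            h = random_hset(np.random.default_rng(trial), J=8)
            coef, cov, q = wls_oracle(h, with_intercept=False)
            fe = ivw(h, mode="fixed")
            assert fe.beta == pytest.approx(float(coef[0]), rel=1e-10)
            assert fe.se == pytest.approx(float(np.sqrt(cov[0, 0])), rel=1e-10)
            mre = ivw(h, mode="multiplicative_random")
            phi = max(1.0, q / (len(h) - 1))
            assert mre.se == pytest.approx(
                float(np.sqrt(cov[0, 0] * phi)), rel=1e-10)

    def test_untruncated_phi_available(self, rng):
        gamma = rng.uniform(0.05, 0.3, 6)
        h = make_hset(gamma, 0.01, 0.2 * gamma, 0.01)  # Q = 0
        res = ivw(h, truncate_phi=False)
        assert res.extras["phi"] == pytest.approx(0.0, abs=1e-20)

    def test_all_zero_gamma_hard_error(self):
        h = make_hset([0.0, 0.0], [0.02], [0.1, 0.2], [0.01])
        with pytest.raises(ValueError):
            ivw(h)


class TestEgger:
    def test_no_pleiotropy_zero_intercept(self, rng):
        gamma = rng.uniform(0.05, 0.4, 8)
        h = make_hset(gamma, 0.01, 0.25 * gamma, 0.01)
        res = egger(h)
        assert res.beta == pytest.approx(0.25, abs=1e-10)
        assert res.extras["egger_intercept"] == pytest.approx(0.0, abs=1e-10)

    def test_affine_recovery(self, rng):
        gamma = rng.uniform(0.05, 0.4, 8)   # all positive: orientation no-op
        c = 0.03
        h = make_hset(gamma, 0.01, c + 0.25 * gamma, 0.01)
        res = egger(h)
        assert res.beta == pytest.approx(0.25, abs=1e-10)
        assert res.extras["egger_intercept"] == pytest.approx(c, abs=1e-10)

    def test_matches_wls_oracle_and_statsmodels(self):
        for trial in range(20):
            h = random_hset(np.random.default_rng(1000 + trial), J=10)
            res = egger(h)
            coef, cov, q = wls_oracle(h, with_intercept=True)
            phi = max(1.0, q / (len(h) - 2))
            assert res.beta == pytest.approx(float(coef[1]), rel=1e-10)
            assert res.extras["egger_intercept"] == pytest.approx(
                float(coef[0]), rel=1e-10, abs=1e-14)
            assert res.se == pytest.approx(
                float(np.sqrt(phi * cov[1, 1])), rel=1e-10)
            # independent route: statsmodels WLS on the oriented pairs
            s = np.where(h.gamma < 0, -1.0, 1.0)
            X = sm.add_constant(s * h.gamma)
            fit = sm.WLS(s * h.Gamma, X, weights=h.se_Gamma ** -2).fit()
            assert res.beta == pytest.approx(fit.params[1], rel=1e-9)

    def test_requires_three_instruments(self):
        h = make_hset([0.1, 0.2], [0.02], [0.1, 0.1], [0.01])
        with pytest.raises(MethodUnavailable):
            egger(h)

    def test_orientation_makes_intercept_identifiable(self, rng):
        """Sign-flipping a pair's coding does not change the Egger fit."""
        gamma = rng.uniform(0.05, 0.4, 6)
        h1 = make_hset(gamma, 0.01, 0.02 + 0.3 * gamma, 0.01)
        gamma2, Gamma2 = gamma.copy(), 0.02 + 0.3 * gamma
        gamma2[2] *= -1
        G2 = Gamma2.copy()
        G2[2] *= -1
        h2 = make_hset(gamma2, 0.01, G2, 0.01)
        r1, r2 = egger(h1), egger(h2)
        assert r1.beta == pytest.approx(r2.beta, rel=1e-12)
        assert r1.extras["egger_intercept"] == pytest.approx(
            r2.extras["egger_intercept"], rel=1e-12)


class TestWeightedMedian:
    def test_equal_weight_median(self):
        h = make_hset([1.0, 1.0, 1.0], 0.02, [0.1, 0.5, 0.9], 1.0)
        res = weighted_median(h, n_boot=100, seed=1)
        assert res.beta == pytest.approx(0.5)

    def test_all_ratios_equal(self):
        h = make_hset([0.1, 0.2, 0.4], 0.01, [0.03, 0.06, 0.12], 0.01)
        res = weighted_median(h, n_boot=200, seed=1)
        assert res.beta == pytest.approx(0.3, abs=1e-12)
        assert res.se > 0

    def test_kernel_midpoint_interpolation(self):
        # hand-computed: weights (1,2,1)/4 -> s = (.125, .5, .875)
        v = np.array([0.1, 0.5, 0.9])
        w = np.array([1.0, 2.0, 1.0])
        assert _weighted_median(v, w) == pytest.approx(0.5)
        w2 = np.array([3.0, 1.0, 1.0])  # s = (.3, .7, .9): interp at .5
        assert _weighted_median(v, w2) == pytest.approx(0.3)

    def test_bootstrap_determinism(self):
        h = make_hset([0.1, 0.2, 0.3, 0.15], 0.01, [0.03, 0.05, 0.08, 0.04],
                      0.01)
        a = weighted_median(h, n_boot=300, seed=7)
        b = weighted_median(h, n_boot=300, seed=7)
        c = weighted_median(h, n_boot=300, seed=8)
        assert a.se == b.se and a.beta == b.beta
        assert a.se != c.se


class TestWeightedMode:
    def test_majority_cluster(self):
        h = make_hset([1.0] * 4, 0.02, [0.2, 0.2, 0.2, 0.9], 1.0)
        res = weighted_mode(h, n_boot=50, seed=1)
        assert res.beta == pytest.approx(0.2, abs=0.05)

    def test_tight_cluster_within_bandwidth(self, rng):
        ratios = 0.4 + rng.normal(0, 0.005, 8)
        h = make_hset(np.ones(8), 0.02, ratios, 1.0)
        res = weighted_mode(h, n_boot=50, seed=1)
        assert abs(res.beta - 0.4) < 0.02

    def test_bimodal_tracks_heavier_component(self):
        """60/40 mass split: the mode follows the 60% component."""
        hits = 0
        for s in range(200):
            rng = np.random.default_rng(s)
            r = np.concatenate([0.2 + rng.normal(0, 0.02, 6),
                                0.8 + rng.normal(0, 0.02, 4)])
            h = make_hset(np.ones(10), 0.02, r, 1.0)
            res = weighted_mode(h, n_boot=2, seed=s)
            hits += abs(res.beta - 0.2) < abs(res.beta - 0.8)
        assert hits >= 190

    def test_bootstrap_determinism(self):
        h = make_hset([0.1, 0.2, 0.3, 0.15], 0.01, [0.03, 0.05, 0.08, 0.04],
                      0.01)
        a = weighted_mode(h, n_boot=100, seed=7)
        b = weighted_mode(h, n_boot=100, seed=7)
        assert a.se == b.se and a.beta == b.beta

    def test_requires_three_instruments(self):
        h = make_hset([0.1, 0.2], [0.02], [0.1, 0.1], [0.01])
        with pytest.raises(MethodUnavailable):
            weighted_mode(h)


ALL_ESTIMATORS = [
    ("ivw_fe", lambda h: ivw(h, mode="fixed")),
    ("ivw_mre", lambda h: ivw(h)),
    ("egger", lambda h: egger(h)),
    ("weighted_median", lambda h: weighted_median(h, n_boot=200, seed=3)),
    ("weighted_mode", lambda h: weighted_mode(h, n_boot=100, seed=3)),
]


@pytest.mark.parametrize("name,fn", ALL_ESTIMATORS)
def test_sign_equivariance(name, fn):
    """Negating every outcome effect negates beta, SEs unchanged.

    The bootstrap SEs of median/mode are compared statistically (the
    negated set resamples with fresh noise realisations), the analytic SEs
    exactly.
    """
    rng = np.random.default_rng(99)
    h = random_hset(rng, J=9)
    neg = make_hset(h.gamma, h.se_gamma, -h.Gamma, h.se_Gamma,
                    p_gamma=h.p_gamma, p_Gamma=h.p_Gamma)
    a, b = fn(h), fn(neg)
    assert b.beta == pytest.approx(-a.beta, rel=1e-9, abs=1e-12)
    if name in ("ivw_fe", "ivw_mre", "egger"):
        assert b.se == pytest.approx(a.se, rel=1e-9)
    else:
        assert b.se == pytest.approx(a.se, rel=0.35)


@pytest.mark.parametrize("name,fn", ALL_ESTIMATORS)
@pytest.mark.parametrize("c", [0.5, 2.0])
def test_scale_equivariance(name, fn, c):
    """Scaling exposure units by c divides every causal estimate by c."""
    rng = np.random.default_rng(7)
    h = random_hset(rng, J=9)
    scaled = make_hset(c * h.gamma, c * h.se_gamma, h.Gamma, h.se_Gamma,
                       p_gamma=h.p_gamma, p_Gamma=h.p_Gamma)
    a, b = fn(h), fn(scaled)
    assert b.beta == pytest.approx(a.beta / c, rel=1e-7)
    assert b.se == pytest.approx(a.se / c, rel=1e-7)
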