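"""Estimator correctness against closed forms, oracles and simulations."""

import numpy as np
import pytest
from scipy import stats as st

import mrchain as mc
from mrchain.estimators import (
    InsufficientInstruments,
    _ivw_core,
    _weighted_ls,
    _weighted_median_point,
    egger,
    ivw,
    mode_estimators,
    wald_ratio,
    weighted_median,
)
from mrchain.models import HarmonizedPair, or_from_beta

from conftest import make_pairs


class TestWaldRatio:
    def test_arithmetic(self):
        p = HarmonizedPair("rs1", 0.5, 0.02, 0.25, 0.1)
        est = wald_ratio(p)
        assert est.beta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.2)

    def test_null_outcome(self):
        est = wald_ratio(HarmonizedPair("rs1", 0.5, 0.02, 0.0, 0.1))
        assert est.beta == 0.0
        assert est.pval == pytest.approx(1.0)

    def test_zero_exposure_rejected(self):
        with pytest.raises(ValueError):
            wald_ratio(HarmonizedPair("rs1", 0.0, 0.02, 0.1, 0.1))

    def test_se_matches_monte_carlo_ratio_sd(self):
        """First-order SE within 2% of the sampled ratio SD at strong F."""
        bx, sx, by, sy = 0.5, 0.02, 0.25, 0.1  # |bx/sx| = 25 > 10
        rng = np.random.default_rng(123)
        draws_by = rng.normal(by, sy, 1_000_000)
        draws_bx = rng.normal(bx, sx, 1_000_000)
        mc_sd = np.std(draws_by / draws_bx, ddof=1)
        est = wald_ratio(HarmonizedPair("rs1", bx, sx, by, sy))
        assert est.se == pytest.approx(mc_sd, rel=0.02)


class TestIVW:
    def test_single_pair_reduces_to_wald(self):
        pair = HarmonizedPair("rs1", 0.5, 0.02, 0.25, 0.1)
        est = ivw([pair])
        wr = wald_ratio(pair)
        assert est.method == "ivw"
        assert est.beta == pytest.approx(wr.beta, abs=1e-15)
        assert est.se == pytest.approx(wr.se, abs=1e-15)

    def test_closed_form_oracle(self, toy_pairs):
        bx = np.array([p.beta_exp for p in toy_pairs])
        by = np.array([p.beta_out for p in toy_pairs])
        sy = np.array([p.se_out for p in toy_pairs])
        expected = np.sum(bx * by / sy**2) / np.sum(bx**2 / sy**2)
        assert ivw(toy_pairs).beta == pytest.approx(expected, abs=1e-10)

    def test_statsmodels_wls_oracle(self, toy_pairs):
        import statsmodels.api as sm

        bx = np.array([p.beta_exp for p in toy_pairs])
        by = np.array([p.beta_out for p in toy_pairs])
        sy = np.array([p.se_out for p in toy_pairs])
        fit = sm.WLS(by, bx, weights=1.0 / sy**2).fit()
        assert ivw(toy_pairs).beta == pytest.approx(fit.params[0], abs=1e-12)

    def test_all_zero_exposure_rejected(self):
        pairs = make_pairs([0.0, 0.0], [0.1, 0.1], [0.1, 0.2], [0.1, 0.1])
        with pytest.raises(ValueError):
            ivw(pairs)

    def test_fixed_vs_random_effects_se(self):
        # heterogeneous ratios: random-effects SE strictly larger
        pairs = make_pairs(
            [0.5, 0.4, 0.3, 0.45], [0.02] * 4, [0.30, 0.02, 0.20, -0.05], [0.03] * 4
        )
        assert ivw(pairs, random_effects=True).se > ivw(pairs, random_effects=False).se
        # homogeneous data: dispersion floored at 1, SEs equal
        bx = np.array([0.5, 0.4, 0.3])
        pairs2 = make_pairs(bx, [0.02] * 3, 0.2 * bx, [0.05] * 3)
        assert ivw(pairs2, random_effects=True).se == pytest.approx(
            ivw(pairs2, random_effects=False).se
        )


class TestEgger:
    def test_exact_line_through_origin(self):
        bx = np.array([0.2, 0.3, 0.4, 0.5])
        pairs = make_pairs(bx, [0.02] * 4, 0.3 * bx, [0.05, 0.04, 0.06, 0.05])
        est = egger(pairs)
        assert abs(est.egger_intercept) < 1e-10
        assert est.beta == pytest.approx(0.3, abs=1e-10)

    def test_wls_closed_form_oracle(self):
        import statsmodels.api as sm

        bx = np.array([0.2, 0.35, 0.4, 0.55])
        by = np.array([0.09, 0.05, 0.21, 0.12])
        sy = np.array([0.05, 0.04, 0.06, 0.05])
        pairs = make_pairs(bx, [0.02] * 4, by, sy)
        fit = sm.WLS(by, sm.add_constant(bx), weights=1.0 / sy**2).fit()
        est = egger(pairs)
        assert est.beta == pytest.approx(fit.params[1], abs=1e-10)
        assert est.egger_intercept == pytest.approx(fit.params[0], abs=1e-10)
        # residual dispersion here exceeds 1, so the floor is inactive and
        # SEs/t-tests agree with the plain WLS fit
        assert fit.scale > 1
        assert est.se == pytest.approx(fit.bse[1], abs=1e-10)
        assert est.egger_intercept_se == pytest.approx(fit.bse[0], abs=1e-10)
        assert est.pval == pytest.approx(fit.pvalues[1], rel=1e-10)

    def test_orientation_forces_nonnegative_exposure(self):
        bx = np.array([0.2, -0.3, 0.4, -0.5])
        by = 0.3 * bx
        pairs = make_pairs(bx, [0.02] * 4, by, [0.05] * 4)
        est = egger(pairs)
        assert est.beta == pytest.approx(0.3, abs=1e-10)

    def test_too_few_instruments(self):
        with pytest.raises(InsufficientInstruments):
            egger(make_pairs([0.5, 0.4], [0.02] * 2, [0.1, 0.1], [0.05] * 2))

    def test_directional_pleiotropy_gives_positive_intercept(self):
        """alpha=+0.05 on every SNP: intercept estimate positive in >=90/100 seeds."""
        positive = 0
        for s in range(100):
            cfg = mc.SimulationConfig(
                n_snps=30, n_exposure=2000, n_mediator=100, n_outcome=2000,
                theta1=0, theta2=0, direct_effect=0.1,
                pleiotropy_fraction=1.0, pleiotropy_sd=1e-9, pleiotropy_mean=0.05,
                seed=81000 + s,
            )
            e, _, o, _ = mc.simulate_cohort(cfg)
            est = egger(mc.harmonize(e, o))
            if est.egger_intercept > 0:
                positive += 1
        assert positive >= 90


class TestWeightedMedian:
    def test_equal_weights_plain_median(self):
        pairs = make_pairs([1.0, 1.0, 1.0], [0.01] * 3, [1.0, 2.0, 3.0], [0.1] * 3)
        assert weighted_median(pairs, n_boot=100, seed=0).beta == pytest.approx(2.0)

    def test_cumulative_weight_interpolation_oracle(self):
        ratios = np.array([0.1, 0.25, 0.3, 0.45, 0.9])
        weights = np.array([3.0, 1.0, 2.0, 5.0, 1.5])
        # brute-force: standardized cumulative weights, linear interpolation
        order = np.argsort(ratios)
        b, w = ratios[order], weights[order]
        cum = (np.cumsum(w) - 0.5 * w) / np.sum(w)
        idx = np.argmax(cum > 0.5)
        expected = b[idx - 1] + (b[idx] - b[idx - 1]) * (0.5 - cum[idx - 1]) / (
            cum[idx] - cum[idx - 1]
        )
        assert _weighted_median_point(ratios, weights) == pytest.approx(
            expected, abs=1e-12
        )

    def test_more_robust_than_ivw_with_half_invalid(self):
        """50% pleiotropic instruments: median beats IVW in >=80/100 seeds."""
        theta, closer = 0.2, 0
        for s in range(100):
            rng = np.random.default_rng(90000 + s)
            k = 20
            bx = rng.uniform(0.2, 0.5, k)
            sx = np.full(k, 0.02)
            sy = np.full(k, 0.03)
            # invalid half: heterogeneous directional pleiotropy
            alpha = np.where(np.arange(k) < k // 2, rng.uniform(0.0, 0.3, k), 0.0)
            by = theta * bx + alpha + rng.normal(0, sy)
            pairs = make_pairs(bx, sx, by, sy)
            wm = weighted_median(pairs, n_boot=50, seed=s).beta
            iv = ivw(pairs).beta
            if abs(wm - theta) < abs(iv - theta):
                closer += 1
        assert closer >= 80


class TestModes:
    def test_degenerate_density_all_ratios_equal(self):
        bx = np.array([0.5, 0.4, 0.25])
        pairs = make_pairs(bx, [1e-7] * 3, 0.7 * bx, [1e-7] * 3)
        simple, weighted = mode_estimators(pairs, n_boot=200, seed=1)
        assert simple.beta == pytest.approx(0.7, abs=1e-6)
        assert weighted.beta == pytest.approx(0.7, abs=1e-6)
        assert simple.se < 1e-5 and weighted.se < 1e-5

    def test_bimodal_majority_cluster_wins_simple_mode(self):
        pairs = make_pairs([1.0] * 5, [0.01] * 5, [1.0, 1.0, 1.0, 5.0, 5.0], [0.1] * 5)
        simple, _ = mode_estimators(pairs, n_boot=50, seed=2)
        assert abs(simple.beta - 1.0) < 1.0

    def test_weighted_mode_tracks_dominant_weight(self):
        # minority cluster at 5 carries overwhelming precision
        pairs = make_pairs(
            [1.0] * 5, [0.01] * 5, [1.0, 1.0, 1.0, 5.0, 5.0],
            [2.0, 2.0, 2.0, 0.01, 0.01],
        )
        _, weighted = mode_estimators(pairs, n_boot=50, seed=3)
        assert abs(weighted.beta - 5.0) < 1.0

    def test_density_grid_oracle(self):
        """KDE mode equals an independently summed Gaussian-mixture argmax."""
        from mrchain.estimators import _kde_mode, _robust_spread

        rng = np.random.default_rng(4)
        r = rng.normal(0.3, 0.1, 9)
        w = rng.uniform(0.5, 2.0, 9)
        w = w / w.sum()
        h = 0.9 * _robust_spread(r) * len(r) ** (-0.2)
        grid = np.linspace(r.min() - 3 * h, r.max() + 3 * h, 512)
        dens = np.zeros_like(grid)
        for ri, wi in zip(r, w):  # explicit mixture sum
            dens += wi * st.norm.pdf(grid, loc=ri, scale=h)
        assert _kde_mode(r, w, h) == pytest.approx(grid[np.argmax(dens)], abs=1e-12)


class TestORTransform:
    @pytest.mark.parametrize("beta,expected", [(0.208, 1.231), (0.131, 1.140)])
    def test_printed_odds_ratios(self, beta, expected):
        orp, lo, hi = or_from_beta(beta, 0.05)
        assert round(orp, 3) == expected

    def test_null_beta_symmetric_ci(self):
        orp, lo, hi = or_from_beta(0.0, 0.1)
        assert orp == pytest.approx(1.0)
        assert lo * hi == pytest.approx(1.0)

    def test_ci_ordering_invariant(self, toy_pairs):
        est = ivw(toy_pairs)
        assert est.or_ci_low <= est.or_point <= est.or_ci_high
        assert est.or_point == pytest.approx(np.exp(est.beta))


class TestEstimatorInvariants:
    def test_scale_equivariance(self, toy_pairs):
        c = 2.5
        scaled = make_pairs(
            [p.beta_exp for p in toy_pairs],
            [p.se_exp for p in toy_pairs],
            [c * p.beta_out for p in toy_pairs],
            [c * p.se_out for p in toy_pairs],
        )
        for fn in (ivw, egger):
            a, b = fn(toy_pairs), fn(scaled)
            assert b.beta == pytest.approx(c * a.beta, rel=1e-12)
            assert b.se == pytest.approx(c * a.se, rel=1e-12)
        a = weighted_median(toy_pairs, n_boot=200, seed=5)
        b = weighted_median(scaled, n_boot=200, seed=5)
        assert b.beta == pytest.approx(c * a.beta, rel=1e-12)
        assert b.se == pytest.approx(c * a.se, rel=1e-9)

    def test_sign_equivariance(self, toy_pairs):
        negated = make_pairs(
            [-p.beta_exp for p in toy_pairs],
            [p.se_exp for p in toy_pairs],
            [p.beta_out for p in toy_pairs],
            [p.se_out for p in toy_pairs],
        )
        for fn in (ivw, egger):
            assert fn(negated).beta == pytest.approx(-fn(toy_pairs).beta, rel=1e-12)

    def test_egger_nests_fixed_effect_ivw(self, toy_pairs):
        """Zero-intercept fixed-effect WLS reproduces the fixed-effect IVW slope."""
        bx = np.array([p.beta_exp for p in toy_pairs])
        by = np.array([p.beta_out for p in toy_pairs])
        sy = np.array([p.se_out for p in toy_pairs])
        slope, _, _, _, _ = _weighted_ls(
            bx, by, 1.0 / sy**2, fit_intercept=False, floor_dispersion=False
        )
        beta_ivw, _, _, _ = _ivw_core(bx, by, sy)
        assert slope == pytest.approx(beta_ivw, abs=1e-10)

    def test_bootstrap_reproducible_under_fixed_seed(self, toy_pairs):
        a = weighted_median(toy_pairs, n_boot=300, seed=11)
        b = weighted_median(toy_pairs, n_boot=300, seed=11)
        assert (a.beta, a.se) == (b.beta, b.se)
        m1 = mode_estimators(toy_pairs, n_boot=300, seed=11)
        m2 = mode_estimators(toy_pairs, n_boot=300, seed=11)
        assert (m1[0].beta, m1[0].se, m1[1].se) == (m2[0].beta, m2[0].se, m2[1].se)


def test_fit_all_respects_preconditions(toy_pairs):
    out = mc.fit_all(toy_pairs, seed=1)
    assert set(out) == {"ivw", "egger", "weighted_median", "simple_mode", "weighted_mode"}
    two = mc.fit_all(toy_pairs[:2], seed=1)
    assert set(two) == {"ivw"}
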