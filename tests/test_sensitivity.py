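"""Diagnostics: Cochran's Q, Egger intercept, MR-PRESSO, Steiger, leave-one-out."""

import numpy as np
import pandas as pd
import pytest

import mrchain as mc
from mrchain.sensitivity import (
    SensitivityGate,
    cochran_q,
    leave_one_out,
    mr_presso,
    run_sensitivity,
    steiger_test,
)
from mrchain.models import SensitivityReport

from conftest import make_pairs


class TestCochranQ:
    def test_identical_ratios_give_zero_q(self):
        bx = np.array([0.5, 0.4, 0.25])
        pairs = make_pairs(bx, [0.02] * 3, 0.3 * bx, [0.05] * 3)
        q = cochran_q(pairs)
        assert q.q_stat == pytest.approx(0.0, abs=1e-12)
        assert q.q_df == 2
        assert q.q_pval == pytest.approx(1.0)

    def test_two_pairs_hand_computed(self):
        pairs = make_pairs([0.5, 0.4], [0.02] * 2, [0.10, 0.12], [0.05, 0.04])
        # hand computation on ratio scale
        r = np.array([0.10 / 0.5, 0.12 / 0.4])
        w = np.array([(0.5 / 0.05) ** 2, (0.4 / 0.04) ** 2])
        beta = (w * r).sum() / w.sum()
        expected = (w * (r - beta) ** 2).sum()
        q = cochran_q(pairs)
        assert q.q_stat == pytest.approx(expected, abs=1e-12)
        from scipy.stats import chi2

        assert q.q_pval == pytest.approx(chi2.sf(expected, 1), abs=1e-12)

    def test_single_pair_not_applicable(self):
        q = cochran_q(make_pairs([0.5], [0.02], [0.1], [0.05]))
        assert q.q_df == 0
        assert np.isnan(q.q_pval)

    def test_per_snp_contributions_sum_to_q(self, toy_pairs):
        bx = np.array([p.beta_exp for p in toy_pairs])
        by = np.array([p.beta_out for p in toy_pairs])
        sy = np.array([p.se_out for p in toy_pairs])
        r, w = by / bx, bx**2 / sy**2
        beta = (w * r).sum() / w.sum()
        contributions = [wi * (ri - beta) ** 2 for wi, ri in zip(w, r)]
        assert sum(contributions) == pytest.approx(cochran_q(toy_pairs).q_stat, abs=1e-9)


class TestMRPresso:
    def test_rss_matches_brute_force_loo_oracle(self):
        import statsmodels.api as sm

        pairs = make_pairs(
            [0.5, 0.4, 0.3, 0.45, 0.35], [0.02] * 5,
            [0.10, 0.09, 0.05, 0.30, 0.08], [0.05, 0.04, 0.06, 0.05, 0.04],
        )
        res = mr_presso(pairs, n_sim=1000, seed=0)
        bx = np.array([p.beta_exp for p in pairs])
        by = np.array([p.beta_out for p in pairs])
        sy = np.array([p.se_out for p in pairs])
        rss = 0.0
        for i in range(5):
            keep = np.arange(5) != i
            fit = sm.WLS(by[keep], bx[keep], weights=1.0 / sy[keep] ** 2).fit()
            rss += (by[i] - fit.params[0] * bx[i]) ** 2 / sy[i] ** 2
        assert res.global_rss == pytest.approx(rss, abs=1e-10)

    def test_deterministic_under_fixed_seed(self, toy_pairs):
        pairs = make_pairs(
            [0.5, 0.4, 0.3, 0.45], [0.02] * 4, [0.10, 0.09, 0.05, 0.12], [0.05] * 4
        )
        a = mr_presso(pairs, n_sim=1000, seed=42)
        b = mr_presso(pairs, n_sim=1000, seed=42)
        assert a.global_p == b.global_p
        assert a.outlier_ids == b.outlier_ids

    def test_too_few_pairs_not_applicable(self):
        res = mr_presso(make_pairs([0.5, 0.4, 0.3], [0.02] * 3, [0.1] * 3, [0.05] * 3))
        assert not res.applicable

    def test_small_n_sim_rejected(self):
        pairs = make_pairs([0.5, 0.4, 0.3, 0.45], [0.02] * 4, [0.1] * 4, [0.05] * 4)
        with pytest.raises(ValueError):
            mr_presso(pairs, n_sim=100)

    def test_flags_gross_outlier_and_corrects_toward_truth(self):
        rng = np.random.default_rng(7)
        k, theta = 30, 0.15
        bx = rng.uniform(0.2, 0.5, k)
        sy = np.full(k, 0.03)
        by = theta * bx + rng.normal(0, sy)
        by[4] *= 10
        pairs = make_pairs(bx, np.full(k, 0.02), by, sy)
        res = mr_presso(pairs, n_sim=2000, seed=1)
        assert "rs4" in res.outlier_ids
        full = mc.ivw(pairs)
        assert abs(res.corrected.beta - theta) < abs(full.beta - theta)
        assert res.distortion_p <= 1.0

    def test_clean_data_global_p_not_extreme(self):
        rng = np.random.default_rng(9)
        k = 20
        bx = rng.uniform(0.2, 0.5, k)
        sy = np.full(k, 0.03)
        by = 0.15 * bx + rng.normal(0, sy)
        res = mr_presso(make_pairs(bx, np.full(k, 0.02), by, sy), n_sim=2000, seed=2)
        assert res.global_p > 0.05
        assert res.outlier_ids == frozenset()


class TestSteiger:
    def test_strong_exposure_null_outcome(self):
        pairs = make_pairs([0.5, 0.4, 0.3], [0.02] * 3, [0.001, 0.002, 0.001], [0.05] * 3)
        direction, p = steiger_test(pairs, n_exp=5000, n_out=5000)
        assert direction is True
        assert p < 1e-10

    def test_antisymmetric_under_swap(self):
        pairs = make_pairs([0.5, 0.4, 0.3], [0.02] * 3, [0.01, 0.02, 0.01], [0.05] * 3)
        swapped = make_pairs([0.01, 0.02, 0.01], [0.05] * 3, [0.5, 0.4, 0.3], [0.02] * 3)
        d1, p1 = steiger_test(pairs, n_exp=5000, n_out=8000)
        d2, p2 = steiger_test(swapped, n_exp=8000, n_out=5000)
        assert d1 != d2
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_invariant_to_common_rescaling(self, toy_pairs):
        c = 3.7
        scaled = make_pairs(
            [c * p.beta_exp for p in toy_pairs],
            [c * p.se_exp for p in toy_pairs],
            [p.beta_out for p in toy_pairs],
            [p.se_out for p in toy_pairs],
        )
        d1, p1 = steiger_test(toy_pairs, 5000, 5000)
        d2, p2 = steiger_test(scaled, 5000, 5000)
        assert d1 == d2
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_missing_sample_size_rejected(self, toy_pairs):
        with pytest.raises(ValueError, match="sample_size_required"):
            steiger_test(toy_pairs, None, 5000)

    def test_pooled_r2_matches_individual_level_oracle(self):
        """Implied r^2 agrees with correlations computed on raw data."""
        import statsmodels.api as sm

        rng = np.random.default_rng(12)
        n, k = 4000, 4
        mafs = rng.uniform(0.2, 0.5, k)
        G = rng.binomial(2, mafs, (n, k)).astype(float)
        gamma = np.array([0.3, 0.25, 0.35, 0.28])
        x = G @ gamma + rng.normal(0, 1, n)
        y = 0.2 * x + rng.normal(0, 1, n)
        rows = []
        for j in range(k):
            fx = sm.OLS(x, sm.add_constant(G[:, j])).fit()
            fy = sm.OLS(y, sm.add_constant(G[:, j])).fit()
            rows.append((fx.params[1], fx.bse[1], fy.params[1], fy.bse[1]))
        pairs = make_pairs(*(list(col) for col in zip(*rows)))
        direction, p = steiger_test(pairs, n_exp=n, n_out=n)
        r2x = sum(np.corrcoef(G[:, j], x)[0, 1] ** 2 for j in range(k))
        r2y = sum(np.corrcoef(G[:, j], y)[0, 1] ** 2 for j in range(k))
        assert direction == (r2x > r2y)
        z_oracle = (np.arctanh(np.sqrt(r2x)) - np.arctanh(np.sqrt(r2y))) / np.sqrt(
            2 / (n - 3)
        )
        from scipy.stats import norm

        assert p == pytest.approx(2 * norm.sf(abs(z_oracle)), rel=0.05)


class TestLeaveOneOut:
    def test_identical_pairs_give_identical_rows(self):
        pairs = make_pairs([0.5] * 3, [0.02] * 3, [0.1] * 3, [0.05] * 3)
        loo = leave_one_out(pairs)
        assert len(loo) == 3
        assert loo["beta"].nunique() == 1
        assert loo["se"].nunique() == 1

    def test_row_count_equals_nsnp(self, toy_pairs):
        assert len(leave_one_out(toy_pairs)) == len(toy_pairs)

    def test_omitting_outlier_shifts_estimate_most(self):
        rng = np.random.default_rng(3)
        k = 15
        bx = rng.uniform(0.3, 0.5, k)
        sy = np.full(k, 0.03)
        by = 0.15 * bx + rng.normal(0, sy)
        by[7] += 0.5
        pairs = make_pairs(bx, np.full(k, 0.02), by, sy)
        loo = leave_one_out(pairs)
        full_beta = mc.ivw(pairs).beta
        shifts = (loo["beta"] - full_beta).abs()
        assert loo.loc[shifts.idxmax(), "omitted_snp"] == "rs7"


class TestGateAndReport:
    def test_run_sensitivity_populates_all_sections(self, small_cohort):
        _, exposure, _, outcome, _ = small_cohort
        pairs = mc.harmonize(exposure, outcome)
        rep = run_sensitivity(pairs, n_exp=2000, n_out=2000, n_sim=1000, seed=0)
        assert rep.q_df == rep.nsnp - 1
        assert np.isfinite(rep.q_pval)
        assert np.isfinite(rep.egger_intercept_p)
        assert np.isfinite(rep.presso_global_p)
        assert rep.steiger_direction is True
        assert len(rep.loo_table) == rep.nsnp

    def test_gate_failure_enumeration(self):
        rep = SensitivityReport(
            nsnp=10, q_pval=0.01, egger_intercept_p=0.01,
            presso_global_p=0.5, steiger_direction=False,
        )
        gate = SensitivityGate()
        ok, failures = gate.evaluate(rep, ivw_random_effects=True)
        assert not ok
        assert failures == ["pleiotropy", "steiger"]
        # heterogeneity matters only under fixed-effect IVW
        ok_fe, failures_fe = gate.evaluate(rep, ivw_random_effects=False)
        assert "heterogeneity" in failures_fe

    def test_gate_criteria_individually_switchable(self):
        rep = SensitivityReport(nsnp=10, egger_intercept_p=0.01, steiger_direction=True)
        ok, _ = SensitivityGate(pleiotropy=False).evaluate(rep)
        assert ok

    def test_presso_sign_concordance_rescues_gate(self):
        rep = SensitivityReport(
            nsnp=10, egger_intercept_p=0.5, steiger_direction=True,
            presso_global_p=0.01, presso_outlier_ids=frozenset({"rs1"}),
            presso_corrected_beta=0.2,
        )
        est = mc.MREstimate.from_beta("ivw", 10, 0.25, 0.05)
        ok, _ = SensitivityGate().evaluate(rep, est)
        assert ok
        est_neg = mc.MREstimate.from_beta("ivw", 10, -0.25, 0.05)
        ok2, failures = SensitivityGate().evaluate(rep, est_neg)
        assert not ok2 and failures == ["presso"]
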