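"""Sensitivity diagnostics attached to every MR fit.

Covers heterogeneity (Cochran's Q), directional pleiotropy (Egger
intercept), outlier instruments (MR-PRESSO global/outlier/distortion tests),
directionality (Steiger) and per-SNP influence (leave-one-out), plus the
configurable pass/fail gate the screening pipeline applies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd
from scipy import stats as _st

from .estimators import InsufficientInstruments, as_arrays, egger, ivw, PairsLike
from .models import MREstimate, SensitivityReport


class QResult(NamedTuple):
    q_stat: float
    q_df: int
    q_pval: float


def cochran_q(pairs: PairsLike) -> QResult:
    """Cochran's Q over per-SNP Wald ratios around the fixed-effect IVW mean.

    Q ~ chi-square with nsnp-1 df under homogeneity.  With a single pair the
    statistic is not applicable and p is reported as nan.
    """
    ids, bx, sx, by, sy = as_arrays(pairs)
    k = len(bx)
    if k < 1:
        raise InsufficientInstruments("cochran_q needs >= 1 instrument")
    ratios = by / bx
    w = bx**2 / sy**2
    beta = float(np.sum(w * ratios) / np.sum(w))
    q = float(np.sum(w * (ratios - beta) ** 2))
    df = k - 1
    p = float(_st.chi2.sf(q, df)) if df > 0 else float("nan")
    return QResult(q, df, p)


def egger_intercept_test(pairs: PairsLike) -> tuple[float, float, float]:
    """Egger intercept, its SE and p — the directional-pleiotropy test."""
    est = egger(pairs)
    return est.egger_intercept, est.egger_intercept_se, est.egger_intercept_p


@dataclass
class PressoResult:
    applicable: bool
    global_rss: float = float("nan")
    global_p: float = float("nan")
    outlier_ids: frozenset = frozenset()
    outlier_pvals: Optional[pd.Series] = None
    corrected: Optional[MREstimate] = None
    distortion_p: float = float("nan")


def _loo_slopes(bx: np.ndarray, by: np.ndarray, sy: np.ndarray) -> np.ndarray:
    """Fixed-effect IVW slope with each SNP left out in turn (vectorized)."""
    w = bx**2 / sy**2
    num = np.sum((by / bx) * w) - (by / bx) * w
    den = np.sum(w) - w
    return num / den


def _presso_rss(bx, by, sy) -> tuple[float, np.ndarray]:
    """Leave-one-out weighted residual sum of squares and per-SNP terms."""
    slopes = _loo_slopes(bx, by, sy)
    resid2 = (by - slopes * bx) ** 2 / sy**2
    return float(np.sum(resid2)), resid2


def mr_presso(
    pairs: PairsLike,
    n_sim: int = 5000,
    outlier_p_threshold: Optional[float] = None,
    seed: int = 0,
    random_effects: bool = True,
) -> PressoResult:
    """MR-PRESSO global, outlier and distortion tests.

    The observed leave-one-out weighted residual sum of squares is compared
    against a null distribution built from ``n_sim`` parametric simulations
    of the per-SNP betas under the fitted (outlier-free) model.  Per-SNP
    residuals yield outlier p-values thresholded at ``outlier_p_threshold``
    (default 0.05/nsnp, Bonferroni-style).  When outliers are found, the
    IVW estimate is recomputed without them and a distortion test compares
    the shift against removals of random same-size SNP subsets.
    """
    ids, bx, sx, by, sy = as_arrays(pairs)
    k = len(bx)
    if k < 4:
        return PressoResult(applicable=False)
    if n_sim < 1000:
        raise ValueError("n_sim must be >= 1000")
    if np.any(sx <= 0) or np.any(sy <= 0):
        raise ValueError("degenerate zero-variance input")
    if outlier_p_threshold is None:
        outlier_p_threshold = 0.05 / k

    rss_obs, resid2_obs = _presso_rss(bx, by, sy)
    slopes = _loo_slopes(bx, by, sy)

    rng = np.random.default_rng(seed)
    BX = rng.normal(bx, sx, size=(n_sim, k))
    BY = rng.normal(slopes * bx, sy, size=(n_sim, k))
    W = BX**2 / sy**2
    R = BY / BX
    num = (R * W).sum(axis=1, keepdims=True) - R * W
    den = W.sum(axis=1, keepdims=True) - W
    loo = num / den
    resid2_sim = (BY - loo * BX) ** 2 / sy**2
    rss_sim = resid2_sim.sum(axis=1)

    global_p = float((np.sum(rss_sim >= rss_obs) + 1) / (n_sim + 1))
    pvals = (np.sum(resid2_sim >= resid2_obs[None, :], axis=0) + 1) / (n_sim + 1)
    outlier_pvals = pd.Series(pvals, index=ids)
    outlier_mask = pvals < outlier_p_threshold
    outlier_ids = frozenset(np.asarray(ids)[outlier_mask])

    corrected = None
    distortion_p = float("nan")
    n_out = int(outlier_mask.sum())
    if n_out and k - n_out >= 2:
        keep = ~outlier_mask
        kept_df = pd.DataFrame(
            {
                "snp_id": np.asarray(ids)[keep],
                "beta_exp": bx[keep],
                "se_exp": sx[keep],
                "beta_out": by[keep],
                "se_out": sy[keep],
            }
        )
        corrected = ivw(kept_df, random_effects=random_effects)
        full = ivw(
            pd.DataFrame(
                {"snp_id": ids, "beta_exp": bx, "se_exp": sx, "beta_out": by, "se_out": sy}
            ),
            random_effects=random_effects,
        )
        if corrected.beta != 0:
            d_obs = abs(full.beta - corrected.beta) / abs(corrected.beta)
            n_draw = min(n_sim, 1000)
            d_null = np.empty(n_draw)
            keep_idx = np.flatnonzero(keep)
            w_all = bx**2 / sy**2
            r_all = by / bx
            sw, swr = float(np.sum(w_all)), float(np.sum(w_all * r_all))
            size = min(n_out, len(keep_idx))
            for i in range(n_draw):
                drop = rng.choice(keep_idx, size=size, replace=False)
                b_sub = (swr - np.sum(w_all[drop] * r_all[drop])) / (
                    sw - np.sum(w_all[drop])
                )
                d_null[i] = abs(full.beta - b_sub) / abs(corrected.beta)
            distortion_p = float((np.sum(d_null >= d_obs) + 1) / (n_draw + 1))

    return PressoResult(
        applicable=True,
        global_rss=rss_obs,
        global_p=global_p,
        outlier_ids=outlier_ids,
        outlier_pvals=outlier_pvals,
        corrected=corrected,
        distortion_p=distortion_p,
    )


def steiger_test(pairs: PairsLike, n_exp: int, n_out: int) -> tuple[bool, float]:
    """Directionality check: do the instruments explain more exposure than outcome?

    Per-instrument variance explained comes from the squared correlation
    implied by the Wald statistic, r^2 = t^2/(t^2 + n - 2); for binary
    outcomes this is a liability-scale approximation.  Direction is TRUE when
    the summed instrument R^2 on the exposure exceeds that on the outcome;
    the p-value is a z-test on the difference of Fisher-transformed pooled
    correlations.
    """
    if n_exp is None or n_out is None or n_exp <= 3 or n_out <= 3:
        raise ValueError("sample_size_required")
    ids, bx, sx, by, sy = as_arrays(pairs)
    t_exp = bx / sx
    t_out = by / sy
    r2_exp = t_exp**2 / (t_exp**2 + n_exp - 2)
    r2_out = t_out**2 / (t_out**2 + n_out - 2)
    R2e = float(np.clip(np.sum(r2_exp), 0.0, 1.0 - 1e-12))
    R2o = float(np.clip(np.sum(r2_out), 0.0, 1.0 - 1e-12))
    direction = R2e > R2o
    z = (np.arctanh(np.sqrt(R2e)) - np.arctanh(np.sqrt(R2o))) / np.sqrt(
        1.0 / (n_exp - 3) + 1.0 / (n_out - 3)
    )
    p = float(2.0 * _st.norm.sf(abs(z)))
    return bool(direction), p


def leave_one_out(pairs: PairsLike, random_effects: bool = True) -> pd.DataFrame:
    """IVW re-estimated omitting each SNP in turn.

    Flags omissions that change the estimate's sign or move it across the
    0.05 significance boundary relative to the full-set fit.
    """
    ids, bx, sx, by, sy = as_arrays(pairs)
    k = len(bx)
    if k < 3:
        raise InsufficientInstruments("leave_one_out needs >= 3 instruments")
    full = ivw(
        pd.DataFrame({"snp_id": ids, "beta_exp": bx, "se_exp": sx, "beta_out": by, "se_out": sy}),
        random_effects=random_effects,
    )
    rows = []
    for i in range(k):
        keep = np.arange(k) != i
        est = ivw(
            pd.DataFrame(
                {
                    "snp_id": ids[keep],
                    "beta_exp": bx[keep],
                    "se_exp": sx[keep],
                    "beta_out": by[keep],
                    "se_out": sy[keep],
                }
            ),
            random_effects=random_effects,
        )
        rows.append(
            {
                "omitted_snp": ids[i],
                "beta": est.beta,
                "se": est.se,
                "pval": est.pval,
                "sign_change": np.sign(est.beta) != np.sign(full.beta),
                "significance_change": (est.pval < 0.05) != (full.pval < 0.05),
            }
        )
    return pd.DataFrame(rows)


def run_sensitivity(
    pairs: PairsLike,
    n_exp: Optional[int] = None,
    n_out: Optional[int] = None,
    n_sim: int = 5000,
    seed: int = 0,
    random_effects: bool = True,
) -> SensitivityReport:
    """Full diagnostic suite; stages whose preconditions fail report nan."""
    ids, bx, sx, by, sy = as_arrays(pairs)
    k = len(bx)
    report = SensitivityReport(nsnp=k)
    if k >= 2:
        q = cochran_q(pairs)
        report.q_stat, report.q_df, report.q_pval = q
    if k >= 3:
        (
            report.egger_intercept,
            report.egger_intercept_se,
            report.egger_intercept_p,
        ) = egger_intercept_test(pairs)
        report.loo_table = leave_one_out(pairs, random_effects=random_effects)
    presso = mr_presso(pairs, n_sim=n_sim, seed=seed, random_effects=random_effects)
    if presso.applicable:
        report.presso_global_p = presso.global_p
        report.presso_outlier_ids = presso.outlier_ids
        if presso.corrected is not None:
            report.presso_corrected_beta = presso.corrected.beta
            report.presso_corrected_se = presso.corrected.se
        report.presso_distortion_p = presso.distortion_p
    if n_exp is not None and n_out is not None:
        report.steiger_direction, report.steiger_p = steiger_test(pairs, n_exp, n_out)
    return report


@dataclass
class SensitivityGate:
    """Configurable retention criteria applied to a sensitivity report.

    An exposure is retained when every enabled criterion holds:
    heterogeneity (Q p > alpha, or waived under random-effects IVW),
    no directional pleiotropy (Egger intercept p > alpha), MR-PRESSO
    (global p > alpha, or no outliers flagged, or the outlier-corrected
    estimate concordant in sign with the original), and Steiger direction
    TRUE.  Criteria are individually switchable.
    """

    heterogeneity: bool = True
    pleiotropy: bool = True
    presso: bool = True
    steiger: bool = True
    alpha: float = 0.05

    def evaluate(
        self,
        report: SensitivityReport,
        ivw_estimate: Optional[MREstimate] = None,
        ivw_random_effects: bool = True,
    ) -> tuple[bool, list[str]]:
        """(passes, list of failed criteria)."""
        failures: list[str] = []
        if self.heterogeneity and not ivw_random_effects:
            if np.isfinite(report.q_pval) and report.q_pval <= self.alpha:
                failures.append("heterogeneity")
        if self.pleiotropy:
            p = report.egger_intercept_p
            if np.isfinite(p) and p <= self.alpha:
                failures.append("pleiotropy")
        if self.presso and np.isfinite(report.presso_global_p):
            ok = report.presso_global_p > self.alpha
            if not ok and not report.presso_outlier_ids:
                ok = True  # nothing to correct
            if not ok and np.isfinite(report.presso_corrected_beta):
                if ivw_estimate is not None and np.sign(
                    report.presso_corrected_beta
                ) == np.sign(ivw_estimate.beta):
                    ok = True
            if not ok:
                failures.append("presso")
        if self.steiger and report.steiger_direction is not None:
            if not report.steiger_direction:
                failures.append("steiger")
        return (not failures), failures
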