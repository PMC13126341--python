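"""Two-sample MR estimators from harmonized summary statistics.

All estimators consume harmonized exposure/outcome betas and SEs, either as a
list of :class:`~mrchain.models.HarmonizedPair` or as a DataFrame with
``beta_exp``/``se_exp``/``beta_out``/``se_out`` columns.  The IVW estimator is
the primary method; MR-Egger, the weighted median, and the simple and
weighted mode estimators serve as pleiotropy-robust complements.
"""

from __future__ import annotations

from typing import Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats as _st

from .models import HarmonizedPair, MREstimate, or_from_beta  # noqa: F401 (re-export)

PairsLike = Union[pd.DataFrame, Sequence[HarmonizedPair]]


class InsufficientInstruments(ValueError):
    """Raised when an estimator is given fewer instruments than it requires."""


def as_arrays(pairs: PairsLike) -> tuple[np.ndarray, ...]:
    """(ids, beta_exp, se_exp, beta_out, se_out) from retained pairs."""
    if isinstance(pairs, pd.DataFrame):
        df = pairs
        if "action" in df.columns:
            df = df[df["action"] != "dropped"]
        ids = df["snp_id"].to_numpy() if "snp_id" in df.columns else np.arange(len(df))
        return (
            np.asarray(ids),
            df["beta_exp"].to_numpy(float),
            df["se_exp"].to_numpy(float),
            df["beta_out"].to_numpy(float),
            df["se_out"].to_numpy(float),
        )
    kept = [p for p in pairs if p.retained]
    return (
        np.array([p.snp_id for p in kept]),
        np.array([p.beta_exp for p in kept]),
        np.array([p.se_exp for p in kept]),
        np.array([p.beta_out for p in kept]),
        np.array([p.se_out for p in kept]),
    )


def wald_ratio(pair: HarmonizedPair) -> MREstimate:
    """Single-SNP causal estimate: beta_out/beta_exp with first-order SE."""
    if pair.beta_exp == 0:
        raise ValueError("wald ratio undefined for beta_exp == 0")
    beta = pair.beta_out / pair.beta_exp
    se = pair.se_out / abs(pair.beta_exp)
    return MREstimate.from_beta("wald_ratio", 1, beta, se)


def _ivw_core(bx, by, sy) -> tuple[float, float, float, int]:
    """Zero-intercept weighted regression of by on bx with weights 1/sy^2.

    Returns (beta, fixed-effect se, multiplicative dispersion, k).
    """
    w = 1.0 / sy**2
    denom = float(np.sum(w * bx * bx))
    if denom == 0:
        raise ValueError("all exposure betas are zero")
    beta = float(np.sum(w * bx * by)) / denom
    se_fe = 1.0 / np.sqrt(denom)
    k = len(bx)
    if k > 1:
        resid = by - beta * bx
        phi = float(np.sum(w * resid**2)) / (k - 1)
    else:
        phi = 1.0
    return beta, se_fe, phi, k


def ivw(pairs: PairsLike, random_effects: bool = True) -> MREstimate:
    """Inverse-variance-weighted estimate (the pipeline's primary method).

    Point estimate is the 1/se_out^2-weighted zero-intercept slope, equal to
    the inverse-variance-weighted mean of the per-SNP Wald ratios.  With
    ``random_effects`` (default) the SE carries a multiplicative residual
    dispersion floored at 1; p-values use the normal approximation.
    """
    ids, bx, sx, by, sy = as_arrays(pairs)
    if len(bx) == 0:
        raise InsufficientInstruments("ivw requires at least 1 instrument")
    beta, se_fe, phi, k = _ivw_core(bx, by, sy)
    se = se_fe * np.sqrt(max(phi, 1.0)) if random_effects else se_fe
    return MREstimate.from_beta("ivw", k, beta, se)


def _weighted_ls(x, y, w, fit_intercept: bool = True, floor_dispersion: bool = True):
    """Weighted least squares via the closed-form normal equations.

    Returns (slope, intercept, se_slope, se_intercept, dof).  The residual
    dispersion multiplying the coefficient covariance is floored at 1 when
    ``floor_dispersion`` (the summary-data MR convention for Egger fits).
    """
    if fit_intercept:
        X = np.column_stack([np.ones_like(x), x])
    else:
        X = x[:, None]
    W = w
    XtWX = X.T @ (W[:, None] * X)
    XtWy = X.T @ (W * y)
    coef = np.linalg.solve(XtWX, XtWy)
    resid = y - X @ coef
    dof = len(x) - X.shape[1]
    phi = float(np.sum(W * resid**2)) / dof if dof > 0 else 1.0
    if floor_dispersion:
        phi = max(phi, 1.0)
    cov = np.linalg.inv(XtWX) * phi
    if fit_intercept:
        intercept, slope = coef
        se_int, se_slope = np.sqrt(np.diag(cov))
    else:
        slope, se_slope = coef[0], float(np.sqrt(cov[0, 0]))
        intercept, se_int = 0.0, float("nan")
    return float(slope), float(intercept), float(se_slope), float(se_int), dof


def egger(pairs: PairsLike) -> MREstimate:
    """MR-Egger: weighted regression with a free intercept.

    Exposure betas are oriented non-negative first (flipping the pair's
    signs), so the intercept estimates the average directional pleiotropy.
    Slope and intercept p-values use the t distribution with nsnp-2 df.
    """
    ids, bx, sx, by, sy = as_arrays(pairs)
    k = len(bx)
    if k < 3:
        raise InsufficientInstruments("insufficient_instruments: egger needs >= 3")
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    bx, by = bx * flip, by * flip
    w = 1.0 / sy**2
    slope, intercept, se_slope, se_int, dof = _weighted_ls(bx, by, w)
    int_p = float(2.0 * _st.t.sf(abs(intercept) / se_int, dof)) if se_int > 0 else float("nan")
    return MREstimate.from_beta(
        "egger",
        k,
        slope,
        se_slope,
        df=dof,
        egger_intercept=intercept,
        egger_intercept_se=se_int,
        egger_intercept_p=int_p,
    )


def _weighted_median_point(b: np.ndarray, w: np.ndarray) -> float:
    """Interpolated weighted median of b with weights w."""
    order = np.argsort(b, kind="mergesort")
    b = b[order]
    w = w[order]
    s = np.cumsum(w) - 0.5 * w
    s = s / np.sum(w)
    below = np.searchsorted(s, 0.5, side="right") - 1
    below = int(np.clip(below, 0, len(b) - 2))
    return float(
        b[below] + (b[below + 1] - b[below]) * (0.5 - s[below]) / (s[below + 1] - s[below])
    )


def weighted_median(pairs: PairsLike, n_boot: int = 1000, seed: int = 0) -> MREstimate:
    """Weighted median of per-SNP Wald ratios with inverse-variance weights.

    Consistent when at least half the weight comes from valid instruments.
    The SE is a seeded parametric bootstrap over the per-SNP betas.
    """
    ids, bx, sx, by, sy = as_arrays(pairs)
    k = len(bx)
    if k < 3:
        raise InsufficientInstruments("weighted_median needs >= 3 instruments")
    ratios = by / bx
    w = bx**2 / sy**2
    beta = _weighted_median_point(ratios, w)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    BX = rng.normal(bx, sx, size=(n_boot, k))
    BY = rng.normal(by, sy, size=(n_boot, k))
    for i in range(n_boot):
        r = BY[i] / BX[i]
        wi = BX[i] ** 2 / sy**2
        boots[i] = _weighted_median_point(r, wi)
    se = float(np.std(boots, ddof=1))
    return MREstimate.from_beta("weighted_median", k, beta, se)


def _robust_spread(r: np.ndarray) -> float:
    sd = float(np.std(r, ddof=1))
    q75, q25 = np.percentile(r, [75, 25])
    iqr_scale = float(q75 - q25) / 1.349
    candidates = [v for v in (sd, iqr_scale) if v > 0]
    return min(candidates) if candidates else 0.0


def _kde_mode(r: np.ndarray, w: np.ndarray, h: float, grid_size: int = 512) -> float:
    """Mode of the Gaussian-kernel-smoothed weighted density of r."""
    if h <= 0 or np.ptp(r) == 0:
        return float(r[0])
    grid = np.linspace(r.min() - 3 * h, r.max() + 3 * h, grid_size)
    dens = (w[None, :] * _st.norm.pdf((grid[:, None] - r[None, :]) / h)).sum(axis=1)
    return float(grid[np.argmax(dens)])


def mode_estimators(
    pairs: PairsLike,
    bandwidth_factor: float = 1.0,
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[MREstimate, MREstimate]:
    """Simple and weighted mode-based estimates of the causal effect.

    The estimate is the mode of the smoothed empirical density of Wald
    ratios — unweighted for the simple mode, inverse-variance weighted for
    the weighted mode.  Kernel bandwidth is ``bandwidth_factor`` times
    ``0.9 * min(SD, IQR/1.349) * k^(-1/5)``; SEs come from a seeded
    parametric bootstrap.
    """
    ids, bx, sx, by, sy = as_arrays(pairs)
    k = len(bx)
    if k < 3:
        raise InsufficientInstruments("mode estimators need >= 3 instruments")
    ratios = by / bx
    se_r = sy / np.abs(bx)

    def bandwidth(r):
        return bandwidth_factor * 0.9 * _robust_spread(r) * len(r) ** (-0.2)

    w_simple = np.full(k, 1.0 / k)
    w_weighted = (1.0 / se_r**2) / np.sum(1.0 / se_r**2)
    b_simple = _kde_mode(ratios, w_simple, bandwidth(ratios))
    b_weighted = _kde_mode(ratios, w_weighted, bandwidth(ratios))

    rng = np.random.default_rng(seed)
    BX = rng.normal(bx, sx, size=(n_boot, k))
    BY = rng.normal(by, sy, size=(n_boot, k))
    boot_s = np.empty(n_boot)
    boot_w = np.empty(n_boot)
    for i in range(n_boot):
        r = BY[i] / BX[i]
        sr = sy / np.abs(BX[i])
        h = bandwidth(r)
        boot_s[i] = _kde_mode(r, np.full(k, 1.0 / k), h)
        ww = (1.0 / sr**2) / np.sum(1.0 / sr**2)
        boot_w[i] = _kde_mode(r, ww, h)
    se_simple = float(np.std(boot_s, ddof=1))
    se_weighted = float(np.std(boot_w, ddof=1))
    if se_simple == 0:
        se_simple = 1e-12
    if se_weighted == 0:
        se_weighted = 1e-12
    return (
        MREstimate.from_beta("simple_mode", k, b_simple, se_simple),
        MREstimate.from_beta("weighted_mode", k, b_weighted, se_weighted),
    )


def fit_all(
    pairs: PairsLike,
    random_effects: bool = True,
    n_boot: int = 1000,
    bandwidth_factor: float = 1.0,
    seed: int = 0,
) -> dict[str, MREstimate]:
    """All five estimators (those whose instrument-count preconditions hold)."""
    ids, bx, sx, by, sy = as_arrays(pairs)
    k = len(bx)
    out: dict[str, MREstimate] = {}
    if k == 0:
        return out
    out["ivw"] = ivw(pairs, random_effects=random_effects)
    if k >= 3:
        out["egger"] = egger(pairs)
        out["weighted_median"] = weighted_median(pairs, n_boot=n_boot, seed=seed)
        simple, weighted = mode_estimators(
            pairs, bandwidth_factor=bandwidth_factor, n_boot=n_boot, seed=seed + 1
        )
        out["simple_mode"] = simple
        out["weighted_mode"] = weighted
    return out
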