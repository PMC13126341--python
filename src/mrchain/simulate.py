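"""Synthetic GWAS summary statistics under a known causal chain.

The generator emulates the statistical structure of two-sample MR inputs:
three (or four) non-overlapping cohorts, each genotyped at the same SNP
panel, with per-SNP marginal regressions producing the beta/SE/p/EAF/N
columns a consumer of public pQTL / metabolite-QTL / GWAS summary data
would see.  The structural model is

    X = G·gamma + e_x                      (exposure)
    M = theta1·X + e_m                     (mediator)
    Y = direct·X + theta2·M + G·alpha + e_y   (outcome; alpha = pleiotropy)

so the total exposure→outcome effect is ``direct + theta1*theta2`` and the
mediated proportion is ``theta1*theta2 / total`` — the ground truth against
which estimator recovery is tested.  Binary outcomes are generated from a
logistic model so outcome betas are log-odds ratios.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace, asdict
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as _st
from scipy.special import expit, logit

from .models import SUMSTATS_COLUMNS

# Non-palindromic allele pairs cycled over the SNP panel by default.
_ALLELE_PAIRS = [("A", "G"), ("C", "T"), ("A", "C"), ("G", "T")]


@dataclass
class SimulationConfig:
    """Generating parameters for a three-trait two-sample simulation.

    Defaults describe a realistic desk-scale study: 30 independent common
    SNPs, 5000 individuals per cohort, per-SNP instrument effects of SD 0.15
    on a unit-variance-noise exposure (per-SNP R^2 of a few percent, mean
    F well above the weak-instrument bound of 10).
    """

    n_snps: int = 30
    n_exposure: int = 5000
    n_mediator: int = 5000
    n_outcome: int = 5000
    maf_range: tuple = (0.05, 0.5)
    instrument_effect_sd: float = 0.15
    theta1: float = 0.2
    theta2: float = 0.15
    direct_effect: float = 0.1
    pleiotropy_fraction: float = 0.0
    pleiotropy_sd: float = 0.0
    pleiotropy_mean: float = 0.0
    n_outliers: int = 0
    outlier_multiplier: float = 1.0
    palindromic_fraction: float = 0.0
    noise_sd_exposure: float = 1.0
    noise_sd_mediator: float = 1.0
    noise_sd_outcome: float = 1.0
    outcome_type: str = "continuous"
    case_fraction: float = 0.056
    ld_block_size: int = 1
    ld_rho: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        for name in ("n_exposure", "n_mediator", "n_outcome"):
            if getattr(self, name) < 100:
                raise ValueError(f"{name} must be >= 100 for stable SEs")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("maf_range must lie within (0, 1)")
        if not 0.0 <= self.pleiotropy_fraction <= 1.0:
            raise ValueError("pleiotropy_fraction must be in [0, 1]")
        if not 0.0 <= self.palindromic_fraction <= 1.0:
            raise ValueError("palindromic_fraction must be in [0, 1]")
        if self.n_outliers < 0 or self.n_outliers > self.n_snps:
            raise ValueError("n_outliers must be in [0, n_snps]")
        for name in (
            "instrument_effect_sd",
            "pleiotropy_sd",
            "noise_sd_exposure",
            "noise_sd_mediator",
            "noise_sd_outcome",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.outcome_type not in ("continuous", "binary"):
            raise ValueError("outcome_type must be 'continuous' or 'binary'")
        if not 0.0 < self.case_fraction < 1.0:
            raise ValueError("case_fraction must be in (0, 1)")
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")
        if not 0.0 <= self.ld_rho < 1.0:
            raise ValueError("ld_rho must be in [0, 1)")

    @property
    def true_total(self) -> float:
        """Total exposure→outcome effect implied by the chain."""
        return self.direct_effect + self.theta1 * self.theta2


@dataclass
class SimulationTruth:
    """Ground truth recorded by the generator for recovery tests."""

    instrument_effects: np.ndarray
    pleiotropic_effects: np.ndarray
    true_theta1: float
    true_theta2: float
    true_direct: float
    true_total: float
    true_proportion: float
    outlier_snp_ids: frozenset = frozenset()
    palindromic_snp_ids: frozenset = frozenset()
    seed: int = 0

    def to_json(self) -> str:
        d = asdict(self)
        d["instrument_effects"] = list(map(float, self.instrument_effects))
        d["pleiotropic_effects"] = list(map(float, self.pleiotropic_effects))
        d["outlier_snp_ids"] = sorted(self.outlier_snp_ids)
        d["palindromic_snp_ids"] = sorted(self.palindromic_snp_ids)
        return json.dumps(d, indent=2)


def _draw_genotypes(
    rng: np.random.Generator,
    n: int,
    mafs: np.ndarray,
    block_size: int = 1,
    rho: float = 0.0,
) -> np.ndarray:
    """Genotypes as Binomial(2, MAF); optionally block-correlated.

    Correlation is induced with a Gaussian copula per haplotype: latent
    normals share a block factor with loading sqrt(rho), thresholded at the
    allele frequency quantile, then summed over two haplotypes.
    """
    k = len(mafs)
    if block_size <= 1 or rho == 0.0:
        return rng.binomial(2, mafs, size=(n, k)).astype(np.float64)
    thr = _st.norm.ppf(mafs)
    g = np.zeros((n, k))
    n_blocks = math.ceil(k / block_size)
    for _ in range(2):  # two haplotypes
        z = np.empty((n, k))
        for b in range(n_blocks):
            cols = slice(b * block_size, min((b + 1) * block_size, k))
            width = cols.stop - cols.start
            shared = rng.normal(size=(n, 1))
            z[:, cols] = math.sqrt(rho) * shared + math.sqrt(1 - rho) * rng.normal(
                size=(n, width)
            )
        g += (z < thr).astype(np.float64)
    return g


def _marginal_ols(G: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, ...]:
    """Simple-regression slope/SE/p of y on each genotype column (with intercept)."""
    n = len(y)
    gc = G - G.mean(axis=0)
    yc = y - y.mean()
    sxx = (gc**2).sum(axis=0)
    sxy = gc.T @ yc
    syy = float(yc @ yc)
    safe = sxx > 0
    beta = np.zeros(G.shape[1])
    beta[safe] = sxy[safe] / sxx[safe]
    rss = np.maximum(syy - beta * sxy, 0.0)
    s2 = rss / (n - 2)
    se = np.full_like(beta, np.inf)
    se[safe] = np.sqrt(s2[safe] / sxx[safe])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, 0.0)
    pval = 2.0 * _st.t.sf(np.abs(t), n - 2)
    return beta, se, pval


def _marginal_logistic(
    G: np.ndarray, y: np.ndarray, max_iter: int = 30, tol: float = 1e-10
) -> tuple[np.ndarray, ...]:
    """Per-SNP logistic regression (intercept + genotype) by vectorized Newton."""
    n, k = G.shape
    ybar = float(np.clip(y.mean(), 1e-9, 1 - 1e-9))
    b0 = np.full(k, logit(ybar))
    b1 = np.zeros(k)
    det = s0 = s1 = s2 = None
    for _ in range(max_iter):
        eta = b0 + G * b1
        mu = expit(eta)
        r = y[:, None] - mu
        g0 = r.sum(axis=0)
        g1 = (G * r).sum(axis=0)
        w = mu * (1.0 - mu)
        s0 = w.sum(axis=0)
        s1 = (w * G).sum(axis=0)
        s2 = (w * G * G).sum(axis=0)
        det = s0 * s2 - s1 * s1
        det = np.where(np.abs(det) < 1e-300, np.nan, det)
        db0 = (s2 * g0 - s1 * g1) / det
        db1 = (s0 * g1 - s1 * g0) / det
        b0 = b0 + db0
        b1 = b1 + db1
        if np.nanmax(np.abs(np.concatenate([db0, db1]))) < tol:
            break
    se1 = np.sqrt(s0 / det)
    with np.errstate(invalid="ignore"):
        z = b1 / se1
    pval = 2.0 * _st.norm.sf(np.abs(z))
    return b1, se1, pval


def _snp_meta(k: int, pal_ids: Optional[set] = None) -> pd.DataFrame:
    ids = [f"rs{i + 1:06d}" for i in range(k)]
    ea, oa = [], []
    for i, sid in enumerate(ids):
        a1, a2 = _ALLELE_PAIRS[i % len(_ALLELE_PAIRS)]
        ea.append(a1)
        oa.append(a2)
    return pd.DataFrame(
        {
            "snp_id": ids,
            "chrom": "1",
            "pos": 500_000 + 1_000_000 * np.arange(k),
            "effect_allele": ea,
            "other_allele": oa,
        }
    )


def _stats_table(meta: pd.DataFrame, G: np.ndarray, beta, se, pval, n: int) -> pd.DataFrame:
    df = meta.copy()
    df["eaf"] = G.mean(axis=0) / 2.0
    df["beta"] = beta
    df["se"] = se
    df["pval"] = pval
    df["n"] = n
    return df[SUMSTATS_COLUMNS]


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, SimulationTruth]:
    """Simulate exposure/mediator/outcome summary statistics plus ground truth.

    Three disjoint cohorts are generated (two-sample design); each trait's
    table comes from marginal simple regressions within its own cohort.
    Artifact injection (palindromic rewrites, outlier inflation) configured
    on ``config`` is applied via :func:`inject_artifacts` before returning.
    """
    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    s_par, s_exp, s_med, s_out, s_art = ss.spawn(5)
    rng_p = np.random.default_rng(s_par)

    k = cfg.n_snps
    mafs = rng_p.uniform(cfg.maf_range[0], cfg.maf_range[1], k)
    gamma = rng_p.normal(0.0, cfg.instrument_effect_sd, k)
    pleio_mask = rng_p.random(k) < cfg.pleiotropy_fraction
    # pleiotropy_mean is on the exposure-increasing-allele scale: a directional
    # (nonzero-mean) effect is aligned with the instrument's sign, which is
    # what the Egger intercept estimates after orientation
    orient = np.where(gamma >= 0, 1.0, -1.0)
    alpha = np.where(
        pleio_mask,
        orient * rng_p.normal(cfg.pleiotropy_mean, cfg.pleiotropy_sd, k),
        0.0,
    )
    meta = _snp_meta(k)

    def draw(rng, n):
        return _draw_genotypes(rng, n, mafs, cfg.ld_block_size, cfg.ld_rho)

    # exposure cohort
    rng = np.random.default_rng(s_exp)
    G = draw(rng, cfg.n_exposure)
    x = G @ gamma + rng.normal(0.0, cfg.noise_sd_exposure, cfg.n_exposure)
    exp_tab = _stats_table(meta, G, *_marginal_ols(G, x), cfg.n_exposure)

    # mediator cohort
    rng = np.random.default_rng(s_med)
    G = draw(rng, cfg.n_mediator)
    x = G @ gamma + rng.normal(0.0, cfg.noise_sd_exposure, cfg.n_mediator)
    m = cfg.theta1 * x + rng.normal(0.0, cfg.noise_sd_mediator, cfg.n_mediator)
    med_tab = _stats_table(meta, G, *_marginal_ols(G, m), cfg.n_mediator)

    # outcome cohort
    rng = np.random.default_rng(s_out)
    G = draw(rng, cfg.n_outcome)
    x = G @ gamma + rng.normal(0.0, cfg.noise_sd_exposure, cfg.n_outcome)
    m = cfg.theta1 * x + rng.normal(0.0, cfg.noise_sd_mediator, cfg.n_outcome)
    liability = cfg.direct_effect * x + cfg.theta2 * m + G @ alpha
    if cfg.outcome_type == "binary":
        eta = logit(cfg.case_fraction) + liability
        y = (rng.random(cfg.n_outcome) < expit(eta)).astype(np.float64)
        out_tab = _stats_table(meta, G, *_marginal_logistic(G, y), cfg.n_outcome)
    else:
        y = liability + rng.normal(0.0, cfg.noise_sd_outcome, cfg.n_outcome)
        out_tab = _stats_table(meta, G, *_marginal_ols(G, y), cfg.n_outcome)

    total = cfg.true_total
    truth = SimulationTruth(
        instrument_effects=gamma,
        pleiotropic_effects=alpha,
        true_theta1=cfg.theta1,
        true_theta2=cfg.theta2,
        true_direct=cfg.direct_effect,
        true_total=total,
        true_proportion=(cfg.theta1 * cfg.theta2 / total) if total != 0 else float("nan"),
        seed=cfg.seed,
    )

    if cfg.palindromic_fraction > 0 or cfg.n_outliers > 0:
        (exp_tab, med_tab, out_tab), truth = inject_artifacts(
            (exp_tab, med_tab, out_tab),
            truth,
            palindromic_fraction=cfg.palindromic_fraction,
            n_outliers=cfg.n_outliers,
            outlier_multiplier=cfg.outlier_multiplier,
            seed=int(s_art.generate_state(1, np.uint32)[0]),
        )
    return exp_tab, med_tab, out_tab, truth


def inject_artifacts(
    tables: tuple,
    truth: SimulationTruth,
    palindromic_fraction: float = 0.0,
    n_outliers: int = 0,
    outlier_multiplier: float = 1.0,
    seed: int = 0,
    missing_eaf_fraction: float = 0.5,
) -> tuple[tuple, SimulationTruth]:
    """Rewrite simulated tables with the failure modes the pipeline must catch.

    A fraction of SNPs is rewritten with A/T or C/G (palindromic) allele
    pairs consistently across all tables, a subset of those losing their
    outcome EAF; ``n_outliers`` SNPs get their outcome beta multiplied by
    ``outlier_multiplier``.  Affected ids are recorded on the returned truth.
    """
    tables = tuple(t.copy() for t in tables)
    k = len(tables[0])
    if n_outliers > k:
        raise ValueError("n_outliers exceeds the number of SNPs")
    if not 0.0 <= palindromic_fraction <= 1.0:
        raise ValueError("palindromic_fraction must be in [0, 1]")
    if palindromic_fraction == 0 and n_outliers == 0:
        return tables, replace(truth)

    rng = np.random.default_rng(seed)
    ids = tables[0]["snp_id"].to_numpy()
    pal_ids: frozenset = truth.palindromic_snp_ids
    out_ids: frozenset = truth.outlier_snp_ids

    if palindromic_fraction > 0:
        n_pal = int(round(palindromic_fraction * k))
        chosen = rng.choice(k, size=n_pal, replace=False)
        pal_pairs = [("A", "T"), ("C", "G")]
        no_freq = rng.random(n_pal) < missing_eaf_fraction
        for j, idx in enumerate(chosen):
            a1, a2 = pal_pairs[j % 2]
            for t in tables:
                t.loc[t.index[idx], ["effect_allele", "other_allele"]] = [a1, a2]
            if no_freq[j]:
                out_tab = tables[-1]
                out_tab.loc[out_tab.index[idx], "eaf"] = np.nan
        pal_ids = pal_ids | frozenset(ids[chosen])

    if n_outliers > 0:
        # Outliers only matter if they reach the estimator, so they are
        # injected among instrument-grade SNPs (exposure p < 5e-8 when
        # enough exist, else the strongest by exposure p).
        exp_tab = tables[0]
        strong = np.flatnonzero(exp_tab["pval"].to_numpy() < 5e-8)
        if len(strong) < n_outliers:
            strong = np.argsort(exp_tab["pval"].to_numpy())[: max(n_outliers, 1)]
        chosen = rng.choice(strong, size=n_outliers, replace=False)
        out_tab = tables[-1]
        out_tab.loc[out_tab.index[chosen], "beta"] *= outlier_multiplier
        out_ids = out_ids | frozenset(ids[chosen])

    return tables, replace(truth, palindromic_snp_ids=pal_ids, outlier_snp_ids=out_ids)


def make_ld_panel(config: SimulationConfig, n_ref: int = 2000):
    """Empirical LD panel from an independent reference cohort.

    Draws a fresh cohort under the same MAFs and block-LD structure as the
    study cohorts (same seed fan-out, dedicated child stream) and returns
    the genotype correlation matrix as an :class:`~mrchain.instruments.LDPanel`.
    """
    from .instruments import LDPanel

    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(6)
    rng_p = np.random.default_rng(children[0])
    mafs = rng_p.uniform(config.maf_range[0], config.maf_range[1], config.n_snps)
    rng_ref = np.random.default_rng(children[5])
    G = _draw_genotypes(rng_ref, n_ref, mafs, config.ld_block_size, config.ld_rho)
    sd = G.std(axis=0)
    sd[sd == 0] = 1.0
    r = np.corrcoef(G, rowvar=False)
    r = np.where(np.isfinite(r), r, 0.0)
    np.fill_diagonal(r, 1.0)
    meta = _snp_meta(config.n_snps)
    return LDPanel(pd.DataFrame(r, index=meta["snp_id"], columns=meta["snp_id"]))


# ---------------------------------------------------------------------------
# Four-trait chain for end-to-end regulatory-axis tests
# ---------------------------------------------------------------------------


@dataclass
class ChainConfig:
    """Generating parameters for an upstream→mediator→metabolite→outcome chain.

    Each trait has its own specific instruments (disjoint SNP blocks).
    Structural model per individual:

        U = G_U·g_U + e_u
        M = theta1·U + G_M·g_M + e_m
        Z = phi1·M + G_Z·g_Z + e_z
        Y = direct_uy·U + direct_my·M + phi2·Z + e_y

    so upstream mediation (U via M on Y) has beta1 = theta1 and
    beta2 = direct_my + phi1·phi2, and downstream mediation (M via Z on Y)
    has beta1 = phi1 and beta2 = phi2.  The default direct effects are zero
    (a pure chain): then any instrument of one trait acts on every
    downstream trait proportionally, so instrument sets selected at
    genome-wide significance stay valid even when a strong upstream SNP
    also reaches significance on a downstream trait.
    """

    n_snps_per_trait: int = 12
    n_per_cohort: int = 5000
    maf_range: tuple = (0.1, 0.5)
    instrument_effect_sd: float = 0.35
    theta1: float = 0.6
    phi1: float = 0.45
    phi2: float = 0.55
    direct_uy: float = 0.0
    direct_my: float = 0.0
    noise_sd: float = 1.0
    outcome_type: str = "continuous"
    case_fraction: float = 0.056
    seed: int = 0

    @property
    def upstream_total(self) -> float:
        return self.direct_uy + self.theta1 * (self.direct_my + self.phi1 * self.phi2)

    @property
    def upstream_proportion(self) -> float:
        return self.theta1 * (self.direct_my + self.phi1 * self.phi2) / self.upstream_total

    @property
    def downstream_proportion(self) -> float:
        return self.phi1 * self.phi2 / (self.direct_my + self.phi1 * self.phi2)


@dataclass
class ChainTruth:
    instrument_effects: dict
    upstream_total: float
    upstream_proportion: float
    downstream_total: float
    downstream_proportion: float
    seed: int


def simulate_chain(config: ChainConfig) -> tuple[dict, ChainTruth]:
    """Simulate four-trait summary statistics over four disjoint cohorts.

    Returns a dict with keys ``"U"``, ``"M"``, ``"Z"``, ``"Y"`` (upstream
    protein, mediator protein, metabolite, outcome) mapping to summary-stat
    tables over the union SNP panel, plus the chain ground truth.
    """
    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    s_par, *cohort_seeds = ss.spawn(5)
    rng_p = np.random.default_rng(s_par)

    kb = cfg.n_snps_per_trait
    k = 3 * kb
    mafs = rng_p.uniform(cfg.maf_range[0], cfg.maf_range[1], k)
    g_u = np.zeros(k)
    g_m = np.zeros(k)
    g_z = np.zeros(k)
    g_u[:kb] = rng_p.normal(0.0, cfg.instrument_effect_sd, kb)
    g_m[kb : 2 * kb] = rng_p.normal(0.0, cfg.instrument_effect_sd, kb)
    g_z[2 * kb :] = rng_p.normal(0.0, cfg.instrument_effect_sd, kb)
    meta = _snp_meta(k)

    def traits(rng, n):
        G = _draw_genotypes(rng, n, mafs)
        u = G @ g_u + rng.normal(0.0, cfg.noise_sd, n)
        m = cfg.theta1 * u + G @ g_m + rng.normal(0.0, cfg.noise_sd, n)
        z = cfg.phi1 * m + G @ g_z + rng.normal(0.0, cfg.noise_sd, n)
        liab = cfg.direct_uy * u + cfg.direct_my * m + cfg.phi2 * z
        return G, {"U": u, "M": m, "Z": z, "_liab": liab}

    tables = {}
    for name, seed_i in zip(("U", "M", "Z", "Y"), cohort_seeds):
        rng = np.random.default_rng(seed_i)
        G, tr = traits(rng, cfg.n_per_cohort)
        if name == "Y":
            if cfg.outcome_type == "binary":
                eta = logit(cfg.case_fraction) + tr["_liab"]
                y = (rng.random(cfg.n_per_cohort) < expit(eta)).astype(np.float64)
                tables[name] = _stats_table(
                    meta, G, *_marginal_logistic(G, y), cfg.n_per_cohort
                )
            else:
                y = tr["_liab"] + rng.normal(0.0, cfg.noise_sd, cfg.n_per_cohort)
                tables[name] = _stats_table(meta, G, *_marginal_ols(G, y), cfg.n_per_cohort)
        else:
            tables[name] = _stats_table(
                meta, G, *_marginal_ols(G, tr[name]), cfg.n_per_cohort
            )

    truth = ChainTruth(
        instrument_effects={"U": g_u, "M": g_m, "Z": g_z},
        upstream_total=cfg.upstream_total,
        upstream_proportion=cfg.upstream_proportion,
        downstream_total=cfg.direct_my + cfg.phi1 * cfg.phi2,
        downstream_proportion=cfg.downstream_proportion,
        seed=cfg.seed,
    )
    return tables, truth


def simulate_screen_panel(
    n_causal: int = 5,
    n_null: int = 15,
    n_snps_per_exposure: int = 8,
    theta: float = 0.25,
    n_per_cohort: int = 5000,
    instrument_effect_sd: float = 0.3,
    maf_range: tuple = (0.1, 0.5),
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[dict, pd.DataFrame, list]:
    """Many exposures against one outcome, for layer-screening tests.

    Each exposure has its own disjoint SNP block and its own cohort; the
    outcome cohort carries all SNPs, with ``Y = sum(theta_e * X_e) + e``
    where ``theta_e = theta`` for the first ``n_causal`` exposures and 0 for
    the rest.  Returns (exposure tables by name, outcome table, causal names).
    """
    ss = np.random.SeedSequence(seed)
    n_exp = n_causal + n_null
    s_par, s_out, *s_cohorts = ss.spawn(2 + n_exp)
    rng_p = np.random.default_rng(s_par)

    kb = n_snps_per_exposure
    k = kb * n_exp
    mafs = rng_p.uniform(maf_range[0], maf_range[1], k)
    gamma = np.zeros((n_exp, k))
    thetas = np.zeros(n_exp)
    names = []
    for e in range(n_exp):
        gamma[e, e * kb : (e + 1) * kb] = rng_p.normal(0.0, instrument_effect_sd, kb)
        thetas[e] = theta if e < n_causal else 0.0
        names.append(f"EXP{e + 1:02d}")
    meta = _snp_meta(k)

    exposures = {}
    for e, (name, s_e) in enumerate(zip(names, s_cohorts)):
        rng = np.random.default_rng(s_e)
        G = _draw_genotypes(rng, n_per_cohort, mafs)
        x = G @ gamma[e] + rng.normal(0.0, noise_sd, n_per_cohort)
        exposures[name] = _stats_table(meta, G, *_marginal_ols(G, x), n_per_cohort)

    rng = np.random.default_rng(s_out)
    G = _draw_genotypes(rng, n_per_cohort, mafs)
    X = G @ gamma.T + rng.normal(0.0, noise_sd, (n_per_cohort, n_exp))
    y = X @ thetas + rng.normal(0.0, noise_sd, n_per_cohort)
    outcome = _stats_table(meta, G, *_marginal_ols(G, y), n_per_cohort)
    return exposures, outcome, names[:n_causal]
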