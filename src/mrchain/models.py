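"""Core record types shared across the pipeline.

Summary-statistics tables are plain :class:`pandas.DataFrame` objects with the
columns in :data:`SUMSTATS_COLUMNS`; the dataclasses here are the typed
single-record views and result containers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Optional

import numpy as np
import pandas as pd
from scipy import stats as _st

#: Canonical column order of a summary-statistics table.
SUMSTATS_COLUMNS = [
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
]

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
#: Allele pairs that are their own strand complement (ambiguous strand).
PALINDROMIC_PAIRS = (frozenset("AT"), frozenset("CG"))


def is_palindromic(a1: str, a2: str) -> bool:
    return frozenset((a1, a2)) in PALINDROMIC_PAIRS


def normal_p(beta: float, se: float) -> float:
    """Two-sided p-value for beta/se under the normal approximation."""
    if se <= 0 or not math.isfinite(se):
        return float("nan")
    return float(2.0 * _st.norm.sf(abs(beta) / se))


@dataclass
class VariantAssociation:
    """One SNP's marginal association with one trait.

    ``beta`` is the per-effect-allele effect; for binary traits it is a
    log-odds ratio. ``eaf`` may be ``nan`` when the source omits frequencies.
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pval: float
    n: int

    def validate(self) -> None:
        if self.effect_allele not in VALID_ALLELES or self.other_allele not in VALID_ALLELES:
            raise ValueError(f"{self.snp_id}: alleles must be A/C/G/T")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: effect and other allele identical")
        if not (self.se > 0):
            raise ValueError(f"{self.snp_id}: se must be > 0")
        if not (0.0 <= self.pval <= 1.0):
            raise ValueError(f"{self.snp_id}: pval outside [0, 1]")
        if not (math.isnan(self.eaf) or 0.0 < self.eaf < 1.0):
            raise ValueError(f"{self.snp_id}: eaf outside (0, 1)")

    @property
    def maf(self) -> float:
        """Effect-allele frequency folded to the minor-allele scale."""
        if math.isnan(self.eaf):
            return float("nan")
        return min(self.eaf, 1.0 - self.eaf)


@dataclass
class HarmonizedPair:
    """An exposure/outcome SNP record aligned to a common effect allele.

    ``action`` records what harmonization did: ``kept`` (orientation already
    shared), ``flipped`` (outcome beta sign inverted, EAF complemented) or
    ``dropped`` (with ``drop_reason``).
    """

    snp_id: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    eaf_exp: float = float("nan")
    eaf_out: float = float("nan")
    action: str = "kept"
    drop_reason: str = ""

    @property
    def retained(self) -> bool:
        return self.action != "dropped"


def pairs_frame(pairs: list[HarmonizedPair], retained_only: bool = True) -> pd.DataFrame:
    """Tabulate harmonized pairs (by default only those reaching estimators)."""
    rows = [p for p in pairs if p.retained or not retained_only]
    return pd.DataFrame(
        {
            "snp_id": [p.snp_id for p in rows],
            "beta_exp": [p.beta_exp for p in rows],
            "se_exp": [p.se_exp for p in rows],
            "beta_out": [p.beta_out for p in rows],
            "se_out": [p.se_out for p in rows],
            "eaf_exp": [p.eaf_exp for p in rows],
            "eaf_out": [p.eaf_out for p in rows],
            "action": [p.action for p in rows],
            "drop_reason": [p.drop_reason for p in rows],
        }
    )


@dataclass
class MREstimate:
    """One estimator's causal estimate on the log-odds (or outcome) scale."""

    method: str
    nsnp: int
    beta: float
    se: float
    pval: float
    or_point: float = float("nan")
    or_ci_low: float = float("nan")
    or_ci_high: float = float("nan")
    egger_intercept: Optional[float] = None
    egger_intercept_se: Optional[float] = None
    egger_intercept_p: Optional[float] = None

    @classmethod
    def from_beta(
        cls,
        method: str,
        nsnp: int,
        beta: float,
        se: float,
        pval: Optional[float] = None,
        df: Optional[int] = None,
        **extra: Any,
    ) -> "MREstimate":
        """Build an estimate, filling p (normal, or t with ``df``) and OR/CI."""
        if pval is None:
            if df is not None:
                pval = float(2.0 * _st.t.sf(abs(beta) / se, df)) if se > 0 else float("nan")
            else:
                pval = normal_p(beta, se)
        orp, lo, hi = or_from_beta(beta, se)
        return cls(
            method=method,
            nsnp=nsnp,
            beta=float(beta),
            se=float(se),
            pval=float(pval),
            or_point=orp,
            or_ci_low=lo,
            or_ci_high=hi,
            **extra,
        )


def or_from_beta(beta: float, se: float) -> tuple[float, float, float]:
    """Odds ratio and Wald 95% CI from a log-odds beta and its SE."""
    if not (se > 0):
        raise ValueError("se must be > 0")
    return (
        float(np.exp(beta)),
        float(np.exp(beta - 1.96 * se)),
        float(np.exp(beta + 1.96 * se)),
    )


@dataclass
class MediationResult:
    """Two-step MR decomposition of a total effect through one mediator."""

    exposure_id: str
    mediator_id: str
    outcome_id: str
    beta_all: float
    se_all: float
    beta1: float
    se1: float
    beta2: float
    se2: float
    beta12: float
    se12: float
    ci12_low: float
    ci12_high: float
    p12: float
    proportion: float
    proportion_ci_low: float
    proportion_ci_high: float

    @property
    def proportion_pct(self) -> float:
        return 100.0 * self.proportion


@dataclass
class SensitivityReport:
    """Heterogeneity, pleiotropy, outlier, directionality and influence diagnostics."""

    nsnp: int
    q_stat: float = float("nan")
    q_df: int = 0
    q_pval: float = float("nan")
    egger_intercept: float = float("nan")
    egger_intercept_se: float = float("nan")
    egger_intercept_p: float = float("nan")
    presso_global_p: float = float("nan")
    presso_outlier_ids: frozenset = frozenset()
    presso_corrected_beta: float = float("nan")
    presso_corrected_se: float = float("nan")
    presso_distortion_p: float = float("nan")
    steiger_direction: Optional[bool] = None
    steiger_p: float = float("nan")
    loo_table: Optional[pd.DataFrame] = None


@dataclass
class CausalEdge:
    """One directed exposure→target MR result inside the screening network."""

    source_id: str
    target_id: str
    layer: str
    estimate: Optional[MREstimate]
    estimates: dict = field(default_factory=dict)
    sensitivity: Optional[SensitivityReport] = None
    lead_snp: str = ""
    passed_gate: bool = False
    status: str = "untestable"
    gate_failures: tuple = ()

    @property
    def passed(self) -> bool:
        return self.status == "passed"


@dataclass
class RegulatoryAxis:
    """An upstream→mediator→outcome axis with downstream metabolite support."""

    upstream_id: str
    mediator_id: str
    outcome_id: str
    upstream_mediation: MediationResult
    downstream_mediations: list = field(default_factory=list)
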