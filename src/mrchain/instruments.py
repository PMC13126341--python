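"""Instrument selection: significance, MAF, LD clumping, instrument strength.

Filters are applied in a fixed order (p-value → MAF → LD clump → F), and every
excluded SNP is logged with the first rule that removed it, so the selected
set plus the exclusion log always partition the input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


@dataclass
class InstrumentCriteria:
    """Thresholds for instrument selection.

    Defaults: genome-wide significance 5e-8, clump r^2 < 0.1 within a
    10,000 kb window, MAF > 0.01 and F >= 10.
    """

    p_threshold: float = 5.0e-8
    r2_threshold: float = 0.1
    clump_window: int = 10_000_000  # base pairs
    maf_min: float = 0.01
    f_min: float = 10.0

    def __post_init__(self) -> None:
        if not 0.0 < self.p_threshold < 1.0:
            raise ValueError("p_threshold must be in (0, 1)")
        if not 0.0 <= self.r2_threshold <= 1.0:
            raise ValueError("r2_threshold must be in [0, 1]")
        if self.clump_window <= 0:
            raise ValueError("clump_window must be positive")
        if not 0.0 <= self.maf_min < 0.5:
            raise ValueError("maf_min must be in [0, 0.5)")
        if self.f_min < 0:
            raise ValueError("f_min must be non-negative")


class LDPanel:
    """Symmetric pairwise-correlation matrix keyed by variant id."""

    def __init__(self, r: pd.DataFrame, tol: float = 1e-12):
        if list(r.index) != list(r.columns):
            raise ValueError("LD matrix index and columns must match")
        vals = r.to_numpy(dtype=float)
        if not np.allclose(np.diag(vals), 1.0, atol=tol):
            raise ValueError("LD matrix diagonal must be exactly 1")
        if np.nanmax(np.abs(vals)) > 1.0 + tol:
            raise ValueError("LD matrix entries must satisfy |r| <= 1")
        if not np.allclose(vals, vals.T, atol=tol):
            raise ValueError("LD matrix must be symmetric")
        self.r = r

    @property
    def variant_ids(self) -> list[str]:
        return list(self.r.index)

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self.r.index

    def r2(self, a: str, b: str) -> float:
        return float(self.r.at[a, b]) ** 2

    @classmethod
    def identity(cls, variant_ids) -> "LDPanel":
        ids = list(variant_ids)
        return cls(pd.DataFrame(np.eye(len(ids)), index=ids, columns=ids))

    @classmethod
    def from_tsv(cls, path) -> "LDPanel":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        df.index.name = None
        df.columns.name = None
        return cls(df)

    def to_tsv(self, path) -> None:
        self.r.to_csv(path, sep="\t", index_label="snp_id")


def f_statistic(beta: float, se: float) -> float:
    """Per-SNP instrument strength, the squared Wald statistic (beta/se)^2."""
    if not se > 0:
        raise ValueError("se must be > 0")
    return (beta / se) ** 2


def _ordered(df: pd.DataFrame) -> pd.DataFrame:
    # Deterministic greedy order: ascending p, ties by position then id.
    return df.sort_values(["pval", "pos", "snp_id"], kind="mergesort")


def _clump_detail(
    df: pd.DataFrame,
    panel: LDPanel,
    criteria: InstrumentCriteria,
    strict_panel: bool = False,
) -> tuple[list[str], dict[str, str]]:
    """Greedy clump of an already p-filtered table; returns (kept, removed->reason)."""
    removed: dict[str, str] = {}
    df = _ordered(df)
    missing = [s for s in df["snp_id"] if s not in panel]
    if missing:
        if strict_panel:
            for s in missing:
                removed[s] = "panel_missing"
            df = df[~df["snp_id"].isin(missing)]
        else:
            log.warning(
                "%d SNP(s) absent from LD panel; treated as independent", len(missing)
            )
    rows = list(df[["snp_id", "chrom", "pos"]].itertuples(index=False))
    kept: list[str] = []
    alive = {r.snp_id for r in rows}
    for idx in rows:
        if idx.snp_id not in alive:
            continue
        kept.append(idx.snp_id)
        alive.discard(idx.snp_id)
        for other in rows:
            if other.snp_id not in alive:
                continue
            if other.chrom != idx.chrom:
                continue
            if abs(int(other.pos) - int(idx.pos)) > criteria.clump_window:
                continue
            if idx.snp_id in panel and other.snp_id in panel:
                r2 = panel.r2(idx.snp_id, other.snp_id)
            else:
                r2 = 0.0
            if r2 >= criteria.r2_threshold:
                removed[other.snp_id] = "ld_clump"
                alive.discard(other.snp_id)
    return kept, removed


def clump(
    stats: pd.DataFrame,
    panel: LDPanel,
    criteria: InstrumentCriteria,
    strict_panel: bool = False,
) -> list[str]:
    """Greedy LD clumping of genome-wide-significant SNPs.

    Sorts significant SNPs by ascending p and repeatedly takes the best
    remaining SNP as index, removing all others within ``clump_window`` of it
    with r^2 >= ``r2_threshold``.  Returns the index-SNP ids.
    """
    sig = stats[stats["pval"] < criteria.p_threshold]
    if sig.empty:
        log.warning("no SNPs pass the significance threshold; nothing to clump")
        return []
    kept, _ = _clump_detail(sig, panel, criteria, strict_panel)
    return kept


def select_instruments(
    stats: pd.DataFrame,
    panel: LDPanel,
    criteria: InstrumentCriteria | None = None,
    strict_panel: bool = False,
) -> tuple[list[str], pd.DataFrame]:
    """Apply p-value, MAF, LD-clump and F filters in order.

    Returns the selected ids (in greedy order) and an exclusion log naming,
    for every dropped SNP, the first rule that removed it
    (``p_threshold`` / ``maf`` / ``panel_missing`` / ``ld_clump`` /
    ``f_statistic``) together with the offending value.
    """
    criteria = criteria or InstrumentCriteria()
    excl: list[tuple[str, str, float]] = []
    df = stats.copy()

    sig = df["pval"] < criteria.p_threshold
    for r in df[~sig].itertuples(index=False):
        excl.append((r.snp_id, "p_threshold", float(r.pval)))
    df = df[sig]

    maf = np.minimum(df["eaf"], 1.0 - df["eaf"])
    maf_ok = ~(maf < criteria.maf_min)  # missing EAF passes (checked downstream)
    for r, m in zip(df[~maf_ok].itertuples(index=False), maf[~maf_ok]):
        excl.append((r.snp_id, "maf", float(m)))
    df = df[maf_ok]

    kept, removed = _clump_detail(df, panel, criteria, strict_panel)
    for snp, reason in removed.items():
        r2v = float("nan") if reason == "panel_missing" else criteria.r2_threshold
        excl.append((snp, reason, r2v))
    df = df.set_index("snp_id").loc[kept].reset_index()

    fstat = (df["beta"] / df["se"]) ** 2
    f_ok = fstat >= criteria.f_min
    for r, f in zip(df[~f_ok].itertuples(index=False), fstat[~f_ok]):
        excl.append((r.snp_id, "f_statistic", float(f)))
    selected = list(df[f_ok]["snp_id"])

    log_df = pd.DataFrame(excl, columns=["snp_id", "rule", "value"])
    if not selected:
        log.warning("zero instruments survive selection; exposure is untestable")
    return selected, log_df


def write_exclusion_log(log_df: pd.DataFrame, path) -> None:
    log_df.to_csv(path, sep="\t", index=False)
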