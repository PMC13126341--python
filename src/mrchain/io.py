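"""Reading and writing the pipeline's tab-delimited formats.

Summary statistics travel as TSV with the columns in
:data:`mrchain.models.SUMSTATS_COLUMNS`; missing EAF is written as ``NA``.
Float columns round-trip exactly (shortest-repr formatting on write).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as _st

from .models import SUMSTATS_COLUMNS, VALID_ALLELES

log = logging.getLogger(__name__)

_NA_VALUES = ["NA", "nan", ""]


def read_sumstats(
    path,
    column_map: dict | None = None,
    strict: bool = False,
) -> pd.DataFrame:
    """Read and validate a summary-statistics TSV.

    ``column_map`` renames nonstandard headers to the canonical names.  Rows
    violating per-variant invariants (bad alleles, se <= 0, p outside [0,1],
    EAF outside (0,1)) are dropped with a logged reason, or raise in
    ``strict`` mode.  A p-value inconsistent with |beta/se| under the normal
    approximation (beyond 10% relative) is warned about but never dropped.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"chrom": str},
        na_values=_NA_VALUES,
        keep_default_na=False,
        float_precision="round_trip",
    )
    if column_map:
        df = df.rename(columns=column_map)
    for col in SUMSTATS_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing mandatory column '{col}'")
    df = df[SUMSTATS_COLUMNS].copy()
    df["snp_id"] = df["snp_id"].astype(str)
    if df["snp_id"].duplicated().any():
        dups = df.loc[df["snp_id"].duplicated(), "snp_id"].tolist()
        raise ValueError(f"duplicate snp_id values: {dups[:5]}")

    bad = pd.Series(np.full(len(df), "", dtype=object), index=df.index)
    allele_ok = df["effect_allele"].isin(list(VALID_ALLELES)) & df["other_allele"].isin(
        list(VALID_ALLELES)
    ) & (df["effect_allele"] != df["other_allele"])
    bad[~allele_ok] = "invalid_alleles"
    se_ok = (df["se"] > 0) & np.isfinite(df["se"])
    bad[se_ok.eq(False) & bad.eq("")] = "nonpositive_se"
    p_ok = (df["pval"] >= 0) & (df["pval"] <= 1)
    bad[p_ok.eq(False) & bad.eq("")] = "pval_out_of_range"
    eaf_ok = df["eaf"].isna() | ((df["eaf"] > 0) & (df["eaf"] < 1))
    bad[eaf_ok.eq(False) & bad.eq("")] = "eaf_out_of_range"
    n_ok = df["n"] > 0
    bad[n_ok.eq(False) & bad.eq("")] = "nonpositive_n"

    invalid = bad != ""
    if invalid.any():
        if strict:
            first = df.loc[invalid, "snp_id"].iloc[0]
            raise ValueError(f"invalid row for {first}: {bad[invalid].iloc[0]}")
        for snp, reason in zip(df.loc[invalid, "snp_id"], bad[invalid]):
            log.warning("dropping %s: %s", snp, reason)
        df = df[~invalid].reset_index(drop=True)

    with np.errstate(divide="ignore", invalid="ignore"):
        expected = 2.0 * _st.norm.sf(np.abs(df["beta"] / df["se"]))
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.abs(df["pval"] - expected) / np.where(expected > 0, expected, np.nan)
    n_inconsistent = int(np.nansum(rel > 0.10))
    if n_inconsistent:
        log.warning(
            "%d p-value(s) deviate >10%% from the normal approximation of |beta/se|",
            n_inconsistent,
        )
    df.attrs["n_dropped"] = int(invalid.sum())
    return df


def write_sumstats(df: pd.DataFrame, path) -> None:
    out = df[SUMSTATS_COLUMNS].copy()
    for col in ("eaf", "beta", "se", "pval"):
        # shortest round-trip representation so read(write(df)) is exact
        out[col] = [
            "NA" if pd.isna(v) else repr(float(v)) for v in out[col]
        ]
    out.to_csv(path, sep="\t", index=False, na_rep="NA")
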