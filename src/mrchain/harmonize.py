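"""Allele harmonization between exposure and outcome summary statistics.

Aligns each shared SNP to the exposure's effect allele, resolving strand
flips by complement matching and palindromic (A/T, C/G) SNPs by effect-allele
frequency.  Every shared SNP gets exactly one action: kept, flipped, or
dropped with a reason.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Union

import numpy as np
import pandas as pd

from .models import COMPLEMENT, HarmonizedPair, VariantAssociation, is_palindromic

log = logging.getLogger(__name__)

#: Default half-width of the palindromic ambiguity band around EAF 0.5.
DEFAULT_AMBIGUITY_BAND = 0.08

TableLike = Union[pd.DataFrame, Iterable[VariantAssociation]]


def _as_frame(table: TableLike, label: str) -> pd.DataFrame:
    if isinstance(table, pd.DataFrame):
        df = table
    else:
        df = pd.DataFrame([vars(v) for v in table])
    if df["snp_id"].duplicated().any():
        dups = df.loc[df["snp_id"].duplicated(), "snp_id"].tolist()
        raise ValueError(f"duplicate snp_id in {label} table: {dups[:5]}")
    return df.set_index("snp_id")


def harmonize(
    exposure: TableLike,
    outcome: TableLike,
    ambiguity_band: float = DEFAULT_AMBIGUITY_BAND,
) -> list[HarmonizedPair]:
    """Harmonize exposure and outcome records to a common effect allele.

    For each shared snp_id:

    * identical alleles → kept;
    * swapped alleles → flipped (outcome beta negated, EAF complemented);
    * strand-complement (or complement-swapped) alleles → kept (or flipped);
    * otherwise → dropped ``incompatible_alleles``;
    * palindromic SNPs are oriented purely from allele frequencies: dropped
      ``palindromic_no_freq`` if either EAF is missing; kept if both EAFs sit
      on the same side of 0.5 and outside ``0.5 ± ambiguity_band``; flipped
      if on opposite sides and outside the band; otherwise dropped
      ``palindromic_ambiguous``.
    """
    exp = _as_frame(exposure, "exposure")
    out = _as_frame(outcome, "outcome")
    shared = [s for s in exp.index if s in out.index]
    if not shared:
        log.warning("exposure and outcome share no SNPs; nothing to harmonize")
        return []

    pairs: list[HarmonizedPair] = []
    for snp in shared:
        e = exp.loc[snp]
        o = out.loc[snp]
        e_ea, e_oa = e["effect_allele"], e["other_allele"]
        o_ea, o_oa = o["effect_allele"], o["other_allele"]
        pair = HarmonizedPair(
            snp_id=snp,
            beta_exp=float(e["beta"]),
            se_exp=float(e["se"]),
            beta_out=float(o["beta"]),
            se_out=float(o["se"]),
            eaf_exp=float(e["eaf"]),
            eaf_out=float(o["eaf"]),
        )

        if is_palindromic(e_ea, e_oa):
            same_pair = frozenset((o_ea, o_oa)) == frozenset((e_ea, e_oa))
            if not same_pair:
                _drop(pair, "incompatible_alleles")
            elif math.isnan(pair.eaf_exp) or math.isnan(pair.eaf_out):
                _drop(pair, "palindromic_no_freq")
            else:
                de = pair.eaf_exp - 0.5
                do = pair.eaf_out - 0.5
                if abs(de) <= ambiguity_band or abs(do) <= ambiguity_band:
                    _drop(pair, "palindromic_ambiguous")
                elif de * do > 0:
                    pair.action = "kept"
                else:
                    _flip(pair)
        else:
            comp_ea, comp_oa = COMPLEMENT[e_ea], COMPLEMENT[e_oa]
            if (o_ea, o_oa) == (e_ea, e_oa) or (o_ea, o_oa) == (comp_ea, comp_oa):
                pair.action = "kept"
            elif (o_ea, o_oa) == (e_oa, e_ea) or (o_ea, o_oa) == (comp_oa, comp_ea):
                _flip(pair)
            else:
                _drop(pair, "incompatible_alleles")
        pairs.append(pair)
    return pairs


def _flip(pair: HarmonizedPair) -> None:
    pair.action = "flipped"
    pair.beta_out = -pair.beta_out
    if not math.isnan(pair.eaf_out):
        pair.eaf_out = 1.0 - pair.eaf_out


def _drop(pair: HarmonizedPair, reason: str) -> None:
    pair.action = "dropped"
    pair.drop_reason = reason


def audit_frame(pairs: list[HarmonizedPair]) -> pd.DataFrame:
    """Harmonization audit: one row per shared SNP with the action taken."""
    return pd.DataFrame(
        {
            "snp_id": [p.snp_id for p in pairs],
            "action": [p.action for p in pairs],
            "drop_reason": [p.drop_reason for p in pairs],
        }
    )


def write_audit(pairs: list[HarmonizedPair], path) -> None:
    audit_frame(pairs).to_csv(path, sep="\t", index=False)
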