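"""Two-step MR mediation: effect decomposition, delta-method inference, screening.

The mediation effect through a candidate mediator is the product of the
exposure→mediator effect (beta1) and the mediator→outcome effect (beta2);
the mediated proportion is beta1*beta2 / beta_all, with beta_all the total
exposure→outcome effect.  Standard errors for the product use the delta
method; the two legs are treated as independent, as in a two-sample design
with distinct instrument sets and cohorts.
"""

from __future__ import annotations

import math

import numpy as np

from .models import MediationResult, normal_p


def two_step_mediation(
    beta_all: float,
    se_all: float,
    beta1: float,
    se1: float,
    beta2: float,
    se2: float,
    exposure_id: str = "",
    mediator_id: str = "",
    outcome_id: str = "",
    exact_variance: bool = False,
    propagate_total: bool = False,
) -> MediationResult:
    """Decompose a total effect into the indirect path through one mediator.

    ``se12`` is the first-order delta-method SE
    ``sqrt(beta1^2 se2^2 + beta2^2 se1^2)`` (the exact-product variance adds
    ``se1^2 se2^2`` under ``exact_variance``).  The proportion CI divides the
    beta12 CI by a fixed beta_all; with ``propagate_total`` the uncertainty
    in beta_all is propagated instead via a full delta-method ratio variance.
    With beta_all == 0 the mediation effect is still returned and the
    proportion reported as undefined (nan).
    """
    for name, se in (("se_all", se_all), ("se1", se1), ("se2", se2)):
        if not se > 0:
            raise ValueError(f"{name} must be > 0")

    beta12 = beta1 * beta2
    var12 = beta1**2 * se2**2 + beta2**2 * se1**2
    if exact_variance:
        var12 += se1**2 * se2**2
    se12 = math.sqrt(var12)
    ci12_low = beta12 - 1.96 * se12
    ci12_high = beta12 + 1.96 * se12
    p12 = normal_p(beta12, se12) if se12 > 0 else (1.0 if beta12 == 0 else 0.0)

    if beta_all == 0:
        proportion = prop_lo = prop_hi = float("nan")
    elif propagate_total:
        proportion = beta12 / beta_all
        grad_var = (
            (beta2 / beta_all) ** 2 * se1**2
            + (beta1 / beta_all) ** 2 * se2**2
            + (beta12 / beta_all**2) ** 2 * se_all**2
        )
        se_prop = math.sqrt(grad_var)
        prop_lo = proportion - 1.96 * se_prop
        prop_hi = proportion + 1.96 * se_prop
    else:
        proportion = beta12 / beta_all
        bounds = sorted((ci12_low / beta_all, ci12_high / beta_all))
        prop_lo, prop_hi = bounds

    return MediationResult(
        exposure_id=exposure_id,
        mediator_id=mediator_id,
        outcome_id=outcome_id,
        beta_all=beta_all,
        se_all=se_all,
        beta1=beta1,
        se1=se1,
        beta2=beta2,
        se2=se2,
        beta12=beta12,
        se12=se12,
        ci12_low=ci12_low,
        ci12_high=ci12_high,
        p12=p12,
        proportion=proportion,
        proportion_ci_low=prop_lo,
        proportion_ci_high=prop_hi,
    )


def screen_mediators(
    results: list[MediationResult],
    p_max: float = 0.05,
    proportion_min: float = 0.15,
) -> list[MediationResult]:
    """Prioritize mediations with p12 < p_max and proportion > proportion_min.

    Negative (inconsistent) proportions never pass.  Output is ordered by
    ascending mediation p-value.
    """
    kept = [
        r
        for r in results
        if np.isfinite(r.proportion)
        and r.p12 < p_max
        and r.proportion > proportion_min
    ]
    return sorted(kept, key=lambda r: r.p12)
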