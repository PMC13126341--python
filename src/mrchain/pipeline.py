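"""Three-layer screening pipeline for regulatory-axis discovery.

Orchestrates the per-exposure MR workflow (instrument selection →
harmonization → five estimators → sensitivity suite), the layer screens
against the outcome, and the combined upstream/downstream mediation rule
that retains an upstream→mediator axis only when at least one screened
metabolite mediator supports the mediator→outcome leg.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .estimators import fit_all
from .harmonize import DEFAULT_AMBIGUITY_BAND, harmonize
from .instruments import InstrumentCriteria, LDPanel, select_instruments
from .mediation import screen_mediators, two_step_mediation
from .models import CausalEdge, MediationResult, RegulatoryAxis
from .sensitivity import SensitivityGate, run_sensitivity

log = logging.getLogger(__name__)

LAYER_EXPOSURE_OUTCOME = "exposure→outcome"
LAYER_UPSTREAM_DOWNSTREAM = "upstream→downstream"
LAYER_PROTEIN_METABOLITE = "protein→metabolite"
LAYER_METABOLITE_OUTCOME = "metabolite→outcome"


@dataclass
class PipelineConfig:
    """All thresholds of the pipeline, with the study defaults."""

    criteria: InstrumentCriteria = field(default_factory=InstrumentCriteria)
    gate: SensitivityGate = field(default_factory=SensitivityGate)
    ambiguity_band: float = DEFAULT_AMBIGUITY_BAND
    random_effects: bool = True
    n_boot: int = 1000
    presso_n_sim: int = 5000
    layer_alpha: float = 0.05
    mediation_p_max: float = 0.05
    mediation_proportion_min: float = 0.15
    propagate_total: bool = False
    seed: int = 0

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        d = dict(d)
        crit = InstrumentCriteria(**d.pop("criteria", {}))
        gate = SensitivityGate(**d.pop("gate", {}))
        return cls(criteria=crit, gate=gate, **d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return asdict(self)


def _child_seed(base_seed: int, *labels: str) -> int:
    """Stable per-task seed independent of iteration order (< 2^31)."""
    h = 0
    for lab in labels:
        h = zlib.crc32(lab.encode(), h)
    return int(np.random.SeedSequence([base_seed, h]).generate_state(1, np.uint32)[0] % (2**31))


@dataclass
class PairFit:
    """Everything computed for one exposure/outcome pair."""

    exposure_id: str
    outcome_id: str
    status: str
    instruments: list
    exclusion_log: pd.DataFrame
    pairs: list = field(default_factory=list)
    estimates: dict = field(default_factory=dict)
    sensitivity: object = None
    lead_snp: str = ""


def fit_pair(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    panel: Optional[LDPanel],
    config: PipelineConfig,
    exposure_id: str = "exposure",
    outcome_id: str = "outcome",
    seed: Optional[int] = None,
) -> PairFit:
    """Run the full single-pair MR workflow.

    Selects instruments on the exposure, harmonizes against the outcome,
    fits all estimators whose preconditions hold and attaches the
    sensitivity suite.  ``status`` is ``"untestable"`` when no harmonized
    instrument survives.
    """
    if panel is None:
        panel = LDPanel.identity(exposure["snp_id"])
    if seed is None:
        seed = _child_seed(config.seed, exposure_id, outcome_id)
    selected, excl = select_instruments(exposure, panel, config.criteria)
    result = PairFit(
        exposure_id=exposure_id,
        outcome_id=outcome_id,
        status="untestable",
        instruments=selected,
        exclusion_log=excl,
    )
    if not selected:
        return result
    exp_sel = exposure[exposure["snp_id"].isin(selected)]
    pairs = harmonize(exp_sel, outcome, ambiguity_band=config.ambiguity_band)
    result.pairs = pairs
    retained = [p for p in pairs if p.retained]
    if not retained:
        return result
    result.estimates = fit_all(
        pairs,
        random_effects=config.random_effects,
        n_boot=config.n_boot,
        seed=seed,
    )
    n_exp = int(exposure["n"].median())
    n_out = int(outcome["n"].median())
    result.sensitivity = run_sensitivity(
        pairs,
        n_exp=n_exp,
        n_out=n_out,
        n_sim=config.presso_n_sim,
        seed=seed + 1,
        random_effects=config.random_effects,
    )
    lead = min(
        (p.snp_id for p in retained),
        key=lambda s: exp_sel.set_index("snp_id").at[s, "pval"],
    )
    result.lead_snp = lead
    result.status = "fitted"
    return result


def screen_layer(
    exposures: Mapping[str, pd.DataFrame],
    outcome: tuple[str, pd.DataFrame],
    panel: Optional[LDPanel],
    config: PipelineConfig,
    layer: str = LAYER_EXPOSURE_OUTCOME,
) -> list[CausalEdge]:
    """Screen every exposure against one outcome.

    An edge passes when the IVW p-value clears ``layer_alpha``, the
    sensitivity gate is satisfied and the Steiger direction is TRUE.
    Exposures with zero surviving instruments are reported as untestable,
    never silently skipped.  Output order follows sorted exposure names, so
    the result is invariant to input ordering.
    """
    outcome_id, outcome_df = outcome
    edges: list[CausalEdge] = []
    for name in sorted(exposures):
        fit = fit_pair(
            exposures[name],
            outcome_df,
            panel,
            config,
            exposure_id=name,
            outcome_id=outcome_id,
            seed=_child_seed(config.seed, layer, name, outcome_id),
        )
        edge = CausalEdge(
            source_id=name,
            target_id=outcome_id,
            layer=layer,
            estimate=fit.estimates.get("ivw"),
            estimates=fit.estimates,
            sensitivity=fit.sensitivity,
            lead_snp=fit.lead_snp,
        )
        if fit.status == "untestable":
            edge.status = "untestable"
        else:
            ivw_est = fit.estimates["ivw"]
            gate_ok, failures = config.gate.evaluate(
                fit.sensitivity, ivw_est, ivw_random_effects=config.random_effects
            )
            sig = ivw_est.pval < config.layer_alpha
            steiger_ok = fit.sensitivity.steiger_direction is not False
            edge.passed_gate = gate_ok
            edge.gate_failures = tuple(failures)
            if sig and gate_ok and steiger_ok:
                edge.status = "passed"
            else:
                reasons = list(failures)
                if not sig:
                    reasons.insert(0, "ivw_p")
                if not steiger_ok:
                    reasons.append("steiger")
                edge.status = "failed:" + ",".join(dict.fromkeys(reasons))
        edges.append(edge)
    return edges


def _edge_index(edges: list[CausalEdge]) -> dict[tuple[str, str], CausalEdge]:
    return {(e.source_id, e.target_id): e for e in edges}


def _mediation_from_edges(
    total: CausalEdge,
    leg1: CausalEdge,
    leg2: CausalEdge,
    config: PipelineConfig,
) -> MediationResult:
    t, l1, l2 = total.estimate, leg1.estimate, leg2.estimate
    return two_step_mediation(
        t.beta,
        t.se,
        l1.beta,
        l1.se,
        l2.beta,
        l2.se,
        exposure_id=total.source_id,
        mediator_id=leg1.target_id,
        outcome_id=total.target_id,
        propagate_total=config.propagate_total,
    )


def discover_axes(
    upstream_edges: list[CausalEdge],
    downstream_edges: list[CausalEdge],
    metabolite_edges: list[CausalEdge],
    config: Optional[PipelineConfig] = None,
) -> list[RegulatoryAxis]:
    """Assemble regulatory axes from the screened edge layers.

    ``upstream_edges`` holds upstream-protein→outcome and
    upstream→downstream edges; ``downstream_edges`` the downstream-protein→
    outcome edges; ``metabolite_edges`` the protein→metabolite and
    metabolite→outcome edges.  For every upstream→downstream pair whose two
    proteins both pass against the outcome, the upstream mediation is
    computed and screened; survivors are retained only when at least one
    screened metabolite mediation supports the downstream leg (the combined
    upstream-and-downstream rule).
    """
    config = config or PipelineConfig()
    up_out = _edge_index(
        [e for e in upstream_edges if e.layer == LAYER_EXPOSURE_OUTCOME]
    )
    up_down = [e for e in upstream_edges if e.layer == LAYER_UPSTREAM_DOWNSTREAM]
    down_out = _edge_index(downstream_edges)
    prot_met = [e for e in metabolite_edges if e.layer == LAYER_PROTEIN_METABOLITE]
    met_out = _edge_index(
        [e for e in metabolite_edges if e.layer == LAYER_METABOLITE_OUTCOME]
    )

    axes: list[RegulatoryAxis] = []
    for ud in sorted(up_down, key=lambda e: (e.source_id, e.target_id)):
        if ud.estimate is None:
            continue
        u, d = ud.source_id, ud.target_id
        outcome_ids = {e.target_id for e in downstream_edges}
        for outcome_id in sorted(outcome_ids):
            e_uy = up_out.get((u, outcome_id))
            e_dy = down_out.get((d, outcome_id))
            if e_uy is None or e_dy is None or not (e_uy.passed and e_dy.passed):
                continue
            upstream_med = _mediation_from_edges(e_uy, ud, e_dy, config)
            if not screen_mediators(
                [upstream_med],
                p_max=config.mediation_p_max,
                proportion_min=config.mediation_proportion_min,
            ):
                continue
            downstream_meds: list[MediationResult] = []
            for dm in sorted(prot_met, key=lambda e: e.target_id):
                if dm.source_id != d or dm.estimate is None:
                    continue
                e_my = met_out.get((dm.target_id, outcome_id))
                if e_my is None or not e_my.passed:
                    continue
                downstream_meds.append(_mediation_from_edges(e_dy, dm, e_my, config))
            screened_down = screen_mediators(
                downstream_meds,
                p_max=config.mediation_p_max,
                proportion_min=config.mediation_proportion_min,
            )
            if screened_down:
                axes.append(
                    RegulatoryAxis(
                        upstream_id=u,
                        mediator_id=d,
                        outcome_id=outcome_id,
                        upstream_mediation=upstream_med,
                        downstream_mediations=screened_down,
                    )
                )
    return sorted(axes, key=lambda a: a.upstream_mediation.p12)


# ---------------------------------------------------------------------------
# Full network run + tabular output
# ---------------------------------------------------------------------------


@dataclass
class NetworkInputs:
    """Named summary-statistic tables for the three screening layers."""

    upstream: Mapping[str, pd.DataFrame]
    downstream: Mapping[str, pd.DataFrame]
    metabolites: Mapping[str, pd.DataFrame]
    outcome: tuple[str, pd.DataFrame]
    panel: Optional[LDPanel] = None


def run_network(
    inputs: NetworkInputs, config: Optional[PipelineConfig] = None
) -> tuple[list[RegulatoryAxis], dict]:
    """Run the full three-layer screen and axis discovery.

    Returns the retained axes and a run report with the edge lists and
    per-stage counts.
    """
    config = config or PipelineConfig()
    outcome_id, _ = inputs.outcome

    down_edges = screen_layer(
        inputs.downstream, inputs.outcome, inputs.panel, config, LAYER_EXPOSURE_OUTCOME
    )
    up_out_edges = screen_layer(
        inputs.upstream, inputs.outcome, inputs.panel, config, LAYER_EXPOSURE_OUTCOME
    )
    up_down_edges: list[CausalEdge] = []
    for d_name in sorted(inputs.downstream):
        up_down_edges.extend(
            screen_layer(
                inputs.upstream,
                (d_name, inputs.downstream[d_name]),
                inputs.panel,
                config,
                LAYER_UPSTREAM_DOWNSTREAM,
            )
        )
    prot_met_edges: list[CausalEdge] = []
    for m_name in sorted(inputs.metabolites):
        prot_met_edges.extend(
            screen_layer(
                inputs.downstream,
                (m_name, inputs.metabolites[m_name]),
                inputs.panel,
                config,
                LAYER_PROTEIN_METABOLITE,
            )
        )
    met_out_edges = screen_layer(
        inputs.metabolites, inputs.outcome, inputs.panel, config, LAYER_METABOLITE_OUTCOME
    )

    axes = discover_axes(
        up_out_edges + up_down_edges, down_edges, prot_met_edges + met_out_edges, config
    )

    all_edges = down_edges + up_out_edges + up_down_edges + prot_met_edges + met_out_edges
    report = {
        "version": __version__,
        "config": config.to_dict(),
        "edges": all_edges,
        "counts": {
            "edges_total": len(all_edges),
            "edges_passed": sum(e.passed for e in all_edges),
            "edges_untestable": sum(e.status == "untestable" for e in all_edges),
            "axes_retained": len(axes),
        },
    }
    return axes, report


def estimates_table(edges: list[CausalEdge]) -> pd.DataFrame:
    """Per-edge estimator rows in the shape of a causal-association table."""
    rows = []
    for e in edges:
        for method, est in e.estimates.items():
            rows.append(
                {
                    "exposure": e.source_id,
                    "outcome": e.target_id,
                    "layer": e.layer,
                    "method": method,
                    "nsnp": est.nsnp,
                    "p": est.pval,
                    "beta": est.beta,
                    "se": est.se,
                    "OR": est.or_point,
                    "OR_95CI": f"({est.or_ci_low:.2f}, {est.or_ci_high:.2f})",
                    "status": e.status,
                }
            )
    return pd.DataFrame(rows)


def sensitivity_table(edges: list[CausalEdge]) -> pd.DataFrame:
    """Per-edge diagnostics: lead SNP, Steiger, heterogeneity and pleiotropy p."""
    rows = []
    for e in edges:
        s = e.sensitivity
        if s is None:
            continue
        rows.append(
            {
                "exposure": e.source_id,
                "outcome": e.target_id,
                "SNP": e.lead_snp,
                "steiger_direction": s.steiger_direction,
                "steiger_p": s.steiger_p,
                "heterogeneity_p": s.q_pval,
                "pleiotropy_p": s.egger_intercept_p,
            }
        )
    return pd.DataFrame(rows)


def mediation_table(axes: list[RegulatoryAxis]) -> pd.DataFrame:
    """Axis mediation rows: upstream first, then its downstream metabolites."""
    rows = []

    def add(med: MediationResult):
        rows.append(
            {
                "exposure": med.exposure_id,
                "mediator": med.mediator_id,
                "outcome": med.outcome_id,
                "beta_all": med.beta_all,
                "beta1": med.beta1,
                "beta2": med.beta2,
                "proportion": f"{med.proportion_pct:.1f}%",
                "proportion_95CI": (
                    f"({100 * med.proportion_ci_low:.1f}%, {100 * med.proportion_ci_high:.1f}%)"
                ),
                "p": med.p12,
            }
        )

    for axis in axes:
        add(axis.upstream_mediation)
        for med in axis.downstream_mediations:
            add(med)
    return pd.DataFrame(rows)


def axes_to_dot(axes: list[RegulatoryAxis]) -> str:
    """Graphviz DOT rendering of the retained axes."""
    lines = ["digraph axes {", "  rankdir=LR;"]
    for a in axes:
        up = a.upstream_mediation
        lines.append(
            f'  "{a.upstream_id}" -> "{a.mediator_id}" '
            f'[label="{up.proportion_pct:.1f}%"];'
        )
        lines.append(f'  "{a.mediator_id}" -> "{a.outcome_id}";')
        for med in a.downstream_mediations:
            lines.append(
                f'  "{a.mediator_id}" -> "{med.mediator_id}" '
                f'[label="{med.proportion_pct:.1f}%"];'
            )
            lines.append(f'  "{med.mediator_id}" -> "{a.outcome_id}";')
    lines.append("}")
    return "\n".join(lines)


def write_outputs(
    axes: list[RegulatoryAxis], report: dict, out_dir, write_dot: bool = False
) -> None:
    """Write the result TSVs, the run report JSON and optional DOT export."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    edges = report["edges"]
    estimates_table(edges).to_csv(out / "estimates.tsv", sep="\t", index=False)
    sensitivity_table(edges).to_csv(out / "sensitivity.tsv", sep="\t", index=False)
    mediation_table(axes).to_csv(out / "mediation.tsv", sep="\t", index=False)
    audit_rows = []
    for e in edges:
        audit_rows.append(
            {
                "exposure": e.source_id,
                "outcome": e.target_id,
                "layer": e.layer,
                "status": e.status,
            }
        )
    pd.DataFrame(audit_rows).to_csv(out / "edge_status.tsv", sep="\t", index=False)
    json_report = {
        "version": report["version"],
        "config": report["config"],
        "counts": report["counts"],
        "edge_status": audit_rows,
    }
    (out / "run_report.json").write_text(json.dumps(json_report, indent=2))
    if write_dot:
        (out / "axes.dot").write_text(axes_to_dot(axes))
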