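"""Discounted aggregation and pairwise cost-effectiveness comparison.

Combines the year-1 decision-tree accruals (discount period 0, undiscounted)
with the post-trial Markov trace (periods 1..horizon-1) into per-arm
discounted totals, then forms pairwise increments, ICERs and dominance
verdicts.  Event counts are lifetime expectations per patient, undiscounted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .markov import MarkovTrace, run_markov
from .parameters import ModelParameters, ModelSettings
from .trial import COST_CATEGORIES, TrialPhaseResult, run_trial_phase


def discount_stream(values: Sequence[float], rate: float, start_period: int = 0) -> float:
    """Present value of a per-cycle stream: sum of v_k / (1+rate)^k.

    Period 0 (the trial year) is undiscounted.
    """
    if rate < 0:
        raise ValueError("discount rate must be >= 0")
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        return 0.0
    k = np.arange(start_period, start_period + v.size)
    return float(np.sum(v / (1.0 + rate) ** k))


@dataclass
class EconomicResult:
    """Per-arm discounted and undiscounted lifetime totals."""

    arm: str
    lys: float
    qalys: float
    costs: dict[str, float]
    lys_undiscounted: float = 0.0
    qalys_undiscounted: float = 0.0
    costs_undiscounted: dict[str, float] = field(default_factory=dict)
    events: dict[str, float] = field(default_factory=dict)

    @property
    def total_cost(self) -> float:
        return float(sum(self.costs.values()))

    @property
    def total_cost_undiscounted(self) -> float:
        return float(sum(self.costs_undiscounted.values()))


@dataclass
class ComparisonResult:
    """Pairwise increments (intervention minus comparator) and verdicts."""

    intervention: str
    comparator: str
    delta_ly: float
    delta_qaly: float
    delta_cost: float
    icer_per_qaly: Optional[float]
    icer_per_ly: Optional[float]
    verdict_qaly: str
    verdict_ly: str

    def icer_label(self, per: str = "qaly") -> str:
        """Printable ICER: a rounded ratio, or the dominance verdict."""
        verdict = self.verdict_qaly if per == "qaly" else self.verdict_ly
        icer = self.icer_per_qaly if per == "qaly" else self.icer_per_ly
        if verdict == "icer":
            return f"{icer:.0f}"
        return verdict


def compute_icer(delta_cost: float, delta_effect: float) -> tuple[str, Optional[float]]:
    """Classify an incremental (cost, effect) pair.

    Returns ``(verdict, ratio)`` where verdict is one of ``icer`` (finite
    ratio reported), ``dominant`` (more effect, lower cost), ``dominated``
    (less effect, higher cost), ``equivalent`` (both zero), or
    ``undefined_costlier`` / ``undefined_cheaper`` (zero effect difference
    with a cost difference).  Negative ratios are never reported.
    """
    if delta_effect == 0.0:
        if delta_cost == 0.0:
            return "equivalent", None
        return ("undefined_costlier" if delta_cost > 0 else "undefined_cheaper"), None
    if delta_effect > 0.0 and delta_cost < 0.0:
        return "dominant", None
    if delta_effect < 0.0 and delta_cost > 0.0:
        return "dominated", None
    return "icer", float(delta_cost / delta_effect)


def assemble_results(
    trial: TrialPhaseResult,
    trace: MarkovTrace,
    settings: ModelSettings,
) -> EconomicResult:
    """Discount and sum trial-phase and Markov accruals for one arm."""
    if trace.arm and trace.arm != trial.arm:
        raise ValueError(f"arm mismatch: trial {trial.arm!r} vs trace {trace.arm!r}")
    rc = settings.discount_rate_costs
    rb = settings.discount_rate_benefits

    costs_d, costs_u = {}, {}
    for cat in COST_CATEGORIES:
        stream = trace.costs.get(cat, np.zeros(0))
        costs_d[cat] = trial.costs.get(cat, 0.0) + discount_stream(stream, rc, start_period=1)
        costs_u[cat] = trial.costs.get(cat, 0.0) + float(np.sum(stream))

    lys_d = trial.lys + discount_stream(trace.lys, rb, start_period=1)
    qalys_d = trial.qalys + discount_stream(trace.qalys, rb, start_period=1)
    events = {}
    for key in ("moderate_exacerbation", "severe_exacerbation", "pneumonia"):
        events[key] = trial.events.get(key, 0.0) + float(
            np.sum(trace.events.get(key, np.zeros(0)))
        )
    events["any_exacerbation"] = events["moderate_exacerbation"] + events["severe_exacerbation"]

    return EconomicResult(
        arm=trial.arm,
        lys=lys_d,
        qalys=qalys_d,
        costs=costs_d,
        lys_undiscounted=trial.lys + float(np.sum(trace.lys)),
        qalys_undiscounted=trial.qalys + float(np.sum(trace.qalys)),
        costs_undiscounted=costs_u,
        events=events,
    )


def run_arm(
    params: ModelParameters,
    arm_label: str,
    effect_reduction: float = 0.0,
) -> EconomicResult:
    """Full pipeline (trial year + Markov extrapolation) for one arm."""
    arm = params.arms[arm_label]
    settings = params.settings
    trial = run_trial_phase(arm, params.costs, params.utilities, settings)
    start = np.zeros(7)
    start[:6] = trial.end_distribution * trial.surviving_fraction
    start[6] = 1.0 - trial.surviving_fraction
    trace = run_markov(start, params, arm, settings, effect_reduction=effect_reduction)
    return assemble_results(trial, trace, settings)


def _auto_reduction(params: ModelParameters, intervention: str, comparator: str) -> float:
    """Relative reduction in total 52-week exacerbation rate vs the comparator."""
    a = params.arms[intervention]
    b = params.arms[comparator]
    total_i = a.moderate_exacerbation_rate + a.severe_exacerbation_rate
    total_c = b.moderate_exacerbation_rate + b.severe_exacerbation_rate
    if total_c <= 0:
        return 0.0
    return float(np.clip(1.0 - total_i / total_c, 0.0, 1.0))


def compare(
    result_i: EconomicResult, result_c: EconomicResult
) -> ComparisonResult:
    """Incremental results for intervention vs comparator."""
    d_cost = result_i.total_cost - result_c.total_cost
    d_qaly = result_i.qalys - result_c.qalys
    d_ly = result_i.lys - result_c.lys
    vq, iq = compute_icer(d_cost, d_qaly)
    vl, il = compute_icer(d_cost, d_ly)
    return ComparisonResult(
        intervention=result_i.arm,
        comparator=result_c.arm,
        delta_ly=d_ly,
        delta_qaly=d_qaly,
        delta_cost=d_cost,
        icer_per_qaly=iq,
        icer_per_ly=il,
        verdict_qaly=vq,
        verdict_ly=vl,
    )


def run_comparison(
    params: ModelParameters,
) -> tuple[dict[str, EconomicResult], dict[str, ComparisonResult]]:
    """Run all arms and compare the intervention against each comparator.

    With a direct post-trial effect configured and ``reduction='auto'``, the
    intervention arm is re-run per comparator using the trial-observed
    relative rate reduction against that comparator; comparator arms carry no
    direct effect.
    """
    settings = params.settings
    pte = settings.posttrial_effect
    results: dict[str, EconomicResult] = {}
    for label in params.arms:
        red = 0.0
        if pte is not None and label == params.intervention \
                and not isinstance(pte.reduction, str):
            red = pte.reduction
        results[label] = run_arm(params, label, effect_reduction=red)

    comparisons: dict[str, ComparisonResult] = {}
    for comp in params.comparators:
        res_i = results[params.intervention]
        if pte is not None and isinstance(pte.reduction, str):
            red = _auto_reduction(params, params.intervention, comp)
            res_i = run_arm(params, params.intervention, effect_reduction=red)
        comparisons[comp] = compare(res_i, results[comp])
    return results, comparisons


_ROW_ORDER = [
    ("moderate_exacerbations", "events", "moderate_exacerbation"),
    ("severe_exacerbations", "events", "severe_exacerbation"),
    ("any_exacerbations", "events", "any_exacerbation"),
    ("total_lys_discounted", "lys", None),
    ("total_qalys", "qalys", None),
    ("cost_maintenance", "costs", "maintenance"),
    ("cost_moderate_exacerbation", "costs", "moderate_exacerbation"),
    ("cost_severe_exacerbation", "costs", "severe_exacerbation"),
    ("cost_pneumonia", "costs", "pneumonia"),
    ("cost_treatment", "costs", "treatment"),
    ("cost_replacement", "costs", "replacement"),
    ("cost_societal", "costs", "societal"),
    ("total_costs", "total", None),
]


def results_table(
    results: dict[str, EconomicResult],
    comparisons: dict[str, ComparisonResult],
    intervention: str,
) -> pd.DataFrame:
    """Arm-by-row results table with incremental columns per comparator."""
    cols: dict[str, dict[str, float]] = {}
    for label, res in results.items():
        col = {}
        for row, kind, key in _ROW_ORDER:
            if kind == "events":
                col[row] = res.events.get(key, 0.0)
            elif kind == "costs":
                col[row] = res.costs.get(key, 0.0)
            elif kind == "total":
                col[row] = res.total_cost
            else:
                col[row] = getattr(res, kind)
        cols[label] = col
    for comp, cr in comparisons.items():
        col = {
            row: cols[intervention][row] - cols[comp][row] for row, _, _ in _ROW_ORDER
        }
        col["icer_per_ly"] = cr.icer_per_ly if cr.icer_per_ly is not None else np.nan
        col["icer_per_qaly"] = cr.icer_per_qaly if cr.icer_per_qaly is not None else np.nan
        cols[f"incremental_vs_{comp}"] = col
    return pd.DataFrame(cols)
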