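"""Year-1 decision tree: accrue costs, QALYs and life-years from trial outputs.

The first model year is costed directly from the 52-week per-arm results:
exacerbation and pneumonia expectations from observed rates, mortality from
observed within-trial deaths, drug cost with the midpoint-switch
discontinuation rule, and quality of life from the trial utility trajectory.
Decedents die at the year midpoint and contribute half a year of person-time
to both accruals and event expectations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .parameters import (
    HALF_YEAR_UNITS,
    REPLACEMENT_CLASSES,
    UNITS_PER_YEAR,
    ArmInputs,
    CostInputs,
    ModelSettings,
    UtilityInputs,
)
from .states import SEVERITIES, severity_of_living

COST_CATEGORIES = (
    "maintenance",
    "moderate_exacerbation",
    "severe_exacerbation",
    "pneumonia",
    "treatment",
    "replacement",
    "societal",
)


@dataclass
class TrialPhaseResult:
    """Per-arm year-1 accruals and the Markov starting distribution."""

    arm: str
    costs: dict[str, float]
    qalys: float
    lys: float
    surviving_fraction: float
    end_distribution: np.ndarray  # over 6 living states, conditional on survival
    events: dict[str, float] = field(default_factory=dict)

    @property
    def total_cost(self) -> float:
        return float(sum(self.costs.values()))


def annual_drug_cost(cost_per_30d: float, fraction_of_year: float = 1.0) -> float:
    """Drug cost for a fraction of one average year (365.25 days)."""
    if cost_per_30d < 0 or fraction_of_year < 0:
        raise ValueError("drug cost and year fraction must be non-negative")
    if fraction_of_year > 1:
        raise ValueError("fraction_of_year must be <= 1")
    return cost_per_30d * UNITS_PER_YEAR * fraction_of_year


def replacement_cost_30d(class_costs: dict[str, float], class_mix: dict[str, float]) -> float:
    """Mix-weighted 30-day cost of replacement therapy across the four classes."""
    total = sum(class_mix.get(cls, 0.0) for cls in REPLACEMENT_CLASSES)
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"replacement mix sums to {total}, expected 1")
    return sum(class_costs[cls] * class_mix.get(cls, 0.0) for cls in REPLACEMENT_CLASSES)


def discontinuation_cost(
    arm_cost_30d: float, replacement_cost_30d_: float, p_disc: float
) -> float:
    """Expected year-1 drug + replacement cost with midpoint switching.

    Discontinuers receive 26 weeks of assigned treatment then 26 weeks of
    replacement therapy; continuers receive a full year of assigned treatment.
    """
    if not 0.0 <= p_disc <= 1.0:
        raise ValueError("p_disc must lie in [0, 1]")
    full = annual_drug_cost(arm_cost_30d)
    switched = HALF_YEAR_UNITS * (arm_cost_30d + replacement_cost_30d_)
    return (1.0 - p_disc) * full + p_disc * switched


def pneumonia_event_cost(
    ambulatory_cost: float, inpatient_cost: float, p_hospitalised: float
) -> float:
    """Per-event pneumonia cost weighted by the hospitalised fraction."""
    if ambulatory_cost < 0 or inpatient_cost < 0:
        raise ValueError("costs must be non-negative")
    if not 0.0 <= p_hospitalised <= 1.0:
        raise ValueError("p_hospitalised must lie in [0, 1]")
    return (1.0 - p_hospitalised) * ambulatory_cost + p_hospitalised * inpatient_cost


def trial_utility_auc(
    baseline_utility: float, change_trajectory: list[tuple[float, float]]
) -> float:
    """Mean utility over the trial year from a change-from-baseline trajectory.

    The trajectory lists (week, delta-EQ-5D) points on [0, 52]; utility is
    baseline at week 0, linearly interpolated between visits and held flat
    after the last visit.  Returns the trapezoidal time-average, i.e. the
    QALYs accrued per full year lived.
    """
    weeks = [w for w, _ in change_trajectory]
    if any(not 0 <= w <= 52 for w in weeks):
        raise ValueError("trajectory weeks must lie in [0, 52]")
    if weeks != sorted(weeks):
        raise ValueError("trajectory weeks must be sorted")
    if not change_trajectory:
        return baseline_utility
    t = [0.0]
    u = [baseline_utility]
    for w, d in change_trajectory:
        if w == 0.0:
            u[0] = baseline_utility + d
            continue
        t.append(w)
        u.append(baseline_utility + d)
    if t[-1] < 52.0:
        t.append(52.0)
        u.append(u[-1])
    return float(np.trapezoid(u, t) / 52.0)


def _severity_mix(distribution: np.ndarray) -> np.ndarray:
    """Collapse a living-state distribution to the 3 severity shares."""
    sev = severity_of_living()
    return np.array([distribution[sev == k].sum() for k in range(3)])


def run_trial_phase(
    arm: ArmInputs,
    costs: CostInputs,
    utilities: UtilityInputs,
    settings: ModelSettings,
) -> TrialPhaseResult:
    """Evaluate the 1-year decision tree for one arm."""
    p_death = arm.trial_mortality if settings.include_trial_mortality else 0.0
    p_disc = arm.discontinuation if settings.include_discontinuation else 0.0
    surviving = 1.0 - p_death
    # decedents die at midpoint: half a year of person-time
    person_time = surviving + 0.5 * p_death

    n_mod = arm.moderate_exacerbation_rate * person_time
    n_sev = arm.severe_exacerbation_rate * person_time
    n_pneu = arm.pneumonia_probability * person_time

    # quality of life: trial EQ-5D trajectory, or state utilities weighted by
    # the trial-end severity mix (scenario)
    sev_mix = _severity_mix(arm.trial_end_distribution)
    if settings.trial_utility_source == "eq5d":
        auc = trial_utility_auc(utilities.trial_baseline, arm.trial_utility_deltas)
    else:
        auc = float(sum(sev_mix[int(s)] * utilities.state_utility[s] for s in SEVERITIES))
    qalys = (
        auc * person_time
        - n_mod * utilities.disutility["moderate_exacerbation"]
        - n_sev * utilities.disutility["severe_exacerbation"]
        - n_pneu * utilities.disutility["pneumonia"]
    )

    repl_30d = replacement_cost_30d(costs.replacement_class_costs_30d, arm.replacement_mix)
    # drug cost split into assigned-treatment and replacement components;
    # both scale with living person-time
    treatment = ((1.0 - p_disc) * annual_drug_cost(arm.drug_cost_30d)
                 + p_disc * HALF_YEAR_UNITS * arm.drug_cost_30d) * person_time
    replacement = p_disc * HALF_YEAR_UNITS * repl_30d * person_time

    maintenance = float(
        sum(sev_mix[int(s)] * costs.maintenance_annual[s] for s in SEVERITIES)
    ) * person_time

    out_costs = {
        "maintenance": maintenance,
        "moderate_exacerbation": n_mod * costs.moderate_exacerbation,
        "severe_exacerbation": n_sev * costs.severe_exacerbation,
        "pneumonia": n_pneu * costs.pneumonia,
        "treatment": treatment,
        "replacement": replacement,
        "societal": 0.0,
    }
    if settings.perspective == "societal":
        per_event = costs.societal_per_event
        per_year = costs.societal_per_year
        out_costs["societal"] = (
            n_mod * per_event.get("moderate_exacerbation", 0.0)
            + n_sev * per_event.get("severe_exacerbation", 0.0)
            + n_pneu * per_event.get("pneumonia", 0.0)
            + float(sum(sev_mix[int(s)] * per_year.get(s, 0.0) for s in SEVERITIES))
            * person_time
        )

    return TrialPhaseResult(
        arm=arm.name,
        costs=out_costs,
        qalys=qalys,
        lys=person_time,
        surviving_fraction=surviving,
        end_distribution=arm.trial_end_distribution.copy(),
        events={"moderate_exacerbation": n_mod,
                "severe_exacerbation": n_sev,
                "pneumonia": n_pneu},
    )
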