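"""Annual-cycle Markov cohort engine for the post-trial extrapolation.

Six living states (three FEV1 severities x recent-exacerbation history) plus
absorbing death.  Each cycle applies, in order: state-specific death,
worsening-only severity progression among survivors, exacerbation
expectations from origin-state risks, and the recent-exacerbation stratum
update.  Within-cycle deaths accrue half a cycle of life-years, QALYs and
maintenance cost, approximating a half-cycle correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .parameters import (
    ArmInputs,
    ModelParameters,
    ModelSettings,
    MortalityModel,
    TransitionModel,
)
from .states import DEATH, N_LIVING, N_STATES, SEVERITIES, severity_of_living, validate_distribution
from .trial import annual_drug_cost, replacement_cost_30d


@dataclass
class MarkovTrace:
    """Per-cycle occupancy, events and undiscounted accruals (post-trial cycles)."""

    occupancy: np.ndarray  # (n_cycles + 1, 7); row 0 is the starting distribution
    ages: np.ndarray  # cohort age at the start of each cycle
    lys: np.ndarray
    qalys: np.ndarray
    events: dict[str, np.ndarray]
    costs: dict[str, np.ndarray]
    arm: str = ""

    @property
    def n_cycles(self) -> int:
        return len(self.lys)


def state_death_probability(background_q: float, rr: float) -> float:
    """Severity-adjusted annual death probability.

    The relative risk multiplies the mortality rate, i.e. acts on the
    log-survival scale: 1 - (1 - q)^rr, clamped to [0, 1].
    """
    if not 0.0 <= background_q <= 1.0:
        raise ValueError("background_q must lie in [0, 1]")
    if rr < 0:
        raise ValueError("rr must be >= 0")
    if background_q >= 1.0:
        return 1.0
    return float(np.clip(1.0 - (1.0 - background_q) ** rr, 0.0, 1.0))


def exacerbation_stratum_update(
    p_any_exac: np.ndarray, survivors_by_severity: np.ndarray
) -> np.ndarray:
    """Split each severity's survivors into recent / no-recent strata.

    A fraction ``p_any_exac`` (per severity) of survivors had at least one
    exacerbation this cycle and enters the recent-exacerbation stratum.
    Returns a length-6 living-state vector.
    """
    p = np.asarray(p_any_exac, dtype=float)
    s = np.asarray(survivors_by_severity, dtype=float)
    out = np.zeros(N_LIVING)
    out[0::2] = s * (1.0 - p)  # no-recent
    out[1::2] = s * p  # recent
    return out


def _progression_matrix(t: TransitionModel) -> np.ndarray:
    """(3, 3) severity progression matrix among survivors (worsening only)."""
    m = np.zeros((3, 3))
    m[0, 0] = 1.0 - t.p_moderate_to_severe - t.p_moderate_to_very_severe
    m[0, 1] = t.p_moderate_to_severe
    m[0, 2] = t.p_moderate_to_very_severe
    m[1, 1] = 1.0 - t.p_severe_to_very_severe
    m[1, 2] = t.p_severe_to_very_severe
    m[2, 2] = 1.0
    return m


def run_cycle(
    d: np.ndarray,
    t: TransitionModel,
    m: MortalityModel,
    age: float,
) -> tuple[np.ndarray, dict[str, float]]:
    """Advance the cohort one annual cycle.

    Returns the next distribution and a dict of expected quantities for the
    cycle: deaths, moderate/severe exacerbations (from origin-state risks
    applied to survivors), survivors, and origin-state person-time weights.
    """
    d = np.asarray(d, dtype=float)
    check = validate_distribution(d)
    if not check.valid:
        raise ValueError(f"invalid cohort distribution: {check.message}")

    living = d[:N_LIVING]
    q_bg = m.background_q(age)
    q_state = np.array([
        state_death_probability(q_bg, m.relative_risk[SEVERITIES[s]])
        for s in severity_of_living()
    ])
    deaths = living * q_state
    survivors = living - deaths

    # exacerbation expectations use the origin state's annual risks
    n_mod = float(survivors @ t.p_moderate_exac)
    n_sev = float(survivors @ t.p_severe_exac)
    p_any = t.p_any_exac()

    # survivors progress (worsening only), carrying their exacerbation status
    prog = _progression_matrix(t)
    sev_idx = severity_of_living()
    next_by_sev_exac = np.zeros(3)  # had >=1 exacerbation this cycle
    next_by_sev_none = np.zeros(3)
    for i in range(N_LIVING):
        row = prog[sev_idx[i]]
        next_by_sev_exac += survivors[i] * p_any[i] * row
        next_by_sev_none += survivors[i] * (1.0 - p_any[i]) * row

    nxt = np.zeros(N_STATES)
    nxt[0::2][:3] = next_by_sev_none
    nxt[1::2][:3] = next_by_sev_exac
    nxt[DEATH] = d[DEATH] + deaths.sum()

    info = {
        "deaths": float(deaths.sum()),
        "moderate_exacerbations": n_mod,
        "severe_exacerbations": n_sev,
        "survivors": float(survivors.sum()),
        # person-time per origin living state (deaths credit half a cycle)
        "person_time_by_state": survivors + 0.5 * deaths,
    }
    return nxt, info


def apply_posttrial_effect(
    t: TransitionModel,
    rate_reduction: float,
    cycle_index: int,
    duration_years: int,
    waning: bool = False,
) -> TransitionModel:
    """Exacerbation-probability multiplier for a direct post-trial effect.

    ``cycle_index`` counts post-trial cycles from 0.  Without waning the full
    reduction applies while ``cycle_index < duration_years``; with linear
    waning the reduction scales by (1 - cycle/duration).  Afterwards (or with
    zero reduction, the base case) the model is unchanged.
    """
    if not 0.0 <= rate_reduction <= 1.0:
        raise ValueError("rate_reduction must lie in [0, 1]")
    if rate_reduction == 0.0 or duration_years <= 0 or cycle_index >= duration_years:
        return t
    reduction = rate_reduction
    if waning:
        reduction *= 1.0 - cycle_index / duration_years
    return t.scaled_exacerbations(1.0 - reduction)


def run_markov(
    start: np.ndarray,
    params: ModelParameters,
    arm: ArmInputs,
    settings: Optional[ModelSettings] = None,
    effect_reduction: float = 0.0,
) -> MarkovTrace:
    """Run the post-trial cohort model from the trial-end distribution.

    ``start`` is a 7-state distribution (living mass scaled by trial
    survivors, death mass from the trial year).  Runs ``horizon_years - 1``
    cycles.  Drug and replacement cost accrue to living person-time with the
    discontinuation split fixed at trial end; pneumonia expectation is the
    arm's annual probability applied to survivors.
    """
    settings = settings or params.settings
    t0 = params.transitions
    mort = params.mortality
    costs = params.costs
    utils = params.utilities
    n_cycles = settings.horizon_years - 1

    check = validate_distribution(start)
    if not check.valid:
        raise ValueError(f"invalid starting distribution: {check.message}")

    pte = settings.posttrial_effect
    duration = pte.duration_years if (pte and effect_reduction > 0.0) else 0
    waning = pte.waning if pte else False

    p_disc = arm.discontinuation if settings.include_discontinuation else 0.0
    repl_30d = replacement_cost_30d(costs.replacement_class_costs_30d, arm.replacement_mix)
    annual_treatment = (1.0 - p_disc) * annual_drug_cost(arm.drug_cost_30d)
    annual_replacement = p_disc * annual_drug_cost(repl_30d)

    u_state = np.array([utils.state_utility[SEVERITIES[s]] for s in severity_of_living()])
    c_maint = np.array([costs.maintenance_annual[SEVERITIES[s]]
                        for s in severity_of_living()])
    soc_year = np.array([costs.societal_per_year.get(SEVERITIES[s], 0.0)
                         for s in severity_of_living()])
    societal_on = settings.perspective == "societal"
    per_event = costs.societal_per_event

    occupancy = np.zeros((n_cycles + 1, N_STATES))
    occupancy[0] = start
    ages = settings.start_age + 1.0 + np.arange(n_cycles)
    lys = np.zeros(n_cycles)
    qalys = np.zeros(n_cycles)
    ev = {k: np.zeros(n_cycles) for k in
          ("moderate_exacerbation", "severe_exacerbation", "pneumonia")}
    cc = {k: np.zeros(n_cycles) for k in
          ("maintenance", "moderate_exacerbation", "severe_exacerbation",
           "pneumonia", "treatment", "replacement", "societal")}

    d = start.copy()
    for j in range(n_cycles):
        t = apply_posttrial_effect(t0, effect_reduction, j, duration, waning)
        nxt, info = run_cycle(d, t, mort, float(ages[j]))
        pt_state = info["person_time_by_state"]
        pt_total = float(pt_state.sum())
        n_mod = info["moderate_exacerbations"]
        n_sev = info["severe_exacerbations"]
        n_pneu = arm.pneumonia_probability * info["survivors"]

        lys[j] = pt_total
        qalys[j] = (
            float(pt_state @ u_state)
            - n_mod * utils.disutility["moderate_exacerbation"]
            - n_sev * utils.disutility["severe_exacerbation"]
            - n_pneu * utils.disutility["pneumonia"]
        )
        ev["moderate_exacerbation"][j] = n_mod
        ev["severe_exacerbation"][j] = n_sev
        ev["pneumonia"][j] = n_pneu

        cc["maintenance"][j] = float(pt_state @ c_maint)
        cc["moderate_exacerbation"][j] = n_mod * costs.moderate_exacerbation
        cc["severe_exacerbation"][j] = n_sev * costs.severe_exacerbation
        cc["pneumonia"][j] = n_pneu * costs.pneumonia
        cc["treatment"][j] = annual_treatment * pt_total
        cc["replacement"][j] = annual_replacement * pt_total
        if societal_on:
            cc["societal"][j] = (
                n_mod * per_event.get("moderate_exacerbation", 0.0)
                + n_sev * per_event.get("severe_exacerbation", 0.0)
                + n_pneu * per_event.get("pneumonia", 0.0)
                + float(pt_state @ soc_year)
            )

        occupancy[j + 1] = nxt
        d = nxt

    return MarkovTrace(occupancy=occupancy, ages=ages, lys=lys, qalys=qalys,
                       events=ev, costs=cc, arm=arm.name)
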