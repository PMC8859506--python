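"""Synthetic parameter bundles with the statistical structure the model assumes.

The published main text prints the unit costs, utilities and mortality
relative risks, but the annual transition/exacerbation probability table, the
per-arm 52-week trial outputs and the background life table live in external
sources.  This module generates complete, internally consistent stand-ins:
exacerbation risk increases with severity and with recent-exacerbation
history, utilities decrease and costs increase with severity, triple therapy
has lower exacerbation rates and a milder trial-end distribution,
ICS-containing arms have higher pneumonia risk, and background mortality
rises exponentially with age (Gompertz).  All values marked synthetic are
plausible stand-ins, not transcriptions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .parameters import (
    MAX_AGE,
    MIN_AGE,
    N_TRANSITION_COEF,
    ArmInputs,
    CostInputs,
    ModelParameters,
    ModelSettings,
    MortalityModel,
    TransitionModel,
    UtilityInputs,
    write_parameters,
)
from .sensitivity import PSASpec, default_psa_spec
from .states import SEVERITIES, Severity


@dataclass
class GeneratorSpec:
    """Knobs for the synthetic bundle generator.

    Gradients of 1 give the canonical bundle; ``effect_size`` scales every
    between-arm difference (0 makes the three arms identical), and ``jitter``
    adds a seeded multiplicative wobble to block-level quantities without
    breaking any schema invariant.
    """

    seed: int = 0
    cost_gradient: float = 1.0
    utility_gradient: float = 1.0
    exacerbation_gradient: float = 1.0
    progression_gradient: float = 1.0
    effect_size: float = 1.0
    jitter: float = 0.0
    life_table_a: float = 6.0e-5  # Gompertz level
    life_table_b: float = 0.082  # Gompertz log-slope per year of age
    copd_death_fraction: float = 0.054
    psa_noise: float = 1.0  # multiplier on PSA coefficients of variation
    coef_sd: float = 0.05  # logit-scale sd of transition coefficients
    coef_rho: float = 0.3  # AR(1) correlation between coefficients


# Printed point estimates (costs GBP-2018, utilities, mortality RRs).
TABLE1 = {
    "maintenance": {"moderate": 216.82, "severe": 798.95, "very_severe": 2297.98},
    "rr_mortality": {"moderate": 1.89, "severe": 3.63, "very_severe": 8.33},
    "cost_severe_exacerbation": 6120.30,
    "cost_moderate_exacerbation": 568.48,
    "cost_pneumonia": 1087.98,
    "drug_cost_30d": {"FF/UMEC/VI": 44.50, "FF/VI": 22.00, "UMEC/VI": 32.50},
    "utility": {"moderate": (0.787, (0.771, 0.802)),
                "severe": (0.750, (0.731, 0.786)),
                "very_severe": (0.647, (0.598, 0.695))},
    "disutility": {"severe_exacerbation": (0.020, (0.020, 0.030)),
                   "moderate_exacerbation": (0.011, (0.006, 0.020)),
                   "pneumonia": (0.011, (0.006, 0.020))},
    "replacement_class_costs_30d": {"lama": 29.29, "ics_laba": 31.79,
                                    "lama_laba": 32.50, "ics_lama_laba": 61.08},
    "pneumonia_p_hospitalised": 0.55,
}

# Synthetic stand-ins: pneumonia unit costs consistent with the printed
# hospitalisation-weighted per-event cost.
PNEUMONIA_UNIT_COSTS = {"ambulatory": 140.00, "inpatient": 1863.60}

# Synthetic annual transition / exacerbation-risk table (risk-equation
# outputs).  Living-state order: moderate/no, moderate/recent, severe/no,
# severe/recent, very_severe/no, very_severe/recent.
PROGRESSION = {"moderate_to_severe": 0.128, "severe_to_very_severe": 0.102,
               "moderate_to_very_severe": 0.0}
P_MODERATE_EXAC = np.array([0.385, 0.540, 0.470, 0.620, 0.530, 0.700])
P_SEVERE_EXAC = np.array([0.075, 0.130, 0.120, 0.200, 0.185, 0.290])

# Synthetic per-arm 52-week outputs.  Triple therapy: fewer exacerbations,
# milder trial-end distribution; ICS-containing arms: higher pneumonia risk.
# Replacement mixes are synthetic but consistent with the printed weighted
# 30-day replacement costs per arm.
ARM_TABLE = {
    "FF/UMEC/VI": {
        "moderate_exacerbation_rate": 0.78,
        "severe_exacerbation_rate": 0.13,
        "pneumonia_probability": 0.076,
        "trial_mortality": 0.020,
        "discontinuation": 0.26,
        "replacement_mix": {"lama": 0.18, "ics_laba": 0.20,
                            "lama_laba": 0.0521, "ics_lama_laba": 0.5679},
        "trial_end_distribution": [0.26, 0.17, 0.22, 0.17, 0.10, 0.08],
        "trial_utility_deltas": [[4, 0.043], [16, 0.049], [28, 0.052], [52, 0.048]],
    },
    "FF/VI": {
        "moderate_exacerbation_rate": 0.92,
        "severe_exacerbation_rate": 0.15,
        "pneumonia_probability": 0.069,
        "trial_mortality": 0.023,
        "discontinuation": 0.30,
        "replacement_mix": {"lama": 0.15, "ics_laba": 0.22,
                            "lama_laba": 0.0185, "ics_lama_laba": 0.6115},
        "trial_end_distribution": [0.22, 0.17, 0.22, 0.19, 0.11, 0.09],
        "trial_utility_deltas": [[4, 0.025], [16, 0.029], [28, 0.031], [52, 0.027]],
    },
    "UMEC/VI": {
        "moderate_exacerbation_rate": 1.02,
        "severe_exacerbation_rate": 0.19,
        "pneumonia_probability": 0.047,
        "trial_mortality": 0.025,
        "discontinuation": 0.32,
        "replacement_mix": {"lama": 0.16, "ics_laba": 0.20,
                            "lama_laba": 0.0558, "ics_lama_laba": 0.5842},
        "trial_end_distribution": [0.24, 0.17, 0.22, 0.18, 0.10, 0.09],
        "trial_utility_deltas": [[4, 0.034], [16, 0.038], [28, 0.041], [52, 0.036]],
    },
}

TRIAL_BASELINE_EQ5D = 0.740


def generate_life_table(
    a: float = 6.0e-5, b: float = 0.082, seed: Optional[int] = None
) -> tuple[np.ndarray, np.ndarray]:
    """Gompertz background mortality: q(age) = 1 - exp(-a e^{b age}).

    Increasing in age, q in (0, 1), q(110) pinned to 1.  Returns
    (ages, q) over [40, 110].
    """
    if a <= 0 or b <= 0:
        raise ValueError("Gompertz parameters must be positive")
    ages = np.arange(MIN_AGE, MAX_AGE + 1)
    q = 1.0 - np.exp(-a * np.exp(b * ages))
    q = np.clip(q, 1e-12, 1.0)
    q[-1] = 1.0
    return ages, q


def _interp(pooled: float, value: float, f: float) -> float:
    return pooled + f * (value - pooled)


def generate_parameters(spec: GeneratorSpec | None = None) -> ModelParameters:
    """Full synthetic bundle: Table-1 point estimates plus generated stand-ins.

    Deterministic in ``spec.seed``.  With ``effect_size == 0`` all per-arm
    fields collapse to the pooled mean, so the three arms are identical.
    """
    spec = spec or GeneratorSpec()
    rng = np.random.default_rng(spec.seed)
    # one multiplicative wobble per block keeps ordering invariants intact
    wobble = lambda: float(np.exp(spec.jitter * rng.standard_normal())) if spec.jitter else 1.0

    g = spec.cost_gradient
    m0 = TABLE1["maintenance"]["moderate"]
    w_cost = wobble()
    maintenance = {
        Severity.MODERATE: m0 * w_cost,
        Severity.SEVERE: (m0 + g * (TABLE1["maintenance"]["severe"] - m0)) * w_cost,
        Severity.VERY_SEVERE: (m0 + g * (TABLE1["maintenance"]["very_severe"] - m0)) * w_cost,
    }
    if g <= 0:
        raise ValueError("cost_gradient must be positive for increasing costs")
    costs = CostInputs(
        maintenance_annual=maintenance,
        moderate_exacerbation=TABLE1["cost_moderate_exacerbation"],
        severe_exacerbation=TABLE1["cost_severe_exacerbation"],
        pneumonia=(1 - TABLE1["pneumonia_p_hospitalised"]) * PNEUMONIA_UNIT_COSTS["ambulatory"]
        + TABLE1["pneumonia_p_hospitalised"] * PNEUMONIA_UNIT_COSTS["inpatient"],
        pneumonia_ambulatory=PNEUMONIA_UNIT_COSTS["ambulatory"],
        pneumonia_inpatient=PNEUMONIA_UNIT_COSTS["inpatient"],
        pneumonia_p_hospitalised=TABLE1["pneumonia_p_hospitalised"],
        replacement_class_costs_30d=dict(TABLE1["replacement_class_costs_30d"]),
        # societal stand-ins (used only under the societal perspective):
        # productivity loss per exacerbation event and per severity-year
        societal_per_event={"moderate_exacerbation": 300.0,
                            "severe_exacerbation": 1500.0,
                            "pneumonia": 800.0},
        societal_per_year={Severity.MODERATE: 250.0, Severity.SEVERE: 600.0,
                           Severity.VERY_SEVERE: 1400.0},
    )

    gu = spec.utility_gradient
    if gu <= 0:
        raise ValueError("utility_gradient must be positive for decreasing utilities")
    u0, ci0 = TABLE1["utility"]["moderate"]
    su, sci = {}, {}
    for sev in SEVERITIES:
        uv, ci = TABLE1["utility"][sev.label]
        su[sev] = u0 - gu * (u0 - uv)
        sci[sev] = ci
    du = {k: v[0] for k, v in TABLE1["disutility"].items()}
    dci = {k: v[1] for k, v in TABLE1["disutility"].items()}
    utilities = UtilityInputs(state_utility=su, state_utility_ci=sci,
                              disutility=du, disutility_ci=dci,
                              trial_baseline=TRIAL_BASELINE_EQ5D)

    ge = spec.exacerbation_gradient
    w_exac = wobble()
    base_mod = P_MODERATE_EXAC[0]
    base_sev = P_SEVERE_EXAC[0]
    p_mod = np.clip((base_mod + ge * (P_MODERATE_EXAC - base_mod)) * w_exac, 0.0, 1.0)
    p_sev = np.clip((base_sev + ge * (P_SEVERE_EXAC - base_sev)) * w_exac, 0.0, 1.0)
    w_prog = wobble()
    transitions = TransitionModel(
        p_moderate_to_severe=min(1.0, PROGRESSION["moderate_to_severe"]
                                 * spec.progression_gradient * w_prog),
        p_severe_to_very_severe=min(1.0, PROGRESSION["severe_to_very_severe"]
                                    * spec.progression_gradient * w_prog),
        p_moderate_to_very_severe=PROGRESSION["moderate_to_very_severe"],
        p_moderate_exac=p_mod,
        p_severe_exac=p_sev,
        coef_cov=_coef_covariance(spec),
    )

    ages, q = generate_life_table(spec.life_table_a, spec.life_table_b)
    mortality = MortalityModel(
        ages=ages, q_background=q,
        relative_risk={s: TABLE1["rr_mortality"][s.label] for s in SEVERITIES},
        copd_death_fraction=np.full(len(ages), spec.copd_death_fraction),
    )

    f = spec.effect_size
    labels = list(ARM_TABLE)
    pooled = {}
    for key in ("moderate_exacerbation_rate", "severe_exacerbation_rate",
                "pneumonia_probability", "trial_mortality", "discontinuation"):
        pooled[key] = float(np.mean([ARM_TABLE[lab][key] for lab in labels]))
    pooled["drug_cost_30d"] = float(np.mean(
        [TABLE1["drug_cost_30d"][lab] for lab in labels]))
    pooled["trial_end_distribution"] = np.mean(
        [np.asarray(ARM_TABLE[lab]["trial_end_distribution"]) for lab in labels], axis=0)
    pooled["replacement_mix"] = {
        cls: float(np.mean([ARM_TABLE[lab]["replacement_mix"][cls] for lab in labels]))
        for cls in ARM_TABLE[labels[0]]["replacement_mix"]
    }
    pooled_deltas = np.mean(
        [np.asarray(ARM_TABLE[lab]["trial_utility_deltas"])[:, 1] for lab in labels], axis=0)

    arms = {}
    for lab in labels:
        a = ARM_TABLE[lab]
        ted = np.asarray(a["trial_end_distribution"], dtype=float)
        ted = pooled["trial_end_distribution"] + f * (ted - pooled["trial_end_distribution"])
        ted = ted / ted.sum()
        mix = {cls: _interp(pooled["replacement_mix"][cls], v, f)
               for cls, v in a["replacement_mix"].items()}
        total = sum(mix.values())
        mix = {k: v / total for k, v in mix.items()}
        deltas = [
            (float(w), float(_interp(pooled_deltas[i], dv, f)))
            for i, (w, dv) in enumerate(a["trial_utility_deltas"])
        ]
        arms[lab] = ArmInputs(
            name=lab,
            drug_cost_30d=_interp(pooled["drug_cost_30d"],
                                  TABLE1["drug_cost_30d"][lab], f),
            moderate_exacerbation_rate=_interp(pooled["moderate_exacerbation_rate"],
                                               a["moderate_exacerbation_rate"], f),
            severe_exacerbation_rate=_interp(pooled["severe_exacerbation_rate"],
                                             a["severe_exacerbation_rate"], f),
            pneumonia_probability=_interp(pooled["pneumonia_probability"],
                                          a["pneumonia_probability"], f),
            trial_mortality=_interp(pooled["trial_mortality"], a["trial_mortality"], f),
            discontinuation=_interp(pooled["discontinuation"], a["discontinuation"], f),
            replacement_mix=mix,
            trial_end_distribution=ted,
            trial_utility_deltas=deltas,
        )

    bundle = ModelParameters(
        costs=costs, utilities=utilities, transitions=transitions, mortality=mortality,
        arms=arms, settings=ModelSettings(), intervention="FF/UMEC/VI",
        comparators=["FF/VI", "UMEC/VI"],
        meta={"provenance": "synthetic stand-in generated by copdce.synthetic "
                            f"(seed={spec.seed}); printed point estimates retained"},
    )
    bundle.validate()
    return bundle


def _coef_covariance(spec: GeneratorSpec) -> Optional[np.ndarray]:
    """AR(1)-correlated logit-scale covariance for the coefficient vector."""
    if spec.coef_sd <= 0:
        return None
    idx = np.arange(N_TRANSITION_COEF)
    corr = spec.coef_rho ** np.abs(idx[:, None] - idx[None, :])
    return (spec.coef_sd**2) * corr


def generate_psa_spec(
    bundle: ModelParameters,
    noise: float = 1.0,
    n_draws: int = 10_000,
    seed: int = 20_180_101,
) -> PSASpec:
    """Distribution assignment with means at the bundle's point estimates.

    ``noise`` scales every coefficient of variation; zero gives a degenerate
    spec whose draws all equal the base case.
    """
    spec = default_psa_spec(
        bundle, n_draws=n_draws, seed=seed,
        cost_cv=0.2 * noise, rate_cv=0.1 * noise, prob_cv=0.1 * noise,
        rr_cv=0.2 * noise, ci_sd_scale=noise,
    )
    if noise == 0.0:
        spec.coef_cov = None
    return spec


def base_case_bundle() -> ModelParameters:
    """The canonical analysis bundle (default generator, seed 0)."""
    return generate_parameters(GeneratorSpec())


def write_base_case(path: Union[str, Path]) -> None:
    """Serialise the canonical bundle to a YAML config file."""
    write_parameters(base_case_bundle(), path)


def toy_two_severity_bundle() -> ModelParameters:
    """Hand-traceable toy: two reachable severities, flat mortality.

    Background q = 0.1 at every age, mortality relative risk 2 for all
    severities, moderate-to-severe progression 0.2, no very-severe
    progression, moderate-exacerbation probability 0.3 in every state, no
    severe exacerbations.  Used as the brute-force oracle input in tests.
    """
    ages = np.arange(MIN_AGE, MAX_AGE + 1)
    bundle = ModelParameters(
        costs=CostInputs(
            maintenance_annual={Severity.MODERATE: 100.0, Severity.SEVERE: 200.0,
                                Severity.VERY_SEVERE: 300.0},
            moderate_exacerbation=50.0, severe_exacerbation=500.0, pneumonia=80.0,
            replacement_class_costs_30d={"lama": 10.0, "ics_laba": 10.0,
                                         "lama_laba": 10.0, "ics_lama_laba": 10.0},
        ),
        utilities=UtilityInputs(
            state_utility={Severity.MODERATE: 0.8, Severity.SEVERE: 0.7,
                           Severity.VERY_SEVERE: 0.6},
            state_utility_ci={}, disutility={"moderate_exacerbation": 0.01,
                                             "severe_exacerbation": 0.02,
                                             "pneumonia": 0.01},
            disutility_ci={}, trial_baseline=0.8,
        ),
        transitions=TransitionModel(
            p_moderate_to_severe=0.2,
            p_severe_to_very_severe=0.0,
            p_moderate_exac=np.full(6, 0.3),
            p_severe_exac=np.zeros(6),
        ),
        mortality=MortalityModel(
            ages=ages, q_background=np.full(len(ages), 0.1),
            relative_risk={Severity.MODERATE: 2.0, Severity.SEVERE: 2.0,
                           Severity.VERY_SEVERE: 2.0},
            copd_death_fraction=np.zeros(len(ages)),
        ),
        arms={"toy": ArmInputs(
            name="toy", drug_cost_30d=10.0,
            moderate_exacerbation_rate=0.5, severe_exacerbation_rate=0.0,
            pneumonia_probability=0.0, trial_mortality=0.0, discontinuation=0.0,
            replacement_mix={"lama": 1.0, "ics_laba": 0.0, "lama_laba": 0.0,
                             "ics_lama_laba": 0.0},
            trial_end_distribution=np.array([1.0, 0.0, 0.0, 0.0, 0.0, 0.0]),
        )},
        settings=ModelSettings(horizon_years=3),
        intervention="toy", comparators=[],
        meta={"provenance": "synthetic toy fixture"},
    )
    bundle.validate()
    return bundle
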