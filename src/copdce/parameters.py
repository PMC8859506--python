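"""Parameter schema, validation and config I/O for the cost-effectiveness model.

A full analysis is described by one :class:`ModelParameters` bundle:
unit costs and state utilities, annual transition/exacerbation probabilities
for the extrapolation phase, a background life table with severity-specific
mortality relative risks, per-arm 52-week trial outputs, and run settings
(horizon, discounting, perspective).  Bundles are read from and written to a
nested key-value YAML config so scenario overrides are shallow merges.
"""

from __future__ import annotations

import copy
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional, Union

import numpy as np
import yaml

from .states import (
    N_LIVING,
    SEVERITIES,
    STATE_LABELS,
    Severity,
    severity_of_living,
)

log = logging.getLogger(__name__)

REPLACEMENT_CLASSES = ("lama", "ics_laba", "lama_laba", "ics_lama_laba")
EVENT_KEYS = ("moderate_exacerbation", "severe_exacerbation", "pneumonia")
LIVING_LABELS = STATE_LABELS[:N_LIVING]

#: days per 30-day prescription unit in one average year
UNITS_PER_YEAR = 365.25 / 30.0
#: 26 weeks expressed in 30-day units (treatment-switch convention)
HALF_YEAR_UNITS = 26.0 * 7.0 / 30.0

MIN_AGE, MAX_AGE = 40, 110


class ParameterError(ValueError):
    """A config value is missing or violates a schema invariant."""

    def __init__(self, field_name: str, message: str):
        self.field_name = field_name
        super().__init__(f"{field_name}: {message}")


def _require(mapping: dict, key: str, context: str) -> Any:
    if key not in mapping:
        raise ParameterError(f"{context}.{key}", "required key missing")
    return mapping[key]


def _check_prob(value: float, name: str) -> float:
    value = float(value)
    if not 0.0 <= value <= 1.0:
        raise ParameterError(name, f"probability {value} outside [0, 1]")
    return value


def _check_nonneg(value: float, name: str) -> float:
    value = float(value)
    if value < 0:
        raise ParameterError(name, f"value {value} must be >= 0")
    return value


# ---------------------------------------------------------------------------
# costs


@dataclass
class CostInputs:
    """Unit costs, GBP at 2018 prices.

    ``pneumonia_ambulatory``/``pneumonia_inpatient`` are per-event management
    costs weighted by the hospitalised fraction into a single per-event cost;
    a pre-weighted ``pneumonia`` cost may be given instead.
    """

    maintenance_annual: dict[Severity, float]
    moderate_exacerbation: float
    severe_exacerbation: float
    pneumonia: float
    pneumonia_ambulatory: Optional[float] = None
    pneumonia_inpatient: Optional[float] = None
    pneumonia_p_hospitalised: Optional[float] = None
    replacement_class_costs_30d: dict[str, float] = field(default_factory=dict)
    societal_per_event: dict[str, float] = field(default_factory=dict)
    societal_per_year: dict[Severity, float] = field(default_factory=dict)

    def validate(self) -> None:
        for sev in SEVERITIES:
            if sev not in self.maintenance_annual:
                raise ParameterError(f"costs.maintenance_annual.{sev.label}", "missing")
            _check_nonneg(self.maintenance_annual[sev], f"costs.maintenance_annual.{sev.label}")
        m = [self.maintenance_annual[s] for s in SEVERITIES]
        if not (m[0] < m[1] < m[2]):
            raise ParameterError(
                "costs.maintenance_annual",
                f"must be strictly increasing with severity, got {m}",
            )
        for name in ("moderate_exacerbation", "severe_exacerbation", "pneumonia"):
            _check_nonneg(getattr(self, name), f"costs.{name}")
        for cls in REPLACEMENT_CLASSES:
            if cls not in self.replacement_class_costs_30d:
                raise ParameterError(f"costs.replacement_class_costs_30d.{cls}", "missing")
            _check_nonneg(self.replacement_class_costs_30d[cls],
                          f"costs.replacement_class_costs_30d.{cls}")
        for k, v in self.societal_per_event.items():
            _check_nonneg(v, f"costs.societal_per_event.{k}")
        for k, v in self.societal_per_year.items():
            _check_nonneg(v, f"costs.societal_per_year.{k.label}")


# ---------------------------------------------------------------------------
# utilities


@dataclass
class UtilityInputs:
    """Health-state utilities and per-event QALY losses (with 95% CIs)."""

    state_utility: dict[Severity, float]
    state_utility_ci: dict[Severity, tuple[float, float]]
    disutility: dict[str, float]
    disutility_ci: dict[str, tuple[float, float]]
    trial_baseline: float = 0.0

    def validate(self) -> None:
        for sev in SEVERITIES:
            if sev not in self.state_utility:
                raise ParameterError(f"utilities.states.{sev.label}", "missing")
            u = self.state_utility[sev]
            if not 0.0 <= u <= 1.0:
                raise ParameterError(
                    f"utilities.states.{sev.label}", f"utility {u} outside [0, 1]"
                )
        u = [self.state_utility[s] for s in SEVERITIES]
        if not (u[0] > u[1] > u[2]):
            raise ParameterError(
                "utilities.states", f"must be strictly decreasing with severity, got {u}"
            )
        for key in EVENT_KEYS:
            if key not in self.disutility:
                raise ParameterError(f"utilities.disutilities.{key}", "missing")
            _check_nonneg(self.disutility[key], f"utilities.disutilities.{key}")
        if not 0.0 <= self.trial_baseline <= 1.0:
            raise ParameterError(
                "utilities.trial_baseline", f"utility {self.trial_baseline} outside [0, 1]"
            )


# ---------------------------------------------------------------------------
# transitions

#: coefficient layout for the PSA logit interface:
#: [progression m->s, s->vs, m->vs] + moderate-exac probs (6) + severe-exac probs (6)
N_TRANSITION_COEF = 15
_LOGIT_CLIP = 1e-9


def _logit(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, _LOGIT_CLIP, 1.0 - _LOGIT_CLIP)
    return np.log(p / (1.0 - p))


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class TransitionModel:
    """Annual severity-progression and exacerbation probabilities.

    Progression is worsening-only (moderate->severe, severe->very severe,
    optionally moderate->very severe).  Exacerbation probabilities are the
    annual risk of at least one moderate / severe exacerbation per living
    state; per-cycle expected event counts equal these probabilities under
    the cohort expectation.  ``coef_cov`` is an optional covariance for the
    logit-scale coefficient vector, used for correlated PSA resampling.
    """

    p_moderate_to_severe: float
    p_severe_to_very_severe: float
    p_moderate_to_very_severe: float = 0.0
    p_moderate_exac: np.ndarray = field(default_factory=lambda: np.zeros(N_LIVING))
    p_severe_exac: np.ndarray = field(default_factory=lambda: np.zeros(N_LIVING))
    coef_cov: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.p_moderate_exac = np.asarray(self.p_moderate_exac, dtype=float)
        self.p_severe_exac = np.asarray(self.p_severe_exac, dtype=float)
        if self.coef_cov is not None:
            self.coef_cov = np.asarray(self.coef_cov, dtype=float)

    def validate(self) -> None:
        _check_prob(self.p_moderate_to_severe, "transitions.progression.moderate_to_severe")
        _check_prob(self.p_severe_to_very_severe, "transitions.progression.severe_to_very_severe")
        _check_prob(self.p_moderate_to_very_severe,
                    "transitions.progression.moderate_to_very_severe")
        if self.p_moderate_to_severe + self.p_moderate_to_very_severe > 1.0 + 1e-12:
            raise ParameterError(
                "transitions.progression",
                "outgoing probabilities from moderate sum to more than 1",
            )
        for label, arr in (("moderate_exacerbation", self.p_moderate_exac),
                           ("severe_exacerbation", self.p_severe_exac)):
            if arr.shape != (N_LIVING,):
                raise ParameterError(f"transitions.{label}", f"expected {N_LIVING} entries")
            for i, p in enumerate(arr):
                _check_prob(p, f"transitions.{label}.{LIVING_LABELS[i]}")
            # recent-history stratum carries at least the no-recent risk
            for sev in range(3):
                if arr[2 * sev + 1] < arr[2 * sev] - 1e-12:
                    raise ParameterError(
                        f"transitions.{label}",
                        f"risk in recent stratum below no-recent stratum for "
                        f"severity {SEVERITIES[sev].label}",
                    )
            # risk non-decreasing with severity within each stratum
            for stratum in (0, 1):
                col = arr[stratum::2]
                if np.any(np.diff(col) < -1e-12):
                    raise ParameterError(
                        f"transitions.{label}",
                        f"risk must be non-decreasing with severity (stratum "
                        f"{'recent' if stratum else 'no_recent'}), got {col.tolist()}",
                    )
        if self.coef_cov is not None:
            c = self.coef_cov
            if c.shape != (N_TRANSITION_COEF, N_TRANSITION_COEF):
                raise ParameterError("transitions.coef_cov",
                                     f"expected {N_TRANSITION_COEF}x{N_TRANSITION_COEF}")
            if not np.allclose(c, c.T, atol=1e-10):
                raise ParameterError("transitions.coef_cov", "not symmetric")

    def p_any_exac(self) -> np.ndarray:
        """Annual probability of >=1 exacerbation of any grade, per living state.

        Moderate and severe events are treated as independent within a cycle.
        """
        return 1.0 - (1.0 - self.p_moderate_exac) * (1.0 - self.p_severe_exac)

    def coefficient_mean(self) -> np.ndarray:
        """Point probabilities on the logit scale, in the fixed coefficient layout."""
        probs = np.concatenate((
            [self.p_moderate_to_severe, self.p_severe_to_very_severe,
             self.p_moderate_to_very_severe],
            self.p_moderate_exac,
            self.p_severe_exac,
        ))
        return _logit(probs)

    def from_coefficients(self, coef: np.ndarray) -> "TransitionModel":
        """Rebuild the model from a logit-scale coefficient vector."""
        coef = np.asarray(coef, dtype=float)
        if coef.shape != (N_TRANSITION_COEF,):
            raise ParameterError("coef", f"expected {N_TRANSITION_COEF} coefficients")
        p = _expit(coef)
        return TransitionModel(
            p_moderate_to_severe=float(p[0]),
            p_severe_to_very_severe=float(p[1]),
            p_moderate_to_very_severe=float(p[2]),
            p_moderate_exac=p[3:9].copy(),
            p_severe_exac=p[9:15].copy(),
            coef_cov=None if self.coef_cov is None else self.coef_cov.copy(),
        )

    def scaled_exacerbations(self, multiplier: float) -> "TransitionModel":
        """Copy with exacerbation probabilities scaled (clamped to [0, 1])."""
        return TransitionModel(
            p_moderate_to_severe=self.p_moderate_to_severe,
            p_severe_to_very_severe=self.p_severe_to_very_severe,
            p_moderate_to_very_severe=self.p_moderate_to_very_severe,
            p_moderate_exac=np.clip(self.p_moderate_exac * multiplier, 0.0, 1.0),
            p_severe_exac=np.clip(self.p_severe_exac * multiplier, 0.0, 1.0),
            coef_cov=self.coef_cov,
        )


# ---------------------------------------------------------------------------
# mortality


@dataclass
class MortalityModel:
    """Background annual death probability by age plus severity relative risks.

    The life table is a general-population table; when a COPD-death fraction
    is supplied the background probabilities are pre-adjusted at construction
    (q * (1 - fraction)) so the severity relative risks apply to non-COPD
    background mortality only.
    """

    ages: np.ndarray
    q_background: np.ndarray
    relative_risk: dict[Severity, float]
    copd_death_fraction: Optional[np.ndarray] = None
    _q_adjusted: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=int)
        self.q_background = np.asarray(self.q_background, dtype=float)
        if self.copd_death_fraction is not None:
            frac = np.asarray(self.copd_death_fraction, dtype=float)
            if frac.ndim == 0:
                frac = np.full_like(self.q_background, float(frac))
            self.copd_death_fraction = frac
            self._q_adjusted = self.q_background * (1.0 - frac)
        else:
            log.warning(
                "no COPD-death fraction supplied; using unadjusted background mortality"
            )
            self._q_adjusted = self.q_background.copy()

    def validate(self) -> None:
        if self.ages[0] > MIN_AGE or self.ages[-1] < MAX_AGE:
            raise ParameterError(
                "mortality.life_table",
                f"ages must cover [{MIN_AGE}, {MAX_AGE}], got "
                f"[{self.ages[0]}, {self.ages[-1]}]",
            )
        if np.any(np.diff(self.ages) != 1):
            raise ParameterError("mortality.life_table", "ages must be consecutive integers")
        for q in self.q_background:
            _check_prob(q, "mortality.life_table.q")
        rr = [self.relative_risk.get(s) for s in SEVERITIES]
        if any(r is None for r in rr):
            raise ParameterError("mortality.relative_risk", "all three severities required")
        if any(r < 1.0 for r in rr) or not (rr[0] <= rr[1] <= rr[2]):
            raise ParameterError(
                "mortality.relative_risk",
                f"relative risks must be >= 1 and non-decreasing with severity, got {rr}",
            )

    def background_q(self, age: float) -> float:
        """Adjusted annual death probability at ``floor(age)`` (clamped to table)."""
        idx = int(np.clip(math.floor(age), self.ages[0], self.ages[-1]) - self.ages[0])
        return float(self._q_adjusted[idx])

    def rr_by_living_state(self) -> np.ndarray:
        sev = severity_of_living()
        return np.array([self.relative_risk[Severity(s)] for s in sev])


# ---------------------------------------------------------------------------
# arms


@dataclass
class ArmInputs:
    """52-week trial outputs and prices for one treatment arm."""

    name: str
    drug_cost_30d: float
    moderate_exacerbation_rate: float  # events per patient-year
    severe_exacerbation_rate: float
    pneumonia_probability: float  # annual, arm-specific, severity-independent
    trial_mortality: float
    discontinuation: float
    replacement_mix: dict[str, float]
    trial_end_distribution: np.ndarray  # over the 6 living states, survivors
    trial_utility_deltas: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.trial_end_distribution = np.asarray(self.trial_end_distribution, dtype=float)

    def validate(self) -> None:
        ctx = f"arms.{self.name}"
        _check_nonneg(self.drug_cost_30d, f"{ctx}.drug_cost_30d")
        _check_nonneg(self.moderate_exacerbation_rate, f"{ctx}.moderate_exacerbation_rate")
        _check_nonneg(self.severe_exacerbation_rate, f"{ctx}.severe_exacerbation_rate")
        _check_prob(self.pneumonia_probability, f"{ctx}.pneumonia_probability")
        _check_prob(self.trial_mortality, f"{ctx}.trial_mortality")
        _check_prob(self.discontinuation, f"{ctx}.discontinuation")
        mix_sum = 0.0
        for cls in REPLACEMENT_CLASSES:
            if cls not in self.replacement_mix:
                raise ParameterError(f"{ctx}.replacement_mix.{cls}", "missing")
            mix_sum += _check_prob(self.replacement_mix[cls], f"{ctx}.replacement_mix.{cls}")
        if abs(mix_sum - 1.0) > 1e-6:
            raise ParameterError(f"{ctx}.replacement_mix", f"mix sums to {mix_sum}, not 1")
        d = self.trial_end_distribution
        if d.shape != (N_LIVING,):
            raise ParameterError(f"{ctx}.trial_end_distribution",
                                 f"expected {N_LIVING} living states")
        if np.any(d < -1e-12) or abs(d.sum() - 1.0) > 1e-6:
            raise ParameterError(
                f"{ctx}.trial_end_distribution",
                f"must be non-negative and sum to 1 over survivors, sums to {d.sum():.8f}",
            )
        weeks = [w for w, _ in self.trial_utility_deltas]
        if any(not 0 <= w <= 52 for w in weeks):
            raise ParameterError(f"{ctx}.trial_utility_deltas", "weeks must lie in [0, 52]")
        if weeks != sorted(weeks):
            raise ParameterError(f"{ctx}.trial_utility_deltas", "weeks must be sorted")


# ---------------------------------------------------------------------------
# settings


@dataclass
class PostTrialEffect:
    """Direct post-trial exacerbation effect (scenario analyses only).

    ``reduction`` is the fractional reduction applied to the intervention
    arm's exacerbation probabilities, or ``"auto"`` to use the relative
    reduction in total 52-week exacerbation rate versus the comparator.
    With ``waning`` the reduction declines linearly to zero over
    ``duration_years``; without, it holds fully then stops.
    """

    duration_years: int = 0
    waning: bool = False
    reduction: Union[float, str] = "auto"

    def validate(self) -> None:
        if self.duration_years < 0:
            raise ParameterError("settings.posttrial_effect.duration_years", "must be >= 0")
        if isinstance(self.reduction, str):
            if self.reduction != "auto":
                raise ParameterError("settings.posttrial_effect.reduction",
                                     f"expected a fraction or 'auto', got {self.reduction!r}")
        else:
            _check_prob(self.reduction, "settings.posttrial_effect.reduction")


DEFAULT_WTP_GRID = tuple(float(x) for x in range(0, 50001, 1000))


@dataclass
class ModelSettings:
    """Run settings: horizon, discounting, perspective and scenario switches."""

    horizon_years: int = 35
    cycle_years: float = 1.0
    discount_rate_costs: float = 0.035
    discount_rate_benefits: float = 0.035
    wtp_grid: tuple[float, ...] = DEFAULT_WTP_GRID
    start_age: float = 65.3
    male_fraction: float = 0.66
    perspective: str = "health_service"
    include_trial_mortality: bool = True
    include_discontinuation: bool = True
    trial_utility_source: str = "eq5d"  # or "state"
    pooled_replacement_mix: bool = False
    posttrial_effect: Optional[PostTrialEffect] = None

    def validate(self) -> None:
        if self.horizon_years < 1:
            raise ParameterError("settings.horizon_years", "must be >= 1")
        if self.cycle_years != 1.0:
            raise ParameterError("settings.cycle_years", "cycle length is fixed at 1 year")
        _check_nonneg(self.discount_rate_costs, "settings.discount_rate_costs")
        _check_nonneg(self.discount_rate_benefits, "settings.discount_rate_benefits")
        if self.perspective not in ("health_service", "societal"):
            raise ParameterError("settings.perspective",
                                 f"unknown perspective {self.perspective!r}")
        if self.trial_utility_source not in ("eq5d", "state"):
            raise ParameterError("settings.trial_utility_source",
                                 f"unknown source {self.trial_utility_source!r}")
        if not 0.0 <= self.male_fraction <= 1.0:
            raise ParameterError("settings.male_fraction", "must lie in [0, 1]")
        if not self.wtp_grid:
            raise ParameterError("settings.wtp_grid", "must be non-empty")
        if self.posttrial_effect is not None:
            self.posttrial_effect.validate()


# ---------------------------------------------------------------------------
# full bundle


@dataclass
class ModelParameters:
    """Everything needed for one analysis run."""

    costs: CostInputs
    utilities: UtilityInputs
    transitions: TransitionModel
    mortality: MortalityModel
    arms: dict[str, ArmInputs]
    settings: ModelSettings
    intervention: str
    comparators: list[str]
    meta: dict = field(default_factory=dict)

    def validate(self) -> None:
        self.costs.validate()
        self.utilities.validate()
        self.transitions.validate()
        self.mortality.validate()
        self.settings.validate()
        if not self.arms:
            raise ParameterError("arms", "at least one arm required")
        for arm in self.arms.values():
            arm.validate()
        for label in [self.intervention, *self.comparators]:
            if label not in self.arms:
                raise ParameterError("comparison", f"arm {label!r} not defined under arms")

    def copy(self) -> "ModelParameters":
        return copy.deepcopy(self)

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        c = self.costs
        u = self.utilities
        t = self.transitions
        m = self.mortality
        s = self.settings
        d: dict[str, Any] = {}
        if self.meta:
            d["meta"] = copy.deepcopy(self.meta)
        d["settings"] = {
            "horizon_years": s.horizon_years,
            "cycle_years": s.cycle_years,
            "discount_rate_costs": s.discount_rate_costs,
            "discount_rate_benefits": s.discount_rate_benefits,
            "wtp_grid": list(s.wtp_grid),
            "start_age": s.start_age,
            "male_fraction": s.male_fraction,
            "perspective": s.perspective,
            "include_trial_mortality": s.include_trial_mortality,
            "include_discontinuation": s.include_discontinuation,
            "trial_utility_source": s.trial_utility_source,
            "pooled_replacement_mix": s.pooled_replacement_mix,
        }
        if s.posttrial_effect is not None:
            d["settings"]["posttrial_effect"] = {
                "duration_years": s.posttrial_effect.duration_years,
                "waning": s.posttrial_effect.waning,
                "reduction": s.posttrial_effect.reduction,
            }
        d["costs"] = {
            "maintenance_annual": {sev.label: c.maintenance_annual[sev] for sev in SEVERITIES},
            "moderate_exacerbation": c.moderate_exacerbation,
            "severe_exacerbation": c.severe_exacerbation,
            "replacement_class_costs_30d": {k: c.replacement_class_costs_30d[k]
                                            for k in REPLACEMENT_CLASSES},
        }
        if c.pneumonia_ambulatory is not None:
            d["costs"]["pneumonia"] = {
                "ambulatory": c.pneumonia_ambulatory,
                "inpatient": c.pneumonia_inpatient,
                "p_hospitalised": c.pneumonia_p_hospitalised,
            }
        else:
            d["costs"]["pneumonia"] = c.pneumonia
        if c.societal_per_event or c.societal_per_year:
            d["costs"]["societal"] = {
                "per_event": dict(c.societal_per_event),
                "per_year": {sev.label: v for sev, v in c.societal_per_year.items()},
            }
        d["utilities"] = {
            "states": {
                sev.label: {"value": u.state_utility[sev],
                            "ci": list(u.state_utility_ci.get(sev, ()))}
                for sev in SEVERITIES
            },
            "disutilities": {
                k: {"value": u.disutility[k], "ci": list(u.disutility_ci.get(k, ()))}
                for k in EVENT_KEYS
            },
            "trial_baseline": u.trial_baseline,
        }
        d["transitions"] = {
            "progression": {
                "moderate_to_severe": t.p_moderate_to_severe,
                "severe_to_very_severe": t.p_severe_to_very_severe,
                "moderate_to_very_severe": t.p_moderate_to_very_severe,
            },
            "moderate_exacerbation": {LIVING_LABELS[i]: float(t.p_moderate_exac[i])
                                      for i in range(N_LIVING)},
            "severe_exacerbation": {LIVING_LABELS[i]: float(t.p_severe_exac[i])
                                    for i in range(N_LIVING)},
        }
        if t.coef_cov is not None:
            d["transitions"]["coef_cov"] = [[float(x) for x in row] for row in t.coef_cov]
        d["mortality"] = {
            "relative_risk": {sev.label: m.relative_risk[sev] for sev in SEVERITIES},
            "life_table": {
                "table": [[int(a), float(q)] for a, q in zip(m.ages, m.q_background)],
            },
        }
        if m.copd_death_fraction is not None:
            d["mortality"]["life_table"]["copd_death_fraction"] = [
                float(x) for x in m.copd_death_fraction
            ]
        d["arms"] = {}
        for label, arm in self.arms.items():
            d["arms"][label] = {
                "drug_cost_30d": arm.drug_cost_30d,
                "moderate_exacerbation_rate": arm.moderate_exacerbation_rate,
                "severe_exacerbation_rate": arm.severe_exacerbation_rate,
                "pneumonia_probability": arm.pneumonia_probability,
                "trial_mortality": arm.trial_mortality,
                "discontinuation": arm.discontinuation,
                "replacement_mix": {k: arm.replacement_mix[k] for k in REPLACEMENT_CLASSES},
                "trial_end_distribution": {
                    LIVING_LABELS[i]: float(arm.trial_end_distribution[i])
                    for i in range(N_LIVING)
                },
                "trial_utility_deltas": [[float(w), float(dv)]
                                         for w, dv in arm.trial_utility_deltas],
            }
        d["comparison"] = {"intervention": self.intervention,
                           "comparators": list(self.comparators)}
        return d


# ---------------------------------------------------------------------------
# loading


def _severity_dict(raw: dict, context: str) -> dict[Severity, float]:
    out = {}
    for sev in SEVERITIES:
        out[sev] = float(_require(raw, sev.label, context))
    return out


def _load_life_table(raw: dict) -> tuple[np.ndarray, np.ndarray, Optional[np.ndarray]]:
    ages = np.arange(MIN_AGE, MAX_AGE + 1)
    if "table" in raw:
        arr = np.asarray(raw["table"], dtype=float)
        ages = arr[:, 0].astype(int)
        q = arr[:, 1]
    elif "path" in raw:
        arr = np.loadtxt(raw["path"], delimiter=",", skiprows=1)
        ages = arr[:, 0].astype(int)
        q = arr[:, 1]
    elif "gompertz" in raw:
        g = raw["gompertz"]
        a = float(_require(g, "a", "mortality.life_table.gompertz"))
        b = float(_require(g, "b", "mortality.life_table.gompertz"))
        q = 1.0 - np.exp(-a * np.exp(b * ages))
        q[-1] = 1.0
    else:
        raise ParameterError("mortality.life_table",
                             "one of 'table', 'path' or 'gompertz' required")
    frac = raw.get("copd_death_fraction")
    if frac is not None:
        frac = np.asarray(frac, dtype=float)
    return ages, np.clip(q, 0.0, 1.0), frac


def from_dict(raw: dict) -> ModelParameters:
    """Build and validate a bundle from a nested plain-dict config."""
    if not isinstance(raw, dict):
        raise ParameterError("config", "top level must be a mapping")

    sraw = dict(raw.get("settings", {}))
    pte = None
    if "posttrial_effect" in sraw:
        p = sraw.pop("posttrial_effect")
        if p is not None:
            pte = PostTrialEffect(
                duration_years=int(p.get("duration_years", 0)),
                waning=bool(p.get("waning", False)),
                reduction=p.get("reduction", "auto"),
            )
    known = {f for f in ModelSettings.__dataclass_fields__}
    unknown = set(sraw) - known
    if unknown:
        raise ParameterError(f"settings.{sorted(unknown)[0]}", "unknown settings key")
    if "wtp_grid" in sraw:
        sraw["wtp_grid"] = tuple(float(x) for x in sraw["wtp_grid"])
    settings = ModelSettings(**sraw, posttrial_effect=pte)

    craw = _require(raw, "costs", "config")
    pneu = _require(craw, "pneumonia", "costs")
    if isinstance(pneu, dict):
        amb = float(_require(pneu, "ambulatory", "costs.pneumonia"))
        inp = float(_require(pneu, "inpatient", "costs.pneumonia"))
        ph = _check_prob(_require(pneu, "p_hospitalised", "costs.pneumonia"),
                         "costs.pneumonia.p_hospitalised")
        pneu_cost = (1.0 - ph) * amb + ph * inp
    else:
        amb = inp = ph = None
        pneu_cost = float(pneu)
    soc = craw.get("societal", {})
    costs = CostInputs(
        maintenance_annual=_severity_dict(
            _require(craw, "maintenance_annual", "costs"), "costs.maintenance_annual"),
        moderate_exacerbation=float(_require(craw, "moderate_exacerbation", "costs")),
        severe_exacerbation=float(_require(craw, "severe_exacerbation", "costs")),
        pneumonia=pneu_cost,
        pneumonia_ambulatory=amb,
        pneumonia_inpatient=inp,
        pneumonia_p_hospitalised=ph,
        replacement_class_costs_30d={
            k: float(v)
            for k, v in _require(craw, "replacement_class_costs_30d", "costs").items()
        },
        societal_per_event={k: float(v) for k, v in soc.get("per_event", {}).items()},
        societal_per_year={
            Severity[k.upper()]: float(v) for k, v in soc.get("per_year", {}).items()
        },
    )

    uraw = _require(raw, "utilities", "config")
    states = _require(uraw, "states", "utilities")
    disut = _require(uraw, "disutilities", "utilities")

    def _val_ci(entry: Any) -> tuple[float, tuple[float, float]]:
        if isinstance(entry, dict):
            v = float(_require(entry, "value", "utilities"))
            ci = tuple(float(x) for x in entry.get("ci", ()))
            return v, ci
        return float(entry), ()

    su, sci, du, dci = {}, {}, {}, {}
    for sev in SEVERITIES:
        v, ci = _val_ci(_require(states, sev.label, "utilities.states"))
        su[sev], sci[sev] = v, ci
    for key in EVENT_KEYS:
        v, ci = _val_ci(_require(disut, key, "utilities.disutilities"))
        du[key], dci[key] = v, ci
    utilities = UtilityInputs(
        state_utility=su, state_utility_ci=sci, disutility=du, disutility_ci=dci,
        trial_baseline=float(uraw.get("trial_baseline", 0.0)),
    )

    traw = _require(raw, "transitions", "config")
    prog = _require(traw, "progression", "transitions")
    mod_e = _require(traw, "moderate_exacerbation", "transitions")
    sev_e = _require(traw, "severe_exacerbation", "transitions")
    transitions = TransitionModel(
        p_moderate_to_severe=float(_require(prog, "moderate_to_severe",
                                            "transitions.progression")),
        p_severe_to_very_severe=float(_require(prog, "severe_to_very_severe",
                                               "transitions.progression")),
        p_moderate_to_very_severe=float(prog.get("moderate_to_very_severe", 0.0)),
        p_moderate_exac=np.array([
            float(_require(mod_e, lab, "transitions.moderate_exacerbation"))
            for lab in LIVING_LABELS
        ]),
        p_severe_exac=np.array([
            float(_require(sev_e, lab, "transitions.severe_exacerbation"))
            for lab in LIVING_LABELS
        ]),
        coef_cov=np.asarray(traw["coef_cov"], dtype=float) if "coef_cov" in traw else None,
    )

    mraw = _require(raw, "mortality", "config")
    ages, q, frac = _load_life_table(_require(mraw, "life_table", "mortality"))
    mortality = MortalityModel(
        ages=ages,
        q_background=q,
        relative_risk=_severity_dict(_require(mraw, "relative_risk", "mortality"),
                                     "mortality.relative_risk"),
        copd_death_fraction=frac,
    )

    araw = _require(raw, "arms", "config")
    arms = {}
    for label, a in araw.items():
        ctx = f"arms.{label}"
        ted = _require(a, "trial_end_distribution", ctx)
        if isinstance(ted, dict):
            ted = [float(_require(ted, lab, f"{ctx}.trial_end_distribution"))
                   for lab in LIVING_LABELS]
        arms[label] = ArmInputs(
            name=label,
            drug_cost_30d=float(_require(a, "drug_cost_30d", ctx)),
            moderate_exacerbation_rate=float(_require(a, "moderate_exacerbation_rate", ctx)),
            severe_exacerbation_rate=float(_require(a, "severe_exacerbation_rate", ctx)),
            pneumonia_probability=float(_require(a, "pneumonia_probability", ctx)),
            trial_mortality=float(_require(a, "trial_mortality", ctx)),
            discontinuation=float(_require(a, "discontinuation", ctx)),
            replacement_mix={k: float(v) for k, v in _require(a, "replacement_mix", ctx).items()},
            trial_end_distribution=np.asarray(ted, dtype=float),
            trial_utility_deltas=[(float(w), float(dv))
                                  for w, dv in a.get("trial_utility_deltas", [])],
        )

    comp = raw.get("comparison", {})
    labels = list(arms)
    intervention = comp.get("intervention", labels[0])
    comparators = list(comp.get("comparators", [x for x in labels if x != intervention]))

    bundle = ModelParameters(
        costs=costs, utilities=utilities, transitions=transitions, mortality=mortality,
        arms=arms, settings=settings, intervention=intervention, comparators=comparators,
        meta=dict(raw.get("meta", {})),
    )
    bundle.validate()
    return bundle


def load_parameters(config_path: Union[str, Path]) -> ModelParameters:
    """Read, validate and default-fill a model config file (YAML)."""
    path = Path(config_path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return from_dict(raw)


def write_parameters(bundle: ModelParameters, path: Union[str, Path]) -> None:
    """Serialise a bundle back to YAML; round-trips through ``load_parameters``."""
    with open(path, "w") as fh:
        yaml.safe_dump(bundle.to_dict(), fh, sort_keys=False, default_flow_style=None)
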