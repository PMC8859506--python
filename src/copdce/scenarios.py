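"""Declarative scenario engine: named overrides on the base configuration.

Each scenario is a shallow set of overrides (discount rates, within-trial
mortality, direct post-trial effect, discontinuation, horizon, replacement
mix pooling, perspective, within-trial utility source) applied to a copy of
the base bundle; the full pipeline is then re-run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .economics import run_comparison
from .parameters import (
    REPLACEMENT_CLASSES,
    ModelParameters,
    ParameterError,
    PostTrialEffect,
)

VALID_OVERRIDES = (
    "discount_rate",            # sets both cost and benefit rates
    "within_trial_mortality",   # bool
    "posttrial_effect",         # {duration_years, waning, reduction}
    "discontinuation",          # bool
    "horizon",                  # "trial" or integer years
    "replacement_mix",          # "pooled"
    "perspective",              # "societal" | "health_service"
    "trial_utility",            # "state" | "eq5d"
)


@dataclass
class ScenarioSpec:
    """A named scenario: override keys restricted to :data:`VALID_OVERRIDES`."""

    name: str
    overrides: dict[str, Any] = field(default_factory=dict)

    def validate(self) -> None:
        for key in self.overrides:
            if key not in VALID_OVERRIDES:
                raise ParameterError(
                    f"scenario.{self.name}.{key}",
                    f"unknown override; valid keys: {list(VALID_OVERRIDES)}",
                )


def apply_scenario(base: ModelParameters, spec: ScenarioSpec) -> ModelParameters:
    """Return a copy of ``base`` with the scenario's overrides applied.

    Idempotent: applying the same spec twice gives the same bundle.
    """
    spec.validate()
    p = base.copy()
    s = p.settings
    ov = spec.overrides
    if "discount_rate" in ov:
        rate = float(ov["discount_rate"])
        s.discount_rate_costs = rate
        s.discount_rate_benefits = rate
    if "within_trial_mortality" in ov:
        s.include_trial_mortality = bool(ov["within_trial_mortality"])
    if "discontinuation" in ov:
        s.include_discontinuation = bool(ov["discontinuation"])
    if "horizon" in ov:
        h = ov["horizon"]
        s.horizon_years = 1 if h == "trial" else int(h)
    if "perspective" in ov:
        s.perspective = str(ov["perspective"])
    if "trial_utility" in ov:
        s.trial_utility_source = str(ov["trial_utility"])
    if "posttrial_effect" in ov:
        e = ov["posttrial_effect"]
        s.posttrial_effect = None if e is None else PostTrialEffect(
            duration_years=int(e.get("duration_years", 0)),
            waning=bool(e.get("waning", False)),
            reduction=e.get("reduction", "auto"),
        )
    if ov.get("replacement_mix") == "pooled":
        pooled = {
            cls: float(np.mean([a.replacement_mix[cls] for a in base.arms.values()]))
            for cls in REPLACEMENT_CLASSES
        }
        total = sum(pooled.values())
        pooled = {k: v / total for k, v in pooled.items()}
        for arm in p.arms.values():
            arm.replacement_mix = dict(pooled)
    p.validate()
    return p


#: the standard scenario suite (base-case switches only; societal costs use
#: whatever per-event/per-year values the config supplies)
STANDARD_SCENARIOS = [
    ScenarioSpec("discount_0pct", {"discount_rate": 0.0}),
    ScenarioSpec("discount_5pct", {"discount_rate": 0.05}),
    ScenarioSpec("no_within_trial_mortality", {"within_trial_mortality": False}),
    ScenarioSpec("direct_effect_1y",
                 {"posttrial_effect": {"duration_years": 1, "waning": False}}),
    ScenarioSpec("direct_effect_3y",
                 {"posttrial_effect": {"duration_years": 3, "waning": False}}),
    ScenarioSpec("direct_effect_5y",
                 {"posttrial_effect": {"duration_years": 5, "waning": False}}),
    ScenarioSpec("direct_effect_5y_waning",
                 {"posttrial_effect": {"duration_years": 5, "waning": True}}),
    ScenarioSpec("no_discontinuation", {"discontinuation": False}),
    ScenarioSpec("trial_horizon", {"horizon": "trial"}),
    ScenarioSpec("pooled_replacement_mix", {"replacement_mix": "pooled"}),
    ScenarioSpec("societal_perspective", {"perspective": "societal"}),
    ScenarioSpec("state_utilities_within_trial", {"trial_utility": "state"}),
]


def run_scenario_suite(
    base: ModelParameters,
    specs: list[ScenarioSpec] | None = None,
) -> pd.DataFrame:
    """One row per scenario (base case first) with per-comparator increments.

    Columns per comparator: delta_cost, delta_qaly and the ICER per QALY
    (or the dominance verdict where no ratio is reported).
    """
    specs = STANDARD_SCENARIOS if specs is None else specs
    rows = []

    def row_for(name: str, params: ModelParameters) -> dict[str, Any]:
        _, comparisons = run_comparison(params)
        row: dict[str, Any] = {"scenario": name}
        for comp, cr in comparisons.items():
            row[f"delta_cost_vs_{comp}"] = cr.delta_cost
            row[f"delta_qaly_vs_{comp}"] = cr.delta_qaly
            row[f"icer_vs_{comp}"] = cr.icer_label("qaly")
        return row

    rows.append(row_for("base_case", base))
    for spec in specs:
        rows.append(row_for(spec.name, apply_scenario(base, spec)))
    return pd.DataFrame(rows)
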