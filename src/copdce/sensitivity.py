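"""Deterministic and probabilistic sensitivity analysis.

One-way analysis perturbs single parameters (default +/-20%) through full
model re-runs and reports the resulting ICER span (tornado table).  The
probabilistic analysis assigns standard health-economic distributions (beta
for probabilities and utilities, gamma for costs and rates, log-normal for
relative risks), samples the transition/exacerbation coefficient vector
jointly via a Cholesky factor of its covariance, re-runs the model per draw,
and summarises the incremental cloud as cost-effectiveness acceptability
curves under the net-monetary-benefit rule.
"""

from __future__ import annotations

import copy
import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .economics import compare, run_arm
from .parameters import ModelParameters, ParameterError
from .states import SEVERITIES, Severity

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# one-way sensitivity analysis


@dataclass
class OWSASpec:
    """Parameters to perturb and the perturbation size (fraction of base)."""

    parameters: list[str]
    perturbation: float = 0.20
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)  # scale factors

    def factors(self, name: str) -> tuple[float, float]:
        if name in self.bounds:
            return self.bounds[name]
        return 1.0 - self.perturbation, 1.0 + self.perturbation


def _scale_utility(sev: Severity) -> Callable[[ModelParameters, float], None]:
    def apply(p: ModelParameters, f: float) -> None:
        u = p.utilities.state_utility[sev] * f
        if u > 1.0:
            log.warning("utility %s clamped to 1.0", sev.label)
            u = 1.0
        p.utilities.state_utility[sev] = u
    return apply


def _scale_exac_rates(p: ModelParameters, f: float) -> None:
    for arm in p.arms.values():
        arm.moderate_exacerbation_rate *= f
        arm.severe_exacerbation_rate *= f
    p.transitions = p.transitions.scaled_exacerbations(f)


def _scale_mortality_rr(p: ModelParameters, f: float) -> None:
    for sev in SEVERITIES:
        rr = p.mortality.relative_risk[sev] * f
        if rr < 1.0:
            log.warning("mortality RR %s clamped to 1.0", sev.label)
            rr = 1.0
        p.mortality.relative_risk[sev] = rr


def _scale_maintenance(p: ModelParameters, f: float) -> None:
    for sev in SEVERITIES:
        p.costs.maintenance_annual[sev] *= f


def _scale_drug_cost(arm_label: str) -> Callable[[ModelParameters, float], None]:
    def apply(p: ModelParameters, f: float) -> None:
        p.arms[arm_label].drug_cost_30d *= f
    return apply


def owsa_appliers(params: ModelParameters) -> dict[str, Callable[[ModelParameters, float], None]]:
    """Registry of perturbable parameters for the tornado analysis."""
    reg: dict[str, Callable[[ModelParameters, float], None]] = {
        "utility_moderate": _scale_utility(Severity.MODERATE),
        "utility_very_severe": _scale_utility(Severity.VERY_SEVERE),
        "exacerbation_rates": _scale_exac_rates,
        "mortality_risk": _scale_mortality_rr,
        "maintenance_costs": _scale_maintenance,
    }
    for label in params.arms:
        reg[f"drug_cost_{label}"] = _scale_drug_cost(label)
    return reg


def default_owsa_spec(params: ModelParameters) -> OWSASpec:
    return OWSASpec(parameters=sorted(owsa_appliers(params)))


def _pair_icer(params: ModelParameters, intervention: str, comparator: str) -> float:
    """Raw incremental ratio (may be negative in dominance quadrants)."""
    res_i = run_arm(params, intervention)
    res_c = run_arm(params, comparator)
    d_cost = res_i.total_cost - res_c.total_cost
    d_qaly = res_i.qalys - res_c.qalys
    if d_qaly == 0.0:
        return math.nan
    return d_cost / d_qaly


def run_owsa(
    base: ModelParameters,
    spec: OWSASpec,
    comparison: Optional[tuple[str, str]] = None,
) -> pd.DataFrame:
    """Tornado table: low/high ICER per perturbed parameter, sorted by span.

    ICERs are the raw incremental ratios from full model re-runs with one
    parameter moved at a time, all else held at base case.
    """
    if comparison is None:
        comparison = (base.intervention, base.comparators[0])
    intervention, comparator = comparison
    appliers = owsa_appliers(base)
    base_icer = _pair_icer(base, intervention, comparator)

    rows = []
    for name in sorted(spec.parameters):
        if name not in appliers:
            raise ParameterError(f"owsa.{name}",
                                 f"unknown parameter; valid: {sorted(appliers)}")
        lo_f, hi_f = spec.factors(name)
        icers = []
        for f in (lo_f, hi_f):
            p = base.copy()
            appliers[name](p, f)
            icers.append(_pair_icer(p, intervention, comparator))
        rows.append({
            "parameter": name,
            "low_icer": icers[0],
            "high_icer": icers[1],
            "base_icer": base_icer,
            "span": abs(icers[1] - icers[0]),
        })
    df = pd.DataFrame(rows).sort_values(
        ["span", "parameter"], ascending=[False, True]
    ).reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# Cholesky


def cholesky_factor(cov: np.ndarray) -> np.ndarray:
    """Lower-triangular L with L @ L.T == cov.

    Raises on asymmetric or non-positive-semi-definite input, naming the
    first offending leading principal minor.  Exactly semi-definite inputs
    are handled by a tiny diagonal jitter on the zero eigendirections.
    """
    cov = np.asarray(cov, dtype=float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ValueError("covariance must be a square matrix")
    if not np.allclose(cov, cov.T, atol=1e-10):
        raise ValueError("covariance must be symmetric")
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        pass
    # locate the first non-PSD leading minor for the error message, or
    # factor a PSD-but-singular matrix via jitter
    eigmin = float(np.linalg.eigvalsh(cov).min())
    if eigmin >= -1e-12 * max(1.0, float(np.abs(cov).max())):
        jitter = 1e-12 * max(1.0, float(np.trace(cov)) / len(cov))
        return np.linalg.cholesky(cov + jitter * np.eye(len(cov)))
    for k in range(1, len(cov) + 1):
        if np.linalg.det(cov[:k, :k]) < -1e-12:
            raise ValueError(
                f"covariance is not positive semi-definite: leading minor of order "
                f"{k} is negative"
            )
    raise ValueError("covariance is not positive semi-definite")


# ---------------------------------------------------------------------------
# distributions


@dataclass
class DistSpec:
    """One sampled parameter: distribution family plus hyperparameters."""

    family: str  # beta | gamma | lognormal | fixed
    params: dict[str, float]

    def mean(self) -> float:
        p = self.params
        if self.family == "beta":
            return p["alpha"] / (p["alpha"] + p["beta"])
        if self.family == "gamma":
            return p["shape"] * p["scale"]
        if self.family == "lognormal":
            return math.exp(p["mu"] + 0.5 * p["sigma"] ** 2)
        if self.family == "fixed":
            return p["value"]
        raise ValueError(f"unknown family {self.family!r}")

    def sample(self, rng: np.random.Generator) -> float:
        p = self.params
        if self.family == "beta":
            return float(rng.beta(p["alpha"], p["beta"]))
        if self.family == "gamma":
            return float(rng.gamma(p["shape"], p["scale"]))
        if self.family == "lognormal":
            return float(rng.lognormal(p["mu"], p["sigma"]))
        if self.family == "fixed":
            return p["value"]
        raise ValueError(f"unknown family {self.family!r}")


def beta_from_mean_sd(mean: float, sd: float) -> DistSpec:
    """Method-of-moments beta; degenerates to fixed when sd == 0."""
    if not 0.0 < mean < 1.0:
        if sd == 0.0:
            return DistSpec("fixed", {"value": mean})
        raise ValueError(f"beta mean must lie in (0, 1), got {mean}")
    if sd <= 0.0:
        return DistSpec("fixed", {"value": mean})
    nu = mean * (1.0 - mean) / sd**2 - 1.0
    if nu <= 0:
        raise ValueError(f"sd {sd} too large for a beta with mean {mean}")
    return DistSpec("beta", {"alpha": mean * nu, "beta": (1.0 - mean) * nu})


def beta_from_mean_ci(mean: float, ci: Sequence[float], sd_scale: float = 1.0) -> DistSpec:
    sd = (ci[1] - ci[0]) / 3.92 if len(ci) == 2 else 0.0
    return beta_from_mean_sd(mean, sd * sd_scale)


def gamma_from_mean_sd(mean: float, sd: float) -> DistSpec:
    if mean <= 0.0 or sd <= 0.0:
        return DistSpec("fixed", {"value": mean})
    shape = (mean / sd) ** 2
    return DistSpec("gamma", {"shape": shape, "scale": mean / shape})


def lognormal_from_mean_sd(mean: float, sd: float) -> DistSpec:
    if mean <= 0.0 or sd <= 0.0:
        return DistSpec("fixed", {"value": mean})
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    return DistSpec("lognormal", {"mu": math.log(mean) - 0.5 * sigma2,
                                  "sigma": math.sqrt(sigma2)})


# ---------------------------------------------------------------------------
# PSA parameter plumbing


def _set_utility(sev: Severity):
    return lambda p, v: p.utilities.state_utility.__setitem__(sev, v)


def _set_disutility(key: str):
    return lambda p, v: p.utilities.disutility.__setitem__(key, v)


def _set_maintenance(sev: Severity):
    return lambda p, v: p.costs.maintenance_annual.__setitem__(sev, v)


def _set_cost(attr: str):
    return lambda p, v: setattr(p.costs, attr, v)


def _set_rr(sev: Severity):
    return lambda p, v: p.mortality.relative_risk.__setitem__(sev, v)


def _set_arm(label: str, attr: str):
    return lambda p, v: setattr(p.arms[label], attr, v)


def psa_setters(params: ModelParameters) -> dict[str, Callable[[ModelParameters, float], None]]:
    reg: dict[str, Callable[[ModelParameters, float], None]] = {}
    for sev in SEVERITIES:
        reg[f"utility_{sev.label}"] = _set_utility(sev)
        reg[f"cost_maintenance_{sev.label}"] = _set_maintenance(sev)
        reg[f"rr_mortality_{sev.label}"] = _set_rr(sev)
    for key in ("moderate_exacerbation", "severe_exacerbation", "pneumonia"):
        reg[f"disutility_{key}"] = _set_disutility(key)
    reg["cost_moderate_exacerbation"] = _set_cost("moderate_exacerbation")
    reg["cost_severe_exacerbation"] = _set_cost("severe_exacerbation")
    reg["cost_pneumonia"] = _set_cost("pneumonia")
    for label in params.arms:
        reg[f"rate_moderate_{label}"] = _set_arm(label, "moderate_exacerbation_rate")
        reg[f"rate_severe_{label}"] = _set_arm(label, "severe_exacerbation_rate")
        reg[f"prob_pneumonia_{label}"] = _set_arm(label, "pneumonia_probability")
    return reg


#: admissible range per parameter kind, for the redraw rule
def _bounds_for(name: str) -> tuple[float, float]:
    if name.startswith(("utility_", "disutility_", "prob_")):
        return 0.0, 1.0
    if name.startswith("rr_"):
        return 1.0, math.inf
    return 0.0, math.inf


@dataclass
class PSASpec:
    """Distribution assignment per parameter plus the correlated-coefficient block."""

    entries: dict[str, DistSpec]
    coef_cov: Optional[np.ndarray] = None
    n_draws: int = 10_000
    seed: int = 20_180_101

    def validate(self) -> None:
        for name, d in self.entries.items():
            if d.family not in ("beta", "gamma", "lognormal", "fixed"):
                raise ParameterError(f"psa.{name}", f"unknown family {d.family!r}")
        if self.coef_cov is not None:
            cholesky_factor(self.coef_cov)  # raises if not PSD


def default_psa_spec(
    params: ModelParameters,
    n_draws: int = 10_000,
    seed: int = 20_180_101,
    cost_cv: float = 0.2,
    rate_cv: float = 0.1,
    prob_cv: float = 0.1,
    rr_cv: float = 0.2,
    ci_sd_scale: float = 1.0,
) -> PSASpec:
    """Standard distribution assignment from point estimates and CIs.

    Utilities and event disutilities use beta distributions moment-matched to
    their 95% CIs; costs use gamma with a coefficient of variation
    ``cost_cv``; mortality relative risks log-normal; trial rates and
    probabilities gamma/beta with ``rate_cv``/``prob_cv``.
    """
    u = params.utilities
    c = params.costs
    entries: dict[str, DistSpec] = {}
    for sev in SEVERITIES:
        ci = u.state_utility_ci.get(sev, ())
        mean = u.state_utility[sev]
        entries[f"utility_{sev.label}"] = (
            beta_from_mean_ci(mean, ci, ci_sd_scale) if len(ci) == 2
            else beta_from_mean_sd(mean, prob_cv * mean)
        )
        entries[f"cost_maintenance_{sev.label}"] = gamma_from_mean_sd(
            c.maintenance_annual[sev], cost_cv * c.maintenance_annual[sev])
        rr = params.mortality.relative_risk[sev]
        entries[f"rr_mortality_{sev.label}"] = lognormal_from_mean_sd(rr, rr_cv * rr)
    for key in ("moderate_exacerbation", "severe_exacerbation", "pneumonia"):
        ci = u.disutility_ci.get(key, ())
        mean = u.disutility[key]
        entries[f"disutility_{key}"] = (
            beta_from_mean_ci(mean, ci, ci_sd_scale) if len(ci) == 2
            else beta_from_mean_sd(mean, prob_cv * mean)
        )
    entries["cost_moderate_exacerbation"] = gamma_from_mean_sd(
        c.moderate_exacerbation, cost_cv * c.moderate_exacerbation)
    entries["cost_severe_exacerbation"] = gamma_from_mean_sd(
        c.severe_exacerbation, cost_cv * c.severe_exacerbation)
    entries["cost_pneumonia"] = gamma_from_mean_sd(c.pneumonia, cost_cv * c.pneumonia)
    for label, arm in params.arms.items():
        entries[f"rate_moderate_{label}"] = gamma_from_mean_sd(
            arm.moderate_exacerbation_rate, rate_cv * arm.moderate_exacerbation_rate)
        entries[f"rate_severe_{label}"] = gamma_from_mean_sd(
            arm.severe_exacerbation_rate, rate_cv * arm.severe_exacerbation_rate)
        entries[f"prob_pneumonia_{label}"] = beta_from_mean_sd(
            arm.pneumonia_probability, prob_cv * arm.pneumonia_probability)
    return PSASpec(entries=entries, coef_cov=params.transitions.coef_cov,
                   n_draws=n_draws, seed=seed)


def _draw_rng(seed: int, draw_index: int) -> np.random.Generator:
    # per-draw substream keyed by (master seed, draw index): reproducible and
    # order-independent
    return np.random.default_rng([int(seed), int(draw_index)])


MAX_REDRAWS = 100


def sample_draw(
    base: ModelParameters, spec: PSASpec, draw_index: int
) -> ModelParameters:
    """One PSA parameter draw, reproducible given (spec.seed, draw_index).

    Univariate parameters are drawn from their assigned families with
    out-of-range redraws (max 100); the transition/exacerbation coefficient
    vector is drawn jointly as mean + L z on the logit scale when a
    covariance is configured.  Cross-parameter ordering invariants are not
    re-imposed on individual draws.
    """
    rng = _draw_rng(spec.seed, draw_index)
    p = copy.deepcopy(base)
    setters = psa_setters(base)
    for name in sorted(spec.entries):
        dist = spec.entries[name]
        if name not in setters:
            raise ParameterError(f"psa.{name}",
                                 f"unknown parameter; valid: {sorted(setters)}")
        lo, hi = _bounds_for(name)
        value = dist.sample(rng)
        attempts = 0
        while not lo <= value <= hi:
            attempts += 1
            if attempts > MAX_REDRAWS:
                raise ParameterError(f"psa.{name}",
                                     f"no in-range draw after {MAX_REDRAWS} attempts")
            value = dist.sample(rng)
        setters[name](p, value)
    if spec.coef_cov is not None:
        L = cholesky_factor(spec.coef_cov)
        z = rng.standard_normal(L.shape[0])
        coef = base.transitions.coefficient_mean() + L @ z
        p.transitions = base.transitions.from_coefficients(coef)
    return p


# ---------------------------------------------------------------------------
# PSA run and CEAC


@dataclass
class PSAResult:
    """Per-draw incremental cloud, CEACs and summary means."""

    draws: pd.DataFrame  # columns: draw, comparator, delta_cost, delta_qaly, delta_ly
    wtp_grid: np.ndarray
    ceac: dict[str, np.ndarray]
    mean_delta_cost: dict[str, float]
    mean_delta_qaly: dict[str, float]
    seed: int

    def prob_cost_effective(self, comparator: str, wtp: float) -> float:
        sub = self.draws[self.draws["comparator"] == comparator]
        nmb = wtp * sub["delta_qaly"].to_numpy() - sub["delta_cost"].to_numpy()
        return float(np.mean(nmb > 0.0))


def ceac(pairs: np.ndarray, wtp_grid: Sequence[float]) -> np.ndarray:
    """Probability cost-effective at each willingness-to-pay value.

    ``pairs`` is an (n, 2) array of (delta_cost, delta_qaly) draws; a draw
    counts as cost-effective at wtp when its net monetary benefit
    wtp * delta_qaly - delta_cost is positive.
    """
    grid = np.asarray(list(wtp_grid), dtype=float)
    if grid.size == 0:
        raise ValueError("willingness-to-pay grid must be non-empty")
    pairs = np.atleast_2d(np.asarray(pairs, dtype=float))
    if pairs.shape[0] == 0:
        raise ValueError("at least one draw required")
    d_cost = pairs[:, 0]
    d_qaly = pairs[:, 1]
    nmb = grid[:, None] * d_qaly[None, :] - d_cost[None, :]
    return (nmb > 0.0).mean(axis=1)


def run_psa(
    base: ModelParameters,
    spec: PSASpec,
    comparisons: Optional[list[str]] = None,
) -> PSAResult:
    """Monte Carlo PSA: full model per draw, incremental cloud and CEACs."""
    spec.validate()
    comparators = comparisons or base.comparators
    labels = [base.intervention, *comparators]
    records = []
    for k in range(spec.n_draws):
        p = sample_draw(base, spec, k)
        results = {lab: run_arm(p, lab) for lab in labels}
        ri = results[base.intervention]
        for comp in comparators:
            cr = compare(ri, results[comp])
            records.append({
                "draw": k,
                "comparator": comp,
                "delta_cost": cr.delta_cost,
                "delta_qaly": cr.delta_qaly,
                "delta_ly": cr.delta_ly,
            })
    draws = pd.DataFrame.from_records(records)
    grid = np.asarray(base.settings.wtp_grid, dtype=float)
    curves, mdc, mdq = {}, {}, {}
    for comp in comparators:
        sub = draws[draws["comparator"] == comp]
        pairs = sub[["delta_cost", "delta_qaly"]].to_numpy()
        curves[comp] = ceac(pairs, grid)
        mdc[comp] = float(sub["delta_cost"].mean())
        mdq[comp] = float(sub["delta_qaly"].mean())
    return PSAResult(draws=draws, wtp_grid=grid, ceac=curves,
                     mean_delta_cost=mdc, mean_delta_qaly=mdq, seed=spec.seed)
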