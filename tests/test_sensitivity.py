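"""Tornado analysis, Cholesky sampling, PSA reproducibility and CEACs."""

import numpy as np
import pytest

from copdce.economics import run_comparison
from copdce.sensitivity import (
    DistSpec,
    OWSASpec,
    beta_from_mean_ci,
    ceac,
    cholesky_factor,
    default_psa_spec,
    gamma_from_mean_sd,
    run_owsa,
    run_psa,
    sample_draw,
)
from copdce.synthetic import generate_psa_spec


# ---------------------------------------------------------------------------
# Cholesky


def test_cholesky_closed_forms():
    np.testing.assert_allclose(cholesky_factor(np.eye(3)), np.eye(3))
    L = cholesky_factor(np.array([[4.0, 2.0], [2.0, 3.0]]))
    np.testing.assert_allclose(L, [[2.0, 0.0], [1.0, np.sqrt(2.0)]], atol=1e-12)
    np.testing.assert_allclose(cholesky_factor(np.diag([9.0, 16.0])),
                               np.diag([3.0, 4.0]))


def test_cholesky_reconstructs_covariance(bundle):
    cov = bundle.transitions.coef_cov
    L = cholesky_factor(cov)
    np.testing.assert_allclose(L @ L.T, cov, atol=1e-10)
    assert np.allclose(np.triu(L, 1), 0.0)


def test_cholesky_rejects_non_psd():
    bad = np.array([[1.0, 2.0], [2.0, 1.0]])  # minor of order 2 negative
    with pytest.raises(ValueError, match="order 2"):
        cholesky_factor(bad)
    with pytest.raises(ValueError, match="symmetric"):
        cholesky_factor(np.array([[1.0, 0.5], [0.2, 1.0]]))


def test_correlated_draws_recover_covariance(bundle, rng):
    cov = bundle.transitions.coef_cov
    L = cholesky_factor(cov)
    z = rng.standard_normal((100_000, L.shape[0]))
    draws = z @ L.T
    emp = np.cov(draws, rowvar=False)
    rel = np.linalg.norm(emp - cov) / np.linalg.norm(cov)
    assert rel < 0.05


# ---------------------------------------------------------------------------
# distributions and draws


def test_beta_moment_match_and_sampling(rng):
    spec = beta_from_mean_ci(0.787, (0.771, 0.802))
    a, b = spec.params["alpha"], spec.params["beta"]
    assert a / (a + b) == pytest.approx(0.787)
    n = 50_000
    sample = rng.beta(a, b, size=n)
    se = sample.std(ddof=1) / np.sqrt(n)
    assert abs(sample.mean() - 0.787) < 3 * se


def test_gamma_moment_match():
    spec = gamma_from_mean_sd(6120.30, 0.2 * 6120.30)
    assert spec.mean() == pytest.approx(6120.30)
    assert spec.params["shape"] == pytest.approx(25.0)


def test_sample_draw_reproducible(bundle):
    spec = generate_psa_spec(bundle, n_draws=10, seed=77)
    d1 = sample_draw(bundle, spec, 3)
    d2 = sample_draw(bundle, spec, 3)
    assert d1.to_dict() == d2.to_dict()
    d3 = sample_draw(bundle, spec, 4)
    assert d3.to_dict() != d1.to_dict()


def test_degenerate_psa_equals_base_case(bundle):
    spec = generate_psa_spec(bundle, noise=0.0, n_draws=3, seed=1)
    assert all(d.family == "fixed" for d in spec.entries.values())
    result = run_psa(bundle, spec)
    _, comparisons = run_comparison(bundle)
    for comp, cr in comparisons.items():
        sub = result.draws[result.draws["comparator"] == comp]
        np.testing.assert_allclose(sub["delta_cost"], cr.delta_cost, atol=1e-9)
        np.testing.assert_allclose(sub["delta_qaly"], cr.delta_qaly, atol=1e-12)


def test_psa_mean_recovers_base_deltas_for_cost_linear_model(bundle):
    """Deltas are linear in unit costs, so PSA means equal base-case deltas."""
    base_spec = default_psa_spec(bundle, n_draws=400, seed=42)
    entries = {k: v for k, v in base_spec.entries.items() if k.startswith("cost_")}
    spec = base_spec
    spec.entries = entries
    spec.coef_cov = None
    result = run_psa(bundle, spec)
    _, comparisons = run_comparison(bundle)
    for comp, cr in comparisons.items():
        sub = result.draws[result.draws["comparator"] == comp]
        se = sub["delta_cost"].std(ddof=1) / np.sqrt(len(sub))
        assert abs(sub["delta_cost"].mean() - cr.delta_cost) < 3 * se
        # QALYs untouched by cost draws
        np.testing.assert_allclose(sub["delta_qaly"], cr.delta_qaly, atol=1e-12)


def test_out_of_range_redraw_gives_up():
    spec_entry = DistSpec("fixed", {"value": -1.0})
    from copdce.parameters import ParameterError
    from copdce.sensitivity import PSASpec
    from copdce.synthetic import base_case_bundle

    bundle = base_case_bundle()
    spec = PSASpec(entries={"cost_pneumonia": spec_entry}, n_draws=1, seed=0)
    with pytest.raises(ParameterError, match="no in-range draw"):
        sample_draw(bundle, spec, 0)


# ---------------------------------------------------------------------------
# CEAC


def test_ceac_closed_forms():
    dominant = np.array([[-10.0, 0.1], [-5.0, 0.2]])
    np.testing.assert_allclose(ceac(dominant, [0, 20_000, 50_000]), 1.0)
    # at wtp 0 the curve is the fraction of cost-saving draws
    pairs = np.array([[-10.0, 0.1], [5.0, 0.1], [3.0, -0.1], [-1.0, -0.2]])
    assert ceac(pairs, [0.0])[0] == pytest.approx(0.5)
    # single draw: NMB = 20000 * 0.275 - 1129 = 4371 > 0
    assert ceac(np.array([[1129.0, 0.275]]), [20_000.0])[0] == 1.0
    # step exactly at the base-case ICER
    icer = 1129.0 / 0.275
    curve = ceac(np.array([[1129.0, 0.275]]), [icer - 1, icer + 1])
    np.testing.assert_allclose(curve, [0.0, 1.0])
    with pytest.raises(ValueError):
        ceac(np.array([[1.0, 1.0]]), [])


def test_ceac_monotone_when_qaly_gain_positive(rng):
    pairs = np.column_stack([rng.normal(500, 400, 500), rng.uniform(0.01, 0.5, 500)])
    curve = ceac(pairs, np.arange(0, 50_001, 1000))
    assert np.all(np.diff(curve) >= 0)
    assert np.all((curve >= 0) & (curve <= 1))


# ---------------------------------------------------------------------------
# OWSA


def test_owsa_zero_influence_parameter(bundle):
    # the UMEC/VI price cannot move the FF/UMEC/VI vs FF/VI comparison
    spec = OWSASpec(parameters=["drug_cost_UMEC/VI"])
    df = run_owsa(bundle, spec, ("FF/UMEC/VI", "FF/VI"))
    row = df.iloc[0]
    assert row["low_icer"] == pytest.approx(row["base_icer"])
    assert row["high_icer"] == pytest.approx(row["base_icer"])
    assert row["span"] == pytest.approx(0.0)


def test_intervention_drug_cost_up_raises_icer(bundle):
    spec = OWSASpec(parameters=["drug_cost_FF/UMEC/VI"])
    df = run_owsa(bundle, spec, ("FF/UMEC/VI", "FF/VI"))
    row = df.iloc[0]
    assert row["high_icer"] > row["base_icer"] > row["low_icer"]


def test_tornado_sorted_and_order_invariant(bundle):
    params = ["drug_cost_FF/UMEC/VI", "utility_moderate", "maintenance_costs"]
    df1 = run_owsa(bundle, OWSASpec(parameters=params), ("FF/UMEC/VI", "FF/VI"))
    df2 = run_owsa(bundle, OWSASpec(parameters=params[::-1]), ("FF/UMEC/VI", "FF/VI"))
    assert list(df1["parameter"]) == list(df2["parameter"])
    assert list(df1["span"]) == sorted(df1["span"], reverse=True)


def test_owsa_unknown_parameter(bundle):
    from copdce.parameters import ParameterError

    with pytest.raises(ParameterError, match="unknown parameter"):
        run_owsa(bundle, OWSASpec(parameters=["not_a_parameter"]))
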