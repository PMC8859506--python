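"""Markov engine: cycle mechanics, conservation, oracles and the direct effect.

The toy oracle bundle (see ``copdce.synthetic.toy_two_severity_bundle``) uses
two reachable severities, flat background mortality q = 0.1 with relative
risk 2 (state death probability 1 - 0.9^2 = 0.19), moderate-to-severe
progression 0.2 and a 0.3 any-exacerbation probability in every state.  The
independent oracle below re-traces it with explicit per-path arithmetic.
"""

import copy
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from copdce.markov import (
    apply_posttrial_effect,
    exacerbation_stratum_update,
    run_cycle,
    run_markov,
    state_death_probability,
)
from copdce.states import validate_distribution
from copdce.synthetic import GeneratorSpec, generate_parameters, toy_two_severity_bundle


def test_state_death_probability():
    assert state_death_probability(0.02, 1.0) == pytest.approx(0.02)
    assert state_death_probability(0.0, 8.33) == 0.0
    assert state_death_probability(1.0, 0.5) == 1.0
    expected = 1.0 - math.exp(8.33 * math.log(0.98))
    assert state_death_probability(0.02, 8.33) == pytest.approx(expected)
    assert expected == pytest.approx(0.1549, abs=5e-4)


@given(st.floats(0, 1), st.floats(0, 20))
def test_state_death_probability_is_a_probability(q, rr):
    p = state_death_probability(q, rr)
    assert 0.0 <= p <= 1.0
    if rr >= 1.0:
        assert p >= q - 1e-12  # risk never below background for RR >= 1


def test_stratum_update():
    survivors = np.array([0.5, 0.3, 0.2])
    none = exacerbation_stratum_update(np.zeros(3), survivors)
    assert np.all(none[1::2] == 0) and np.allclose(none[0::2], survivors)
    all_exac = exacerbation_stratum_update(np.ones(3), survivors)
    assert np.all(all_exac[0::2] == 0) and np.allclose(all_exac[1::2], survivors)
    split = exacerbation_stratum_update(np.full(3, 0.4), survivors)
    assert np.allclose(split[1::2], 0.4 * survivors)
    assert np.allclose(split[0::2], 0.6 * survivors)


def _oracle_trace_toy(n_cycles: int):
    """Independent hand trace of the toy model with explicit scalar arithmetic.

    States tracked as dicts keyed (severity, recent); q=0.19, progression
    moderate->severe 0.2, p(any exacerbation)=0.3 for everyone.
    """
    q = 1.0 - 0.9**2
    prog = 0.2
    p_exac = 0.3
    occ = {("mod", False): 1.0, ("mod", True): 0.0,
           ("sev", False): 0.0, ("sev", True): 0.0}
    dead = 0.0
    rows = []
    for _ in range(n_cycles):
        deaths = sum(v * q for v in occ.values())
        surv = {k: v * (1.0 - q) for k, v in occ.items()}
        mod_events = sum(surv.values()) * p_exac  # uniform risk
        # destination severity totals
        mod_surv = surv[("mod", False)] + surv[("mod", True)]
        sev_surv = surv[("sev", False)] + surv[("sev", True)]
        to_mod = mod_surv * (1.0 - prog)
        to_sev = mod_surv * prog + sev_surv
        occ = {
            ("mod", False): to_mod * (1.0 - p_exac),
            ("mod", True): to_mod * p_exac,
            ("sev", False): to_sev * (1.0 - p_exac),
            ("sev", True): to_sev * p_exac,
        }
        dead += deaths
        ly = sum(surv.values()) + 0.5 * deaths
        rows.append({"occ": dict(occ), "dead": dead, "ly": ly,
                     "mod_events": mod_events})
    return rows


def test_run_cycle_matches_hand_trace(toy):
    oracle = _oracle_trace_toy(2)
    d = np.zeros(7)
    d[0] = 1.0
    for step in oracle:
        d, info = run_cycle(d, toy.transitions, toy.mortality, age=70.0)
        assert d[6] == pytest.approx(step["dead"], abs=1e-12)
        assert d[0] == pytest.approx(step["occ"][("mod", False)], abs=1e-12)
        assert d[1] == pytest.approx(step["occ"][("mod", True)], abs=1e-12)
        assert d[2] == pytest.approx(step["occ"][("sev", False)], abs=1e-12)
        assert d[3] == pytest.approx(step["occ"][("sev", True)], abs=1e-12)
        assert info["moderate_exacerbations"] == pytest.approx(
            step["mod_events"], abs=1e-12)


def test_run_markov_totals_match_hand_trace(toy):
    params = copy.deepcopy(toy)
    params.settings.horizon_years = 6
    start = np.zeros(7)
    start[0] = 1.0
    trace = run_markov(start, params, params.arms["toy"])
    oracle = _oracle_trace_toy(5)
    np.testing.assert_allclose(trace.lys, [r["ly"] for r in oracle], atol=1e-12)
    np.testing.assert_allclose(
        trace.events["moderate_exacerbation"], [r["mod_events"] for r in oracle],
        atol=1e-12)
    assert trace.occupancy[-1, 6] == pytest.approx(oracle[-1]["dead"], abs=1e-12)


def test_run_cycle_degenerate_inputs(toy):
    all_dead = np.zeros(7)
    all_dead[6] = 1.0
    nxt, info = run_cycle(all_dead, toy.transitions, toy.mortality, 70.0)
    assert nxt[6] == 1.0 and info["moderate_exacerbations"] == 0.0
    with pytest.raises(ValueError):
        run_cycle(np.full(7, 0.2), toy.transitions, toy.mortality, 70.0)


def test_conservation_and_monotone_death(bundle):
    arm = bundle.arms["FF/UMEC/VI"]
    start = np.zeros(7)
    start[:6] = arm.trial_end_distribution * (1 - arm.trial_mortality)
    start[6] = arm.trial_mortality
    trace = run_markov(start, bundle, arm)
    for row in trace.occupancy:
        assert validate_distribution(row).valid
    deaths = trace.occupancy[:, 6]
    assert np.all(np.diff(deaths) >= -1e-12)
    # no milder-severity mass creation: moderate occupancy never increases
    moderate = trace.occupancy[:, 0] + trace.occupancy[:, 1]
    assert np.all(np.diff(moderate) <= 1e-12)


def test_zero_mortality_zero_discount_lys_equal_horizon(toy):
    params = copy.deepcopy(toy)
    params.mortality.q_background[:] = 0.0
    params.mortality._q_adjusted[:] = 0.0
    params.settings.horizon_years = 10
    start = np.zeros(7)
    start[0] = 1.0
    trace = run_markov(start, params, params.arms["toy"])
    # 9 post-trial cycles, full cohort alive throughout
    assert trace.lys.sum() == pytest.approx(9.0, abs=1e-12)


def test_certain_death_gives_half_cycle_credit_only(toy):
    params = copy.deepcopy(toy)
    params.mortality.q_background[:] = 1.0
    params.mortality._q_adjusted[:] = 1.0
    start = np.zeros(7)
    start[0] = 1.0
    trace = run_markov(start, params, params.arms["toy"])
    assert trace.lys[0] == pytest.approx(0.5)
    assert np.all(trace.lys[1:] == 0.0)


def test_engine_matches_matrix_power_oracle(toy):
    # with zero exacerbation risk the strata collapse; compare against a
    # 4-state (mod, sev, vsev, death) transition-matrix power
    params = copy.deepcopy(toy)
    params.transitions.p_moderate_exac[:] = 0.0
    params.settings.horizon_years = 16
    q = 1.0 - 0.9**2
    prog = 0.2
    M = np.array([
        [(1 - q) * (1 - prog), (1 - q) * prog, 0.0, q],
        [0.0, (1 - q), 0.0, q],
        [0.0, 0.0, (1 - q), q],
        [0.0, 0.0, 0.0, 1.0],
    ])
    start = np.zeros(7)
    start[0] = 1.0
    trace = run_markov(start, params, params.arms["toy"])
    v = np.array([1.0, 0.0, 0.0, 0.0])
    for k in range(trace.occupancy.shape[0]):
        expected = v @ np.linalg.matrix_power(M, k)
        occ = trace.occupancy[k]
        collapsed = np.array([occ[0] + occ[1], occ[2] + occ[3], occ[4] + occ[5], occ[6]])
        np.testing.assert_allclose(collapsed, expected, atol=1e-10)


@pytest.mark.parametrize("factor", [0.8, 1.2])
def test_mortality_rr_monotonically_moves_lys(bundle, factor):
    p = bundle.copy()
    for sev in p.mortality.relative_risk:
        p.mortality.relative_risk[sev] = max(1.0, p.mortality.relative_risk[sev] * factor)
    arm = p.arms["FF/UMEC/VI"]
    start = np.zeros(7)
    start[:6] = arm.trial_end_distribution
    base_lys = run_markov(start, bundle, bundle.arms["FF/UMEC/VI"]).lys.sum()
    new_lys = run_markov(start, p, arm).lys.sum()
    if factor > 1:
        assert new_lys <= base_lys
    else:
        assert new_lys >= base_lys


def test_identical_parameters_identical_traces():
    bundle = generate_parameters(GeneratorSpec(effect_size=0.0))
    start = np.zeros(7)
    start[:6] = bundle.arms["FF/VI"].trial_end_distribution
    traces = [run_markov(start, bundle, arm) for arm in bundle.arms.values()]
    for t in traces[1:]:
        np.testing.assert_array_equal(t.occupancy, traces[0].occupancy)
        np.testing.assert_array_equal(t.qalys, traces[0].qalys)
        for cat in traces[0].costs:
            np.testing.assert_array_equal(t.costs[cat], traces[0].costs[cat])


def test_apply_posttrial_effect():
    bundle = toy_two_severity_bundle()
    t = bundle.transitions
    # base case: no direct effect
    assert apply_posttrial_effect(t, 0.0, 0, 5) is t
    # full effect within duration
    scaled = apply_posttrial_effect(t, 0.4, 2, 5, waning=False)
    np.testing.assert_allclose(scaled.p_moderate_exac, 0.6 * t.p_moderate_exac)
    # linear waning: half the reduction at half the duration
    half = apply_posttrial_effect(t, 0.4, 2, 4, waning=True)
    np.testing.assert_allclose(half.p_moderate_exac, 0.8 * t.p_moderate_exac)
    # elapsed: unchanged
    assert apply_posttrial_effect(t, 0.4, 5, 5) is t
    assert apply_posttrial_effect(t, 0.4, 7, 5, waning=True) is t
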