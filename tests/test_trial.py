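"""Year-1 decision tree: drug costing, discontinuation, utility AUC, accruals."""

import copy

import numpy as np
import pytest

from copdce.states import validate_distribution
from copdce.synthetic import GeneratorSpec, generate_parameters
from copdce.trial import (
    annual_drug_cost,
    discontinuation_cost,
    pneumonia_event_cost,
    replacement_cost_30d,
    run_trial_phase,
    trial_utility_auc,
)

CLASS_COSTS = {"lama": 29.29, "ics_laba": 31.79, "lama_laba": 32.50,
               "ics_lama_laba": 61.08}


@pytest.mark.parametrize(
    "cost_30d, fraction, expected",
    [
        (44.50, 1.0, 44.50 * 365.25 / 30),  # 541.79
        (0.0, 1.0, 0.0),
        (22.00, 0.5, 22.00 * 365.25 / 30 * 0.5),  # 133.93
    ],
)
def test_annual_drug_cost(cost_30d, fraction, expected):
    assert annual_drug_cost(cost_30d, fraction) == pytest.approx(expected)
    assert annual_drug_cost(44.50) == pytest.approx(541.79, abs=0.005)


def test_annual_drug_cost_rejects_negative():
    with pytest.raises(ValueError):
        annual_drug_cost(-1.0)


def test_discontinuation_cost_cases():
    # no discontinuation: full-year assigned treatment, no replacement
    assert discontinuation_cost(44.50, 48.01, 0.0) == pytest.approx(
        annual_drug_cost(44.50))
    # certain discontinuation: 26 weeks each of assigned and replacement therapy
    switched = 26 * 7 / 30 * (44.50 + 48.01)
    assert discontinuation_cost(44.50, 48.01, 1.0) == pytest.approx(switched)
    assert switched == pytest.approx(561.23, abs=0.005)
    # linear in p_disc
    mid = discontinuation_cost(44.50, 48.01, 0.5)
    assert mid == pytest.approx(0.5 * (annual_drug_cost(44.50) + switched))


def test_replacement_cost_weighting():
    only_lama_laba = {"lama": 0, "ics_laba": 0, "lama_laba": 1.0, "ics_lama_laba": 0}
    assert replacement_cost_30d(CLASS_COSTS, only_lama_laba) == pytest.approx(32.50)
    uniform = {k: 0.25 for k in CLASS_COSTS}
    assert replacement_cost_30d(CLASS_COSTS, uniform) == pytest.approx(38.665)
    with pytest.raises(ValueError):
        replacement_cost_30d(CLASS_COSTS, {k: 0.2 for k in CLASS_COSTS})


def test_arm_replacement_costs_match_printed_weighted_values(bundle):
    expected = {"FF/UMEC/VI": 48.01, "UMEC/VI": 48.54, "FF/VI": 49.34}
    for label, value in expected.items():
        mix = bundle.arms[label].replacement_mix
        got = replacement_cost_30d(bundle.costs.replacement_class_costs_30d, mix)
        assert round(got, 2) == value


@pytest.mark.parametrize(
    "amb, inp, p, expected",
    [(100.0, 200.0, 0.5, 150.0), (100.0, 200.0, 0.0, 100.0),
     (140.00, 1863.60, 0.55, 1087.98)],
)
def test_pneumonia_event_cost(amb, inp, p, expected):
    assert pneumonia_event_cost(amb, inp, p) == pytest.approx(expected)


def test_trial_utility_auc():
    assert trial_utility_auc(0.787, []) == pytest.approx(0.787)
    assert trial_utility_auc(0.787, [(26.0, 0.0), (52.0, 0.0)]) == pytest.approx(0.787)
    # flat at 0.7 to week 26, linear rise to 0.8 by week 52:
    # area = 0.7*26 + 0.75*26 = 37.7 over 52 weeks
    assert trial_utility_auc(0.7, [(26.0, 0.0), (52.0, 0.1)]) == pytest.approx(0.725)
    with pytest.raises(ValueError):
        trial_utility_auc(0.7, [(30.0, 0.0), (10.0, 0.0)])
    with pytest.raises(ValueError):
        trial_utility_auc(0.7, [(60.0, 0.0)])


def _quiet_arm(bundle, **overrides):
    arm = copy.deepcopy(bundle.arms["FF/UMEC/VI"])
    arm.moderate_exacerbation_rate = 0.0
    arm.severe_exacerbation_rate = 0.0
    arm.pneumonia_probability = 0.0
    arm.trial_mortality = 0.0
    arm.discontinuation = 0.0
    arm.trial_utility_deltas = []
    for k, v in overrides.items():
        setattr(arm, k, v)
    return arm


def test_trial_phase_zero_event_case(bundle):
    arm = _quiet_arm(bundle)
    res = run_trial_phase(arm, bundle.costs, bundle.utilities, bundle.settings)
    assert res.qalys == pytest.approx(bundle.utilities.trial_baseline)
    assert res.lys == 1.0
    assert res.surviving_fraction == 1.0
    nonzero = {k for k, v in res.costs.items() if v > 0}
    assert nonzero == {"treatment", "maintenance"}
    assert res.costs["treatment"] == pytest.approx(annual_drug_cost(arm.drug_cost_30d))


def test_trial_phase_single_moderate_exacerbation_closed_form(bundle):
    arm = _quiet_arm(bundle, moderate_exacerbation_rate=1.0)
    base = run_trial_phase(_quiet_arm(bundle), bundle.costs, bundle.utilities,
                           bundle.settings)
    res = run_trial_phase(arm, bundle.costs, bundle.utilities, bundle.settings)
    assert res.costs["moderate_exacerbation"] == pytest.approx(568.48)
    assert base.qalys - res.qalys == pytest.approx(0.011)


def test_within_trial_mortality_scenario_flag(bundle):
    settings = copy.deepcopy(bundle.settings)
    settings.include_trial_mortality = False
    arm = bundle.arms["FF/UMEC/VI"]
    res = run_trial_phase(arm, bundle.costs, bundle.utilities, settings)
    assert res.surviving_fraction == 1.0
    res_incl = run_trial_phase(arm, bundle.costs, bundle.utilities, bundle.settings)
    assert res_incl.surviving_fraction == pytest.approx(1.0 - arm.trial_mortality)
    # decedents contribute half a year of person-time
    assert res_incl.lys == pytest.approx(1.0 - 0.5 * arm.trial_mortality)


def test_identical_arms_give_identical_results():
    bundle = generate_parameters(GeneratorSpec(effect_size=0.0))
    results = [
        run_trial_phase(arm, bundle.costs, bundle.utilities, bundle.settings)
        for arm in bundle.arms.values()
    ]
    ref = results[0]
    for res in results[1:]:
        assert res.qalys == pytest.approx(ref.qalys, abs=1e-12)
        assert res.lys == pytest.approx(ref.lys, abs=1e-12)
        for cat in ref.costs:
            assert res.costs[cat] == pytest.approx(ref.costs[cat], abs=1e-12)


def test_costs_linear_in_unit_costs_and_disutilities(fresh_bundle):
    bundle = fresh_bundle
    arm = bundle.arms["FF/VI"]
    base = run_trial_phase(arm, bundle.costs, bundle.utilities, bundle.settings)
    # cost linear in the moderate-exacerbation unit cost
    bundle.costs.moderate_exacerbation += 100.0
    up = run_trial_phase(arm, bundle.costs, bundle.utilities, bundle.settings)
    expected_events = base.events["moderate_exacerbation"]
    assert up.costs["moderate_exacerbation"] - base.costs["moderate_exacerbation"] == \
        pytest.approx(100.0 * expected_events)
    # QALYs linear in the pneumonia disutility
    bundle.utilities.disutility["pneumonia"] += 0.005
    down = run_trial_phase(arm, bundle.costs, bundle.utilities, bundle.settings)
    assert up.qalys - down.qalys == pytest.approx(0.005 * base.events["pneumonia"])


def test_trial_end_distribution_is_valid_over_survivors(bundle):
    for arm in bundle.arms.values():
        res = run_trial_phase(arm, bundle.costs, bundle.utilities, bundle.settings)
        assert validate_distribution(res.end_distribution, tol=1e-6).valid
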