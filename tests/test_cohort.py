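"""Decision-tree engine: expectations, linearity, Monte-Carlo oracle."""

import math
from dataclasses import replace

import pytest

from flucea import (
    ARM_AQIV,
    ARM_HD,
    attributable_admissions,
    expected_arm_outcomes,
    simulate_arm_outcomes,
)
from flucea.cohort import expected_event_counts
from flucea.efficacy import arm_risk_profile, indirect_rve


def _with(params, **epi_updates):
    return replace(params, epi=replace(params.epi, **epi_updates))


def test_simple_tree_arithmetic(params):
    p = _with(params, cohort_size=1_000_000.0, attack_rate=0.05, p_gp_given_case=0.4)
    p = replace(p, efficacy=replace(p.efficacy, rve_hd_vs_sd_cases=0.0))
    ev = expected_event_counts(p, ARM_HD)
    assert ev.cases == pytest.approx(50_000.0)
    assert ev.gp_visits == pytest.approx(20_000.0)


def test_zero_attack_rate_empties_the_tree(params):
    p = _with(params, attack_rate=0.0, excess_mortality_per_100k=0.0)
    out = expected_arm_outcomes(p, ARM_HD)
    pop = out.population
    assert (pop.cases, pop.gp_visits, pop.er_visits, pop.hospitalizations,
            pop.deaths) == (0, 0, 0, 0, 0)
    assert out.per_person.total_cost == pytest.approx(
        p.costs.price_hd + p.costs.admin_cost)


def test_identical_efficacy_differs_only_in_vaccine_cost(params):
    eff = replace(params.efficacy, rve_hd_vs_sd_cases=0.1, rve_hd_vs_sd_hosp=0.1,
                  rve_aqiv_vs_sd_cases=0.1, rve_aqiv_vs_sd_hosp=0.1)
    p = replace(params, efficacy=eff)
    hd = expected_arm_outcomes(p, ARM_HD)
    aq = expected_arm_outcomes(p, ARM_AQIV)
    assert hd.population.cases == aq.population.cases
    assert hd.population.deaths == aq.population.deaths
    assert hd.per_person.qalys == aq.per_person.qalys
    assert hd.per_person.total_cost - aq.per_person.total_cost == pytest.approx(
        p.costs.price_hd - p.costs.price_aqiv)


def test_population_outputs_scale_linearly_with_cohort(params):
    small = expected_arm_outcomes(_with(params, cohort_size=1e5), ARM_HD)
    big = expected_arm_outcomes(_with(params, cohort_size=3e5), ARM_HD)
    for field in ("cases", "gp_visits", "er_visits", "hospitalizations",
                  "deaths", "total_cost", "lys", "qalys"):
        assert getattr(big.population, field) == pytest.approx(
            3 * getattr(small.population, field), rel=1e-12)


@pytest.mark.parametrize("arm", [ARM_HD, ARM_AQIV])
def test_count_and_per_person_invariants(params, cardio_params, arm):
    for p in (params, cardio_params):
        out = expected_arm_outcomes(p, arm)
        pop = out.population
        assert pop.gp_visits <= pop.cases
        assert pop.er_visits <= pop.cases
        if p.scenario.hospitalization_approach == "influenza_coded":
            assert pop.hospitalizations <= pop.cases
        assert out.per_person.total_cost * out.cohort_size == pytest.approx(
            pop.total_cost, rel=1e-9)
        assert out.per_person.qalys * out.cohort_size == pytest.approx(
            pop.qalys, rel=1e-9)


def test_invalid_arm_label_rejected(params):
    with pytest.raises(ValueError, match="unknown arm"):
        expected_arm_outcomes(params, "SD-QIV")


def test_hidden_burden_approach_orders_hospitalizations_by_efficacy(cardio_params):
    """With positive indirect rVE on hospitalization, HD admits fewer."""
    hd = expected_event_counts(cardio_params, ARM_HD)
    aq = expected_event_counts(cardio_params, ARM_AQIV)
    assert indirect_rve(cardio_params.efficacy.rve_hd_vs_sd_hosp,
                        cardio_params.efficacy.rve_aqiv_vs_sd_hosp) > 0
    assert hd.hospitalizations < aq.hospitalizations


def test_death_scale_tracks_cases_avoided(params):
    """Deaths fall by the same proportion as cases for full attenuation."""
    hd = expected_event_counts(params, ARM_HD)
    aq = expected_event_counts(params, ARM_AQIV)
    assert hd.deaths / aq.deaths == pytest.approx(hd.cases / aq.cases, rel=1e-12)


def test_simulation_is_deterministic_per_seed(params):
    a = simulate_arm_outcomes(params, ARM_HD, 5_000, seed=7)
    b = simulate_arm_outcomes(params, ARM_HD, 5_000, seed=7)
    assert a == b
    c = simulate_arm_outcomes(params, ARM_HD, 5_000, seed=8)
    assert c != a


def test_simulation_with_zero_attack_rate_has_no_flu_events(params):
    p = _with(params, attack_rate=0.0, excess_mortality_per_100k=0.0)
    out = simulate_arm_outcomes(p, ARM_HD, 2_000, seed=3)
    assert out.population.cases == 0
    assert out.population.deaths == 0


@pytest.mark.parametrize("approach_fixture", ["params", "cardio_params"])
def test_monte_carlo_oracle_matches_expectation_engine(request, approach_fixture):
    """Empirical event counts from 200k Bernoulli walks stay within 3
    binomial standard errors of the expectation engine's counts."""
    p = request.getfixturevalue(approach_fixture)
    n = 200_000
    sim = simulate_arm_outcomes(p, ARM_HD, n, seed=42)
    exp = expected_arm_outcomes(p, ARM_HD)
    cohort = p.epi.cohort_size
    for field in ("cases", "gp_visits", "er_visits", "hospitalizations", "deaths"):
        rate = getattr(exp.population, field) / cohort
        se = math.sqrt(max(rate * (1 - rate), 1e-30) / n)
        observed = getattr(sim.population, field) / cohort
        assert abs(observed - rate) <= 3 * se, field
    # health totals share the same death-age convention, so they agree too
    assert sim.per_person.qalys == pytest.approx(exp.per_person.qalys, rel=1e-3)


@pytest.mark.parametrize(
    "coded, extra, total",
    [(4_407.0, 15_206.0, 19_613.0), (123.0, 0.0, 123.0), (0.0, 0.0, 0.0)],
)
def test_attributable_admissions_sum(coded, extra, total):
    assert attributable_admissions(coded, extra) == total


def test_attributable_admissions_rejects_negative():
    with pytest.raises(ValueError):
        attributable_admissions(-1.0, 5.0)


def test_risk_profile_uses_scenario_efficacy(params):
    prof_hd = arm_risk_profile(params, ARM_HD)
    prof_aq = arm_risk_profile(params, ARM_AQIV)
    assert prof_hd.risk_cases == pytest.approx(params.epi.attack_rate * (1 - 0.242))
    assert prof_aq.risk_cases == pytest.approx(params.epi.attack_rate)
    assert prof_hd.risk_death_scale == pytest.approx(1 - 0.242)
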