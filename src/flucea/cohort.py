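"""Decision-tree cohort engine for one vaccination strategy.

The tree is evaluated in expectation over a hypothetical vaccinated cohort
for a single season: influenza case → (GP visit, ER visit — independent
and not mutually exclusive) → hospitalization, with deaths driven by
influenza excess mortality scaled by the cases avoided.  Two
hospitalization definitions are supported: admissions coded as influenza
(conditional on a case) and cardiorespiratory admissions possibly related
to influenza (a cohort-level rate — the "hidden burden").

A per-individual Monte-Carlo simulator through the same tree serves as an
independent oracle for the expectation engine.
"""

from __future__ import annotations

import numpy as np

from . import valuation
from .economics import arm_costs, incremental, IncrementalResult
from .efficacy import ARM_AQIV, ARM_HD, ARMS, arm_risk_profile
from .outcomes import ArmOutcomes, EventCounts, PerPersonOutcomes, PopulationOutcomes
from .parameters import ParameterSet


def _price(params: ParameterSet, arm: str) -> float:
    if arm == ARM_HD:
        return params.costs.price_hd
    if arm == ARM_AQIV:
        return params.costs.price_aqiv
    raise ValueError(f"unknown arm {arm!r}; expected one of {ARMS}")


def expected_event_counts(params: ParameterSet, arm: str) -> EventCounts:
    """Expected population event counts for one strategy."""
    _price(params, arm)  # validates the arm label
    profile = arm_risk_profile(params, arm)
    epi = params.epi
    cohort = epi.cohort_size
    cases = cohort * profile.risk_cases
    if params.scenario.hospitalization_approach == "influenza_coded":
        hosp = cases * epi.p_hosp_influenza_given_case
    else:
        hosp = cohort * profile.risk_hosp
    deaths = cohort * (epi.excess_mortality_per_100k / 100_000.0) * profile.risk_death_scale
    return EventCounts(
        cohort_size=cohort,
        cases=cases,
        gp_visits=cases * epi.p_gp_given_case,
        er_visits=cases * epi.p_er_given_case,
        hospitalizations=hosp,
        deaths=deaths,
    )


def _assemble(params: ParameterSet, arm: str, events: EventCounts) -> ArmOutcomes:
    costs = arm_costs(events, params.costs, price_per_dose=_price(params, arm))
    lys, qalys = valuation.arm_health_totals(events, params)
    cohort = events.cohort_size
    pop = PopulationOutcomes(
        cases=events.cases, gp_visits=events.gp_visits, er_visits=events.er_visits,
        hospitalizations=events.hospitalizations, deaths=events.deaths,
        total_cost=costs.total, lys=lys, qalys=qalys,
    )
    pp = PerPersonOutcomes(total_cost=costs.total / cohort, lys=lys / cohort,
                           qalys=qalys / cohort)
    return ArmOutcomes(arm_label=arm, cohort_size=cohort, population=pop, per_person=pp)


def expected_arm_outcomes(params: ParameterSet, arm: str) -> ArmOutcomes:
    """Expected events, costs and discounted health totals for one strategy."""
    return _assemble(params, arm, expected_event_counts(params, arm))


def run_incremental(params: ParameterSet) -> IncrementalResult:
    """Incremental analysis of HD-QIV vs aQIV under one parameter set."""
    ref = expected_arm_outcomes(params, ARM_AQIV)
    alt = expected_arm_outcomes(params, ARM_HD)
    return incremental(ref, alt, params.scenario.wtp_per_qaly)


def simulate_arm_outcomes(params: ParameterSet, arm: str, n_individuals: int,
                          seed: int) -> ArmOutcomes:
    """Monte-Carlo oracle: per-individual Bernoulli draws through the tree.

    Returns empirical means scaled to the population cohort size.  Deaths
    forfeit the discounted expectancy at the cohort mean age, matching the
    expectation engine's convention, so health totals are comparable.
    """
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    rng = np.random.default_rng(seed)
    profile = arm_risk_profile(params, arm)
    epi = params.epi
    n = int(n_individuals)

    ages_grid = np.array(sorted(params.age_distribution), dtype=int)
    weights = np.array([params.age_distribution[a] for a in ages_grid])
    ages = rng.choice(ages_grid, size=n, p=weights / weights.sum())

    is_case = rng.random(n) < profile.risk_cases
    gp = is_case & (rng.random(n) < epi.p_gp_given_case)
    er = is_case & (rng.random(n) < epi.p_er_given_case)
    if params.scenario.hospitalization_approach == "influenza_coded":
        hosp = is_case & (rng.random(n) < epi.p_hosp_influenza_given_case)
    else:
        hosp = rng.random(n) < profile.risk_hosp
    p_death = (epi.excess_mortality_per_100k / 100_000.0) * profile.risk_death_scale
    died = rng.random(n) < p_death

    cohort = epi.cohort_size
    scale = cohort / n
    events = EventCounts(
        cohort_size=cohort,
        cases=float(is_case.sum()) * scale,
        gp_visits=float(gp.sum()) * scale,
        er_visits=float(er.sum()) * scale,
        hospitalizations=float(hosp.sum()) * scale,
        deaths=float(died.sum()) * scale,
    )

    lt, util = params.life_table, params.utilities
    qale_by_age = {int(a): valuation.discounted_qale(int(a), lt, util) for a in ages_grid}
    base_ly = np.array([qale_by_age[int(a)].life_years for a in ages])
    base_q = np.array([qale_by_age[int(a)].qalys for a in ages])
    u_base = valuation.cohort_mean_baseline_utility(params)
    case_loss = valuation.episode_qaly_loss(
        util.influenza_duration_days, u_base, util.utility_influenza_episode)
    hosp_loss = valuation.episode_qaly_loss(
        util.hospitalization_duration_days, u_base, util.utility_hospitalized)
    death_exp = valuation.discounted_qale(valuation.cohort_mean_age(params), lt, util)

    lys = scale * (base_ly.sum() - died.sum() * death_exp.life_years)
    qalys = scale * (base_q.sum() - is_case.sum() * case_loss
                     - hosp.sum() * hosp_loss - died.sum() * death_exp.qalys)

    costs = arm_costs(events, params.costs, price_per_dose=_price(params, arm))
    pop = PopulationOutcomes(
        cases=events.cases, gp_visits=events.gp_visits, er_visits=events.er_visits,
        hospitalizations=events.hospitalizations, deaths=events.deaths,
        total_cost=costs.total, lys=lys, qalys=qalys,
    )
    pp = PerPersonOutcomes(total_cost=costs.total / cohort, lys=lys / cohort,
                           qalys=qalys / cohort)
    return ArmOutcomes(arm_label=arm, cohort_size=cohort, population=pop, per_person=pp)


def attributable_admissions(coded: float, attributable_extra: float) -> float:
    """Total influenza-attributable admissions per year.

    Sum of admissions coded as influenza at discharge and the additional
    cardiorespiratory admissions statistically attributable to influenza;
    used to document and derive the hidden-burden hospitalization rate.
    """
    if coded < 0 or attributable_extra < 0:
        raise ValueError("admission counts must be >= 0")
    return coded + attributable_extra
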