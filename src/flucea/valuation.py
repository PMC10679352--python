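"""Health-outcome valuation: discounted life expectancy and QALYs.

Acute influenza events fall within the one-year horizon and are not
discounted; the life-years and quality-adjusted life-years forfeited by a
premature death are taken over a lifetime horizon and discounted annually
(default 3%).  Annual cycles with end-of-cycle discounting and no
half-cycle correction.
"""

from __future__ import annotations

from dataclasses import dataclass

from .outcomes import EventCounts
from .parameters import LifeTable, ParameterSet, UtilityInputs

DAYS_PER_YEAR = 365.0


@dataclass(frozen=True)
class DiscountedExpectancy:
    """Discounted remaining life-years and QALYs from a given age."""

    age: int
    life_years: float
    qalys: float


def _baseline_utility(utilities: UtilityInputs, age: int) -> float:
    """Population norm utility at an age; the terminal band extends upward."""
    table = utilities.baseline_utility_by_age
    if age in table:
        return table[age]
    known = sorted(table)
    if age > known[-1]:
        return table[known[-1]]
    raise KeyError(f"no baseline utility at age {age}")


def discounted_qale(age: int, lt: LifeTable, utilities: UtilityInputs) -> DiscountedExpectancy:
    """Discounted remaining life expectancy and QALE from ``age``.

    life_years = Σ_{t=1..T} S(age, t) (1 + r)^(−t) with S the cumulative
    product of annual survival probabilities from the life table; qalys
    weight each year by the baseline utility at the attained age.
    """
    if age not in lt.ages:
        raise ValueError(f"age {age} outside the life-table grid "
                         f"[{lt.ages[0]}, {lt.max_age}]")
    r = lt.discount_rate
    survival = 1.0
    lys = 0.0
    qalys = 0.0
    for t in range(1, lt.max_age - age + 1):
        survival *= lt.survival_at(age + t - 1)
        if survival == 0.0:
            break
        disc = survival / (1.0 + r) ** t
        lys += disc
        qalys += disc * _baseline_utility(utilities, age + t)
    return DiscountedExpectancy(age=age, life_years=lys, qalys=qalys)


def episode_qaly_loss(duration_days: float, u_base: float, u_event: float) -> float:
    """QALY decrement of an acute episode: (u_base − u_event) × days / 365."""
    if not 0.0 <= u_event <= u_base <= 1.0:
        raise ValueError(f"need 0 <= u_event <= u_base <= 1, got {u_event}, {u_base}")
    if duration_days <= 0:
        raise ValueError(f"duration_days must be > 0, got {duration_days}")
    return (u_base - u_event) * duration_days / DAYS_PER_YEAR


def cohort_mean_age(params: ParameterSet) -> int:
    """Expected cohort age, rounded onto the life-table grid.

    Deaths are assigned this single age: excess mortality carries no age
    split, so the forfeited expectancy is valued at the cohort mean.
    """
    mean = sum(a * w for a, w in params.age_distribution.items())
    return min(params.life_table.max_age, max(params.life_table.ages[0], round(mean)))


def cohort_mean_baseline_utility(params: ParameterSet) -> float:
    """Age-distribution-weighted population norm utility."""
    return sum(w * _baseline_utility(params.utilities, a)
               for a, w in params.age_distribution.items())


def arm_health_totals(events: EventCounts, params: ParameterSet) -> tuple[float, float]:
    """Population discounted (LYs, QALYs) for one strategy-season.

    QALYs: cohort baseline QALE (age-distribution-weighted), minus acute
    decrements for influenza episodes and hospitalizations, minus the full
    discounted QALE at the death age for each death.  LYs analogously,
    without utility weighting and unaffected by non-fatal events.
    """
    lt, util = params.life_table, params.utilities
    base_ly = 0.0
    base_qaly = 0.0
    for age, w in params.age_distribution.items():
        de = discounted_qale(age, lt, util)
        base_ly += w * de.life_years
        base_qaly += w * de.qalys
    cohort = events.cohort_size
    u_base = cohort_mean_baseline_utility(params)

    case_loss = events.cases * episode_qaly_loss(
        util.influenza_duration_days, u_base, util.utility_influenza_episode)
    hosp_loss = events.hospitalizations * episode_qaly_loss(
        util.hospitalization_duration_days, u_base, util.utility_hospitalized)
    death_exp = discounted_qale(cohort_mean_age(params), lt, util)

    lys = cohort * base_ly - events.deaths * death_exp.life_years
    qalys = (cohort * base_qaly - case_loss - hosp_loss
             - events.deaths * death_exp.qalys)
    return lys, qalys
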