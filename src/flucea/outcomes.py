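"""Shared result containers for one vaccination strategy."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class EventCounts:
    """Expected population event counts for one strategy-season."""

    cohort_size: float
    cases: float
    gp_visits: float
    er_visits: float
    hospitalizations: float
    deaths: float


@dataclass(frozen=True)
class PopulationOutcomes:
    cases: float
    gp_visits: float
    er_visits: float
    hospitalizations: float
    deaths: float
    total_cost: float
    lys: float
    qalys: float


@dataclass(frozen=True)
class PerPersonOutcomes:
    total_cost: float
    lys: float
    qalys: float


@dataclass(frozen=True)
class ArmOutcomes:
    """Expected events, costs, LYs and QALYs for one strategy.

    ``population`` holds cohort totals; ``per_person`` the same costs and
    health totals divided by the cohort size.
    """

    arm_label: str
    cohort_size: float
    population: PopulationOutcomes
    per_person: PerPersonOutcomes

    def to_record(self) -> dict[str, float | str]:
        """Flat CSV-compatible record with documented column names."""
        p, pp = self.population, self.per_person
        return {
            "arm": self.arm_label,
            "cohort_size": self.cohort_size,
            "cases": p.cases,
            "gp_visits": p.gp_visits,
            "er_visits": p.er_visits,
            "hospitalizations": p.hospitalizations,
            "deaths": p.deaths,
            "total_cost": p.total_cost,
            "lys": p.lys,
            "qalys": p.qalys,
            "per_person_total_cost": pp.total_cost,
            "per_person_lys": pp.lys,
            "per_person_qalys": pp.qalys,
        }


def arm_outcomes_from_totals(
    arm_label: str,
    *,
    per_person_cost: float,
    per_person_lys: float,
    per_person_qalys: float,
    cohort_size: float = 1.0,
    cases: float = 0.0,
    gp_visits: float = 0.0,
    er_visits: float = 0.0,
    hospitalizations: float = 0.0,
    deaths: float = 0.0,
    population_lys: float | None = None,
    population_qalys: float | None = None,
) -> ArmOutcomes:
    """Wrap externally supplied strategy totals as an :class:`ArmOutcomes`.

    Used to feed published per-strategy columns through the incremental
    analysis; population health totals default to per-person × cohort.
    """
    pop = PopulationOutcomes(
        cases=cases, gp_visits=gp_visits, er_visits=er_visits,
        hospitalizations=hospitalizations, deaths=deaths,
        total_cost=per_person_cost * cohort_size,
        lys=population_lys if population_lys is not None else per_person_lys * cohort_size,
        qalys=population_qalys if population_qalys is not None else per_person_qalys * cohort_size,
    )
    pp = PerPersonOutcomes(total_cost=per_person_cost, lys=per_person_lys,
                           qalys=per_person_qalys)
    return ArmOutcomes(arm_label=arm_label, cohort_size=cohort_size,
                       population=pop, per_person=pp)
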