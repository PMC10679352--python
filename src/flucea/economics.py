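"""Cost accumulation and incremental cost-effectiveness analysis.

The incremental comparison is reported per person (alternative minus
reference), with the ICER qualified by the cost-effectiveness-plane
quadrant — a bare negative ICER is ambiguous between "dominant" (cheaper,
more effective) and "dominated" (dearer, less effective) — and with the
net monetary benefit NMB = WTP × ΔQALY − ΔCost at the stated
willingness-to-pay threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

from .outcomes import ArmOutcomes, EventCounts
from .parameters import CostInputs

QUADRANTS = ("NE", "SE", "NW", "SW", "axis")


@dataclass(frozen=True)
class CostBreakdown:
    """Population costs by component (euros)."""

    vaccine: float
    gp: float
    er: float
    otc: float
    hospitalization: float

    @property
    def total(self) -> float:
        return self.vaccine + self.gp + self.er + self.otc + self.hospitalization


@dataclass(frozen=True)
class IncrementalResult:
    """Per-person incremental comparison of two strategies."""

    reference_label: str
    alternative_label: str
    delta_cost: float
    delta_ly: float
    delta_qaly: float
    icer_per_ly: float | None
    icer_per_qaly: float | None
    quadrant: str
    dominance: str | None  # "dominant" | "dominated" | None
    wtp: float
    nmb_at_wtp: float
    population_deltas: dict[str, float]


def arm_costs(events: EventCounts, costs: CostInputs, *,
              price_per_dose: float) -> CostBreakdown:
    """Population cost breakdown from expected event counts.

    Over-the-counter medication is costed for every influenza case, not
    only inpatients.
    """
    return CostBreakdown(
        vaccine=events.cohort_size * (price_per_dose + costs.admin_cost),
        gp=events.gp_visits * costs.cost_gp_visit,
        er=events.er_visits * costs.cost_er_visit,
        otc=events.cases * costs.cost_otc_per_case,
        hospitalization=events.hospitalizations * costs.cost_hospitalization,
    )


def _quadrant(delta_cost: float, delta_qaly: float) -> str:
    if delta_qaly == 0.0 or delta_cost == 0.0:
        return "axis"
    if delta_qaly > 0.0:
        return "NE" if delta_cost > 0.0 else "SE"
    return "NW" if delta_cost > 0.0 else "SW"


def incremental(ref: ArmOutcomes, alt: ArmOutcomes, wtp: float) -> IncrementalResult:
    """Incremental analysis of ``alt`` vs ``ref`` (per person, alt − ref).

    ICERs are undefined (``None``) when the effect delta is zero; the SE
    quadrant is flagged dominant and NW dominated.
    """
    dc = alt.per_person.total_cost - ref.per_person.total_cost
    dly = alt.per_person.lys - ref.per_person.lys
    dq = alt.per_person.qalys - ref.per_person.qalys
    quad = _quadrant(dc, dq)
    dominance = {"SE": "dominant", "NW": "dominated"}.get(quad)
    icer_ly = dc / dly if dly != 0.0 else None
    icer_q = dc / dq if dq != 0.0 else None
    pop_deltas = {
        "cases": alt.population.cases - ref.population.cases,
        "gp_visits": alt.population.gp_visits - ref.population.gp_visits,
        "er_visits": alt.population.er_visits - ref.population.er_visits,
        "hospitalizations": alt.population.hospitalizations - ref.population.hospitalizations,
        "deaths": alt.population.deaths - ref.population.deaths,
        "total_cost": alt.population.total_cost - ref.population.total_cost,
        "lys": alt.population.lys - ref.population.lys,
        "qalys": alt.population.qalys - ref.population.qalys,
    }
    return IncrementalResult(
        reference_label=ref.arm_label,
        alternative_label=alt.arm_label,
        delta_cost=dc,
        delta_ly=dly,
        delta_qaly=dq,
        icer_per_ly=icer_ly,
        icer_per_qaly=icer_q,
        quadrant=quad,
        dominance=dominance,
        wtp=wtp,
        nmb_at_wtp=wtp * dq - dc,
        population_deltas=pop_deltas,
    )


def nmb(delta_cost: float, delta_qaly: float, wtp: float) -> float:
    """Net monetary benefit at a willingness-to-pay threshold."""
    return wtp * delta_qaly - delta_cost
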