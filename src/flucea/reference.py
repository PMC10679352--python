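"""Published reference results for the Italian HD-QIV vs aQIV evaluation.

Per-strategy totals as printed in the published Italian cost-effectiveness
evaluation this package models.  They serve as *inputs* to worked examples
— fed through the incremental analysis to check its arithmetic — and as
documentation anchors; they are not produced by this package's engine
(the original full input table is not public).
"""

from __future__ import annotations

from .efficacy import ARM_AQIV, ARM_HD
from .outcomes import ArmOutcomes, arm_outcomes_from_totals

#: Per-person strategy totals under the influenza-coded hospitalization
#: approach, by aQIV rVE scenario (0%, 6%, 12%): (total cost €, LYs, QALYs).
CODED_PER_PERSON = {
    "s1_0pct": {ARM_AQIV: (15.44, 10.2447, 8.8905), ARM_HD: (24.11, 10.2460, 8.8917)},
    "s2_6pct": {ARM_AQIV: (15.35, 10.2450, 8.8908), ARM_HD: (24.11, 10.2460, 8.8917)},
    "s3_12pct": {ARM_AQIV: (15.27, 10.2453, 8.8911), ARM_HD: (24.11, 10.2460, 8.8917)},
}

#: Published headline ICERs (€/QALY) for the three scenarios above.
CODED_ICER_PER_QALY = {"s1_0pct": 7_301.0, "s2_6pct": 9_805.0, "s3_12pct": 14_733.0}

#: Net population clinical outcomes under the cardiorespiratory
#: (hidden-burden) approach, base-case scenario.
CARDIORESP_POPULATION = {
    ARM_AQIV: dict(cases=736_036.0, gp_visits=284_110.0, er_visits=6_022.0,
                   hospitalizations=474_864.0, deaths=6_129.0,
                   qalys=121_296_794.0, lys=139_782_102.0),
    ARM_HD: dict(cases=666_048.0, gp_visits=257_095.0, er_visits=5_420.0,
                 hospitalizations=431_094.0, deaths=4_309.0,
                 qalys=121_313_772.0, lys=139_800_015.0),
}

#: Per-person strategy totals under the cardiorespiratory approach,
#: base case: (total cost €, LYs, QALYs).
CARDIORESP_PER_PERSON = {
    ARM_AQIV: (153.82, 10.2447, 8.8899),
    ARM_HD: (149.90, 10.2460, 8.8912),
}

#: Hospitalizations averted by switching to HD-QIV (cardiorespiratory
#: approach, base case) and the unit admission cost used to value them.
AVERTED_ADMISSIONS = 43_771.0
ADMISSION_COST = 4_035.32

#: Annual admissions coded as influenza and additional cardiorespiratory
#: admissions statistically attributable to influenza (2008–2015 average).
CODED_ADMISSIONS_PER_YEAR = 4_407.0
EXTRA_ATTRIBUTABLE_ADMISSIONS_PER_YEAR = 15_206.0

#: HD-QIV minus aQIV dose price gap (€) implied by the list prices.
PRICE_GAP = 32.27 - 15.45


def coded_arm_outcomes(scenario: str, arm: str) -> ArmOutcomes:
    """Published per-person totals (coded approach) wrapped as ArmOutcomes."""
    cost, lys, qalys = CODED_PER_PERSON[scenario][arm]
    return arm_outcomes_from_totals(arm, per_person_cost=cost,
                                    per_person_lys=lys, per_person_qalys=qalys)


def cardioresp_arm_outcomes(arm: str) -> ArmOutcomes:
    """Published base-case totals (cardiorespiratory approach) as ArmOutcomes.

    Combines the per-person cost/LY/QALY row with the net population
    clinical-outcome column for the same strategy.
    """
    cost, lys, qalys = CARDIORESP_PER_PERSON[arm]
    pop = CARDIORESP_POPULATION[arm]
    return arm_outcomes_from_totals(
        arm, per_person_cost=cost, per_person_lys=lys, per_person_qalys=qalys,
        cases=pop["cases"], gp_visits=pop["gp_visits"], er_visits=pop["er_visits"],
        hospitalizations=pop["hospitalizations"], deaths=pop["deaths"],
        population_lys=pop["lys"], population_qalys=pop["qalys"],
    )
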