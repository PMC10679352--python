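"""Indirect relative-efficacy bridging and rVE-to-risk conversion.

With no head-to-head trial of the high-dose vs the adjuvanted vaccine,
their relative efficacy is bridged through the shared standard-dose
comparator: rVE compose multiplicatively on risk ratios (1 − VE), so

    rVE(A vs B) = 1 − (1 − rVE_A_vs_C) / (1 − rVE_B_vs_C).

A negative result (B outperforms A) is legitimate and propagates.
"""

from __future__ import annotations

from dataclasses import dataclass

from .parameters import ParameterSet

ARM_HD = "HD-QIV"
ARM_AQIV = "aQIV"
ARMS = (ARM_HD, ARM_AQIV)


class UndefinedComparisonError(ValueError):
    """rVE vs the comparator equals 1: the risk-ratio division is undefined."""


@dataclass(frozen=True)
class ArmRiskProfile:
    """Per-person seasonal risks for one strategy after applying its rVE."""

    arm_label: str
    risk_cases: float
    risk_hosp: float
    risk_death_scale: float  # multiplier on the baseline (SD) death risk


def indirect_rve(rve_a_vs_c: float, rve_b_vs_c: float) -> float:
    """rVE of A vs B from each arm's rVE vs a common comparator C."""
    if rve_b_vs_c >= 1.0:
        raise UndefinedComparisonError(
            f"rve_b_vs_c = {rve_b_vs_c} leaves no residual risk in the comparator arm"
        )
    return 1.0 - (1.0 - rve_a_vs_c) / (1.0 - rve_b_vs_c)


def arm_risk(baseline_risk: float, rve_vs_sd: float,
             preventable_fraction: float = 1.0) -> float:
    """Per-person risk under a vaccine, from the SD-comparator baseline risk.

    ``preventable_fraction`` attenuates the rVE before it scales the risk;
    the result is clamped to [0, 1].
    """
    if not 0.0 <= baseline_risk <= 1.0:
        raise ValueError(f"baseline_risk = {baseline_risk} outside [0, 1]")
    return min(1.0, max(0.0, baseline_risk * (1.0 - preventable_fraction * rve_vs_sd)))


def rve_vs_sd(params: ParameterSet, arm: str, outcome: str) -> float:
    """Look up an arm's rVE vs the SD comparator for 'cases' or 'hosp'."""
    eff = params.efficacy
    table = {
        (ARM_HD, "cases"): eff.rve_hd_vs_sd_cases,
        (ARM_HD, "hosp"): eff.rve_hd_vs_sd_hosp,
        (ARM_AQIV, "cases"): eff.rve_aqiv_vs_sd_cases,
        (ARM_AQIV, "hosp"): eff.rve_aqiv_vs_sd_hosp,
    }
    try:
        return table[(arm, outcome)]
    except KeyError:
        raise ValueError(f"unknown arm/outcome: {arm!r}/{outcome!r}") from None


def arm_risk_profile(params: ParameterSet, arm: str) -> ArmRiskProfile:
    """Assemble the per-arm risk profile from the SD-baseline epidemiology.

    Influenza deaths track the cases avoided: the death-risk multiplier is
    1 − f_deaths × rVE_cases, i.e. the arm's case risk ratio with its own
    attenuation factor.
    """
    eff = params.efficacy
    epi = params.epi
    r_cases = arm_risk(epi.attack_rate, rve_vs_sd(params, arm, "cases"),
                       eff.preventable_fraction_cases)
    if params.scenario.hospitalization_approach == "influenza_coded":
        # conditioned on a case downstream; rVE already acts through cases
        r_hosp = epi.p_hosp_influenza_given_case
    else:
        r_hosp = arm_risk(epi.cardioresp_hosp_rate, rve_vs_sd(params, arm, "hosp"),
                          eff.preventable_fraction_hosp)
    death_scale = max(0.0, 1.0 - eff.preventable_fraction_deaths
                      * rve_vs_sd(params, arm, "cases"))
    return ArmRiskProfile(arm_label=arm, risk_cases=r_cases, risk_hosp=r_hosp,
                          risk_death_scale=death_scale)
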