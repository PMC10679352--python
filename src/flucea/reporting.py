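"""Pipeline runner and report writers.

``run_analysis`` executes the full analysis for a configuration — per
scenario, both strategies through the cohort engine, the incremental
comparison, optionally the one-way DSA and the PSA with its CEAC — and
writes figure-ready CSV tables plus a JSON run manifest and a plain-text
log.  Formatting: euros to 2 decimals, per-person LYs/QALYs to 4 decimals;
the underlying CSVs carry full precision.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from . import __version__
from .cohort import expected_arm_outcomes, run_incremental
from .economics import incremental
from .efficacy import ARM_AQIV, ARM_HD
from .parameters import (
    AQIV_SCENARIO_RVE,
    SCHEMA_VERSION,
    ParameterSet,
    load_parameter_set,
    validate,
)
from .sensitivity import ceac, default_dsa_ranges, default_psa_specs, one_way_dsa, run_psa

SCENARIO_ORDER = ("s1_0pct", "s2_6pct", "s3_12pct")


class UsageError(ValueError):
    """Invalid flag combination, rejected before any computation."""


@dataclass(frozen=True)
class RunManifest:
    config: str
    approach: str
    scenarios: tuple[str, ...]
    seed: int
    psa_n: int
    artifacts: tuple[str, ...]
    schema_version: int = SCHEMA_VERSION
    package_version: str = __version__
    timestamp: str = ""
    notes: tuple[str, ...] = field(default_factory=tuple)


def apply_scenario(params: ParameterSet, label: str,
                   custom_rve: float | None = None) -> ParameterSet:
    """Return params with the aQIV-vs-SD rVE set for a named scenario.

    The scenario value applies to both the case and the hospitalization
    outcome (override ``rve_aqiv_vs_sd_hosp`` in the config to decouple).
    """
    if label == "custom":
        if custom_rve is None:
            raise UsageError("custom scenario requires a value")
        rve = custom_rve
    else:
        try:
            rve = AQIV_SCENARIO_RVE[label]
        except KeyError:
            raise UsageError(f"unknown scenario label {label!r}") from None
    return replace(
        params,
        efficacy=replace(params.efficacy, rve_aqiv_vs_sd_cases=rve,
                         rve_aqiv_vs_sd_hosp=rve),
        scenario=replace(params.scenario, aqiv_scenario_label=label),
    )


def incremental_table(params: ParameterSet) -> pd.DataFrame:
    """Per-person strategy totals and increments, one row per quantity.

    Row labels mirror the published summary table: Total costs, Total LYs,
    Total QALYs; columns give both strategies, the increment and the ICER.
    """
    ref = expected_arm_outcomes(params, ARM_AQIV)
    alt = expected_arm_outcomes(params, ARM_HD)
    res = incremental(ref, alt, params.scenario.wtp_per_qaly)
    icer_label = lambda v: (res.dominance.capitalize() if res.dominance
                            else ("" if v is None else f"{v:,.0f}"))
    return pd.DataFrame(
        {
            "outcome": ["Total costs", "Total LYs", "Total QALYs"],
            "aQIV strategy": [ref.per_person.total_cost, ref.per_person.lys,
                              ref.per_person.qalys],
            "HD-QIV strategy": [alt.per_person.total_cost, alt.per_person.lys,
                                alt.per_person.qalys],
            "Incremental": [res.delta_cost, res.delta_ly, res.delta_qaly],
            "ICER": ["", icer_label(res.icer_per_ly), icer_label(res.icer_per_qaly)],
        }
    )


def population_table(params: ParameterSet) -> pd.DataFrame:
    """Net population clinical outcomes per strategy with differentials."""
    ref = expected_arm_outcomes(params, ARM_AQIV)
    alt = expected_arm_outcomes(params, ARM_HD)
    rows = [
        ("Cases of influenza", "cases"),
        ("Influenza-related medical visits", "gp_visits"),
        ("Influenza-related emergency room visits", "er_visits"),
        ("Hospitalizations", "hospitalizations"),
        ("Deaths", "deaths"),
        ("QALYs", "qalys"),
        ("LYs", "lys"),
        ("Total costs", "total_cost"),
    ]
    return pd.DataFrame(
        {
            "outcome": [label for label, _ in rows],
            "aQIV strategy": [getattr(ref.population, k) for _, k in rows],
            "HD-QIV strategy": [getattr(alt.population, k) for _, k in rows],
            "Differential": [getattr(alt.population, k) - getattr(ref.population, k)
                             for _, k in rows],
        }
    )


def run_analysis(
    config: str | Path | ParameterSet,
    approach: str = "influenza_coded",
    scenarios: tuple[str, ...] = SCENARIO_ORDER,
    psa_n: int = 1_000,
    seed: int = 0,
    outdir: str | Path = "results",
    wtp: float | None = None,
    dsa: bool = True,
    custom_rve: float | None = None,
) -> RunManifest:
    """Run the full pipeline and write CSV tables under ``outdir``.

    Deterministic given ``seed``: repeating an invocation reproduces
    byte-identical outputs (timestamps live only in the log/manifest).
    """
    if approach not in ("influenza_coded", "cardiorespiratory"):
        raise UsageError(f"unknown approach {approach!r}")
    if psa_n < 0:
        raise UsageError("psa_n must be >= 0")
    for label in scenarios:
        if label not in SCENARIO_ORDER + ("custom",):
            raise UsageError(f"unknown scenario label {label!r}")

    if isinstance(config, ParameterSet):
        params, config_path = config, "<in-memory>"
    else:
        params, config_path = load_parameter_set(config), str(config)
    report = validate(params)
    if report:
        raise UsageError("invalid configuration:\n" + "\n".join(map(str, report)))

    params = replace(params, scenario=replace(params.scenario,
                                              hospitalization_approach=approach))
    if wtp is not None:
        params = replace(params, scenario=replace(params.scenario, wtp_per_qaly=wtp))

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[str] = []
    notes: list[str] = []
    log_lines: list[str] = [
        f"flucea {__version__} run | config={config_path} approach={approach} "
        f"seed={seed} psa_n={psa_n} wtp={params.scenario.wtp_per_qaly}",
    ]

    def _write(frame: pd.DataFrame, name: str) -> None:
        path = out / name
        frame.to_csv(path, index=False, float_format="%.10g")
        artifacts.append(str(path))
        log_lines.append(f"wrote {path}")

    for label in scenarios:
        sp = apply_scenario(params, label, custom_rve)
        res = run_incremental(sp)
        log_lines.append(
            f"scenario {label}: dCost={res.delta_cost:.2f} dQALY={res.delta_qaly:.6f} "
            f"ICER={res.icer_per_qaly} quadrant={res.quadrant}")
        _write(incremental_table(sp), f"incremental_{label}.csv")
        _write(population_table(sp), f"population_{label}.csv")

    base = apply_scenario(params, scenarios[0], custom_rve)
    if dsa:
        tornado = one_way_dsa(base, default_dsa_ranges(base))
        _write(tornado.to_frame(), "dsa_tornado.csv")
    if psa_n > 0:
        psa = run_psa(base, default_psa_specs(base), psa_n, seed)
        _write(psa.to_frame(), "psa_draws.csv")
        _write(ceac(psa), "ceac.csv")
        if psa.failures:
            notes.append(f"{len(psa.failures)} PSA draw(s) failed and were recorded")
    else:
        notes.append("PSA skipped (psa_n = 0)")

    manifest = RunManifest(
        config=config_path, approach=approach, scenarios=tuple(scenarios),
        seed=seed, psa_n=psa_n, artifacts=tuple(artifacts),
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"), notes=tuple(notes),
    )
    (out / "manifest.json").write_text(json.dumps(manifest.__dict__, indent=2))
    log_lines.extend(notes)
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return manifest
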