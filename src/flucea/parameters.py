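"""Model-input data model: typed parameter bundles, validation, YAML I/O.

The complete input set for the cohort model is a :class:`ParameterSet`
grouping vaccine efficacy, seasonal epidemiology, unit costs, utilities,
a cohort life table and scenario switches.  Configurations are stored as
versioned YAML documents (``schema: 1``); unknown keys are rejected and
documented optional keys take defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Any, Iterator, Mapping

import yaml

SCHEMA_VERSION = 1

HOSPITALIZATION_APPROACHES = ("influenza_coded", "cardiorespiratory")
AQIV_SCENARIO_LABELS = ("s1_0pct", "s2_6pct", "s3_12pct", "custom")

#: rVE of the adjuvanted vaccine vs the standard-dose comparator under the
#: three published scenarios (base case 0%, then 6% and 12%).
AQIV_SCENARIO_RVE = {"s1_0pct": 0.0, "s2_6pct": 0.06, "s3_12pct": 0.12}


class SchemaError(ValueError):
    """Configuration document does not match the documented schema."""


class FormatError(ValueError):
    """Configuration file could not be parsed at all."""


@dataclass(frozen=True)
class EfficacySpec:
    """Relative vaccine efficacy (rVE) inputs, all vs the SD-QIV comparator.

    ``preventable_fraction_*`` attenuate an rVE before it scales a
    population-level risk (e.g. when only a fraction of the outcome is
    vaccine-preventable laboratory-confirmed influenza); 1.0 means the rVE
    applies in full.
    """

    rve_hd_vs_sd_cases: float = 0.242
    rve_hd_vs_sd_hosp: float = 0.182
    rve_aqiv_vs_sd_cases: float = 0.0
    rve_aqiv_vs_sd_hosp: float = 0.0
    preventable_fraction_cases: float = 1.0
    preventable_fraction_hosp: float = 1.0
    preventable_fraction_deaths: float = 1.0


@dataclass(frozen=True)
class EpidemiologyInputs:
    """Seasonal epidemiology for the vaccinated cohort (all rates per season)."""

    cohort_size: float
    attack_rate: float
    p_gp_given_case: float
    p_er_given_case: float
    p_hosp_influenza_given_case: float
    cardioresp_hosp_rate: float
    excess_mortality_per_100k: float
    coverage: float = 1.0


@dataclass(frozen=True)
class CostInputs:
    """Unit costs in euros (payer perspective)."""

    cost_gp_visit: float
    cost_er_visit: float
    cost_otc_per_case: float
    price_aqiv: float = 15.45
    price_hd: float = 32.27
    admin_cost: float = 0.0
    cost_hospitalization: float = 4035.32


@dataclass(frozen=True)
class UtilityInputs:
    """Health-state utilities and event durations.

    ``baseline_utility_by_age`` maps integer age to the population norm
    utility; episode utilities apply for the stated durations (days).
    """

    baseline_utility_by_age: Mapping[int, float]
    utility_influenza_episode: float
    utility_hospitalized: float
    influenza_duration_days: float = 6.0
    hospitalization_duration_days: float = 5.2

    def min_baseline(self) -> float:
        return min(self.baseline_utility_by_age.values())


@dataclass(frozen=True)
class LifeTable:
    """Annual survival probabilities on a closed age grid, with discounting."""

    ages: tuple[int, ...]
    annual_survival_prob: tuple[float, ...]
    discount_rate: float = 0.03

    def survival_at(self, age: int) -> float:
        return self.annual_survival_prob[self.ages.index(age)]

    @property
    def max_age(self) -> int:
        return self.ages[-1]


@dataclass(frozen=True)
class ScenarioSpec:
    """Analysis switches: hospitalization definition, aQIV scenario, WTP."""

    hospitalization_approach: str = "influenza_coded"
    aqiv_scenario_label: str = "s1_0pct"
    wtp_per_qaly: float = 30_000.0


@dataclass(frozen=True)
class ParameterSet:
    """Complete, validated input bundle for one model run."""

    efficacy: EfficacySpec
    epi: EpidemiologyInputs
    costs: CostInputs
    utilities: UtilityInputs
    life_table: LifeTable
    scenario: ScenarioSpec
    age_distribution: Mapping[int, float]


@dataclass(frozen=True)
class Violation:
    field: str
    value: Any
    rule: str

    def __str__(self) -> str:
        return f"{self.field} = {self.value!r} violates: {self.rule}"


def _check(report: list[Violation], ok: bool, name: str, value: Any, rule: str) -> None:
    if not ok:
        report.append(Violation(name, value, rule))


def validate(params: ParameterSet) -> list[Violation]:
    """Return the list of invariant violations (empty iff valid).

    Pure: the same input always produces the same report.
    """
    r: list[Violation] = []
    eff = params.efficacy
    for name in (
        "rve_hd_vs_sd_cases",
        "rve_hd_vs_sd_hosp",
        "rve_aqiv_vs_sd_cases",
        "rve_aqiv_vs_sd_hosp",
        "preventable_fraction_cases",
        "preventable_fraction_hosp",
        "preventable_fraction_deaths",
    ):
        v = getattr(eff, name)
        _check(r, 0.0 <= v <= 1.0, f"efficacy.{name}", v, "must lie in [0, 1]")
    for name in ("rve_aqiv_vs_sd_cases", "rve_aqiv_vs_sd_hosp"):
        v = getattr(eff, name)
        _check(r, v < 1.0, f"efficacy.{name}", v,
               "must be < 1 so the common-comparator division is defined")

    epi = params.epi
    _check(r, epi.cohort_size > 0, "epi.cohort_size", epi.cohort_size, "must be > 0")
    for name in ("attack_rate", "p_gp_given_case", "p_er_given_case",
                 "p_hosp_influenza_given_case", "cardioresp_hosp_rate", "coverage"):
        v = getattr(epi, name)
        _check(r, 0.0 <= v <= 1.0, f"epi.{name}", v, "probability must lie in [0, 1]")
    _check(r, epi.excess_mortality_per_100k >= 0, "epi.excess_mortality_per_100k",
           epi.excess_mortality_per_100k, "must be >= 0")

    costs = params.costs
    for f in fields(costs):
        v = getattr(costs, f.name)
        _check(r, v >= 0, f"costs.{f.name}", v, "cost must be >= 0")

    util = params.utilities
    for age, u in util.baseline_utility_by_age.items():
        _check(r, 0.0 <= u <= 1.0, f"utilities.baseline_utility_by_age[{age}]", u,
               "utility must lie in [0, 1]")
    for name in ("utility_influenza_episode", "utility_hospitalized"):
        v = getattr(util, name)
        _check(r, 0.0 <= v <= 1.0, f"utilities.{name}", v, "utility must lie in [0, 1]")
    _check(r, util.utility_hospitalized <= util.utility_influenza_episode,
           "utilities.utility_hospitalized", util.utility_hospitalized,
           "hospitalized utility must not exceed influenza-episode utility")
    _check(r, util.utility_influenza_episode <= util.min_baseline(),
           "utilities.utility_influenza_episode", util.utility_influenza_episode,
           "episode utility must not exceed the minimum baseline utility")
    for name in ("influenza_duration_days", "hospitalization_duration_days"):
        v = getattr(util, name)
        _check(r, v > 0, f"utilities.{name}", v, "duration must be > 0")

    lt = params.life_table
    _check(r, len(lt.ages) == len(lt.annual_survival_prob), "life_table.ages",
           len(lt.ages), "ages and annual_survival_prob must have equal length")
    _check(r, all(b - a == 1 for a, b in zip(lt.ages, lt.ages[1:])),
           "life_table.ages", lt.ages[:3] if lt.ages else (),
           "age grid must be consecutive integers without gaps")
    for age, s in zip(lt.ages, lt.annual_survival_prob):
        _check(r, 0.0 <= s <= 1.0, f"life_table.annual_survival_prob[{age}]", s,
               "survival probability must lie in [0, 1]")
    _check(r, lt.discount_rate >= 0, "life_table.discount_rate", lt.discount_rate,
           "discount rate must be >= 0")

    sc = params.scenario
    _check(r, sc.hospitalization_approach in HOSPITALIZATION_APPROACHES,
           "scenario.hospitalization_approach", sc.hospitalization_approach,
           f"must be one of {HOSPITALIZATION_APPROACHES}")
    _check(r, sc.aqiv_scenario_label in AQIV_SCENARIO_LABELS,
           "scenario.aqiv_scenario_label", sc.aqiv_scenario_label,
           f"must be one of {AQIV_SCENARIO_LABELS}")
    _check(r, sc.wtp_per_qaly > 0, "scenario.wtp_per_qaly", sc.wtp_per_qaly,
           "willingness-to-pay must be > 0")

    dist = params.age_distribution
    total = sum(dist.values())
    _check(r, abs(total - 1.0) <= 1e-9, "age_distribution", total,
           "proportions must sum to 1 within 1e-9")
    for age, w in dist.items():
        _check(r, w >= 0, f"age_distribution[{age}]", w, "proportion must be >= 0")
        _check(r, age in lt.ages, f"age_distribution[{age}]", age,
               "age must lie on the life-table grid")
    return r


# ---------------------------------------------------------------------------
# serialisation

_SECTIONS = {
    "efficacy": EfficacySpec,
    "epi": EpidemiologyInputs,
    "costs": CostInputs,
    "utilities": UtilityInputs,
    "life_table": LifeTable,
    "scenario": ScenarioSpec,
}


def _section_from_mapping(cls: type, name: str, data: Mapping[str, Any]) -> Any:
    if not isinstance(data, Mapping):
        raise SchemaError(f"section '{name}' must be a mapping")
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise SchemaError(f"unknown key(s) in '{name}': {sorted(unknown)}")
    kwargs: dict[str, Any] = {}
    for f in fields(cls):
        if f.name in data:
            v = data[f.name]
            if f.name == "baseline_utility_by_age":
                v = {int(k): float(u) for k, u in v.items()}
            elif f.name == "ages":
                v = tuple(int(a) for a in v)
            elif f.name == "annual_survival_prob":
                v = tuple(float(s) for s in v)
            elif f.name in ("hospitalization_approach", "aqiv_scenario_label"):
                v = str(v)
            else:
                v = float(v)
            kwargs[f.name] = v
        elif f.default is dataclasses.MISSING and f.default_factory is dataclasses.MISSING:
            raise SchemaError(f"missing required key '{name}.{f.name}'")
    return cls(**kwargs)


def from_mapping(doc: Mapping[str, Any]) -> ParameterSet:
    """Build a validated :class:`ParameterSet` from a plain mapping."""
    if not isinstance(doc, Mapping):
        raise SchemaError("top-level document must be a mapping")
    if doc.get("schema") != SCHEMA_VERSION:
        raise SchemaError(f"missing or unsupported 'schema' key (expected {SCHEMA_VERSION})")
    expected = set(_SECTIONS) | {"schema", "age_distribution"}
    unknown = set(doc) - expected
    if unknown:
        raise SchemaError(f"unknown top-level key(s): {sorted(unknown)}")
    missing = (set(_SECTIONS) | {"age_distribution"}) - set(doc)
    if missing:
        raise SchemaError(f"missing required key '{sorted(missing)[0]}'")
    sections = {name: _section_from_mapping(cls, name, doc[name])
                for name, cls in _SECTIONS.items()}
    age_distribution = {int(a): float(w) for a, w in doc["age_distribution"].items()}
    params = ParameterSet(age_distribution=age_distribution, **sections)
    report = validate(params)
    if report:
        raise SchemaError("invalid parameter set:\n" + "\n".join(map(str, report)))
    return params


def to_mapping(params: ParameterSet) -> dict[str, Any]:
    doc: dict[str, Any] = {"schema": SCHEMA_VERSION}
    for name in _SECTIONS:
        section = getattr(params, name)
        d = dataclasses.asdict(section)
        if name == "utilities":
            d["baseline_utility_by_age"] = dict(section.baseline_utility_by_age)
        if name == "life_table":
            d["ages"] = list(section.ages)
            d["annual_survival_prob"] = list(section.annual_survival_prob)
        doc[name] = d
    doc["age_distribution"] = dict(params.age_distribution)
    return doc


def load_parameter_set(path: str | Path) -> ParameterSet:
    """Load and validate a parameter configuration from a YAML file."""
    text = Path(path).read_text()
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise FormatError(f"could not parse {path}: {exc}") from exc
    return from_mapping(doc)


def save_parameter_set(params: ParameterSet, path: str | Path) -> None:
    """Write a parameter set as a YAML document (round-trips via load)."""
    Path(path).write_text(yaml.safe_dump(to_mapping(params), sort_keys=True))


# ---------------------------------------------------------------------------
# dotted-path access for sensitivity analyses

def iter_scalar_paths(params: ParameterSet) -> Iterator[str]:
    """Yield dotted paths of every scalar numeric leaf (maps excluded)."""
    for name, cls in _SECTIONS.items():
        for f in fields(cls):
            v = getattr(getattr(params, name), f.name)
            if isinstance(v, (int, float)) and not isinstance(v, bool):
                yield f"{name}.{f.name}"


def get_param(params: ParameterSet, path: str) -> float:
    section, _, leaf = path.partition(".")
    if section not in _SECTIONS or not leaf:
        raise KeyError(f"unknown parameter path {path!r}")
    try:
        value = getattr(getattr(params, section), leaf)
    except AttributeError:
        raise KeyError(f"unknown parameter path {path!r}") from None
    if not isinstance(value, (int, float)):
        raise KeyError(f"parameter path {path!r} is not a scalar")
    return float(value)


def with_params(params: ParameterSet, updates: Mapping[str, float]) -> ParameterSet:
    """Return a copy with scalar leaves replaced per ``{dotted path: value}``."""
    by_section: dict[str, dict[str, float]] = {}
    for path, value in updates.items():
        section, _, leaf = path.partition(".")
        get_param(params, path)  # raises on unknown paths
        by_section.setdefault(section, {})[leaf] = float(value)
    return replace(params, **{
        section: replace(getattr(params, section), **leaves)
        for section, leaves in by_section.items()
    })


def with_param(params: ParameterSet, path: str, value: float) -> ParameterSet:
    return with_params(params, {path: value})


def param_bounds(path: str) -> tuple[float, float]:
    """Hard bounds a parameter must respect after clamping a DSA/PSA value."""
    leaf = path.rsplit(".", 1)[-1]
    eps = 1e-9
    if leaf.startswith("rve_aqiv"):
        return (0.0, 1.0 - 1e-6)  # comparator division must stay defined
    if leaf.startswith(("rve_", "preventable_", "p_", "attack_", "coverage",
                        "utility_", "cardioresp_")):
        return (0.0, 1.0)
    if leaf.startswith(("cost_", "price_", "admin_", "excess_", "discount_")):
        return (0.0, float("inf"))
    if leaf.endswith("_days") or leaf in ("cohort_size", "wtp_per_qaly"):
        return (eps, float("inf"))
    return (-float("inf"), float("inf"))
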