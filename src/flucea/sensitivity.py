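"""Deterministic (one-way) and probabilistic sensitivity analysis.

One-way DSA reruns the whole pipeline at each parameter's low and high
bound (95% CI when supplied, else mean ± 15%) and ranks parameters into a
tornado table.  Because an ICER is sign-ambiguous across quadrants, the
tornado span is measured on the incremental net monetary benefit at the
base-case willingness-to-pay — a scale that is monotone and defined in
every quadrant — while the ICERs at both endpoints are still recorded
with their dominance flags.

PSA draws parameters from moment-matched distributions (beta for
probabilities and utilities, gamma for costs, normal for efficacies),
reruns both arms per draw, and summarises the (ΔCost, ΔQALY) cloud as a
cost-effectiveness acceptability curve: the probability that
NMB = WTP × ΔQALY − ΔCost is strictly positive, per WTP.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import run_incremental
from .economics import nmb
from .parameters import ParameterSet, get_param, param_bounds, validate, with_params

DEFAULT_REL_RANGE = 0.15
DEFAULT_WTP_GRID = tuple(range(0, 100_001, 1_000))

#: parameters given a ±15% one-way range (and a PSA distribution) by default
DEFAULT_SENSITIVITY_PATHS = (
    "efficacy.rve_hd_vs_sd_cases",
    "efficacy.rve_hd_vs_sd_hosp",
    "efficacy.rve_aqiv_vs_sd_cases",
    "efficacy.rve_aqiv_vs_sd_hosp",
    "epi.attack_rate",
    "epi.p_gp_given_case",
    "epi.p_er_given_case",
    "epi.p_hosp_influenza_given_case",
    "epi.cardioresp_hosp_rate",
    "epi.excess_mortality_per_100k",
    "costs.cost_gp_visit",
    "costs.cost_er_visit",
    "costs.cost_otc_per_case",
    "costs.cost_hospitalization",
    "utilities.utility_influenza_episode",
    "utilities.utility_hospitalized",
)


@dataclass(frozen=True)
class ParamRange:
    """One-way range for a parameter (95% CI when available, else ±15%)."""

    parameter: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if self.low > self.high:
            raise ValueError(f"{self.parameter}: low {self.low} > high {self.high}")


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    low: float
    high: float
    icer_at_low: float | None
    icer_at_high: float | None
    dominance_at_low: str | None
    dominance_at_high: str | None
    nmb_at_low: float
    nmb_at_high: float
    span: float  # |NMB(high) − NMB(low)| at the base-case WTP


@dataclass(frozen=True)
class TornadoTable:
    base_icer: float | None
    base_nmb: float
    wtp: float
    entries: tuple[TornadoEntry, ...]  # sorted by span, descending

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([e.__dict__ for e in self.entries])


def default_dsa_ranges(params: ParameterSet,
                       rel: float = DEFAULT_REL_RANGE) -> list[ParamRange]:
    """Mean ± ``rel`` ranges for the standard sensitivity parameter list."""
    ranges = []
    for path in DEFAULT_SENSITIVITY_PATHS:
        mean = get_param(params, path)
        ranges.append(ParamRange(path, mean * (1.0 - rel), mean * (1.0 + rel)))
    return ranges


def one_way_dsa(params: ParameterSet, ranges: list[ParamRange]) -> TornadoTable:
    """Tornado table: rerun the pipeline at each range's low and high bound.

    Bounds are clamped to the parameter's hard invariants first; a range
    that collapses or still violates an invariant is skipped with a warning.
    """
    wtp = params.scenario.wtp_per_qaly
    base = run_incremental(params)
    entries: list[TornadoEntry] = []
    for rng_ in ranges:
        lo_b, hi_b = param_bounds(rng_.parameter)
        low = min(max(rng_.low, lo_b), hi_b)
        high = min(max(rng_.high, lo_b), hi_b)
        try:
            res_low = run_incremental(with_params(params, {rng_.parameter: low}))
            res_high = run_incremental(with_params(params, {rng_.parameter: high}))
        except Exception as exc:  # invariant still violated after clamping
            warnings.warn(f"skipping {rng_.parameter}: {exc}", stacklevel=2)
            continue
        entries.append(TornadoEntry(
            parameter=rng_.parameter, low=low, high=high,
            icer_at_low=res_low.icer_per_qaly, icer_at_high=res_high.icer_per_qaly,
            dominance_at_low=res_low.dominance, dominance_at_high=res_high.dominance,
            nmb_at_low=res_low.nmb_at_wtp, nmb_at_high=res_high.nmb_at_wtp,
            span=abs(res_high.nmb_at_wtp - res_low.nmb_at_wtp),
        ))
    entries.sort(key=lambda e: (-e.span, e.parameter))
    return TornadoTable(base_icer=base.icer_per_qaly, base_nmb=base.nmb_at_wtp,
                        wtp=wtp, entries=tuple(entries))


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis

FAMILIES = ("beta", "gamma", "normal", "point")


class DistributionSpecError(ValueError):
    """Moments incompatible with the distribution family's support."""


@dataclass(frozen=True)
class DistributionSpec:
    """Moment-parameterised sampling distribution for one parameter."""

    parameter: str
    family: str
    mean: float
    se: float

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise DistributionSpecError(f"unknown family {self.family!r}")
        if self.se < 0:
            raise DistributionSpecError(f"{self.parameter}: se must be >= 0")
        if self.family == "beta":
            if not 0.0 <= self.mean <= 1.0:
                raise DistributionSpecError(f"{self.parameter}: beta mean outside [0, 1]")
            if self.se > 0 and self.se ** 2 >= self.mean * (1.0 - self.mean):
                raise DistributionSpecError(
                    f"{self.parameter}: se {self.se} too large for beta mean {self.mean}")
        if self.family == "gamma" and self.mean < 0:
            raise DistributionSpecError(f"{self.parameter}: gamma mean must be >= 0")


def default_psa_specs(params: ParameterSet, rel: float = DEFAULT_REL_RANGE
                      ) -> list[DistributionSpec]:
    """Distribution specs by parameter class, se such that ±rel ≈ a 95% CI.

    Beta for probabilities and utilities, gamma for costs, normal for
    relative efficacies.
    """
    specs = []
    for path in DEFAULT_SENSITIVITY_PATHS:
        mean = get_param(params, path)
        leaf = path.rsplit(".", 1)[-1]
        if leaf.startswith("rve_"):
            family = "normal"
        elif path.startswith("costs."):
            family = "gamma"
        elif 0.0 < mean < 1.0:
            family = "beta"
        else:  # nonnegative rates outside (0, 1), e.g. per-100k mortality
            family = "gamma" if mean > 0.0 else "point"
        se = rel * abs(mean) / 1.96
        if se == 0.0:
            family = "point"
        specs.append(DistributionSpec(path, family, mean, se))
    return specs


def _sample(spec: DistributionSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    if spec.family == "point" or spec.se == 0.0:
        return np.full(n, spec.mean)
    if spec.family == "beta":
        nu = spec.mean * (1.0 - spec.mean) / spec.se ** 2 - 1.0
        return rng.beta(spec.mean * nu, (1.0 - spec.mean) * nu, size=n)
    if spec.family == "gamma":
        shape = (spec.mean / spec.se) ** 2
        scale = spec.se ** 2 / spec.mean
        return rng.gamma(shape, scale, size=n)
    return rng.normal(spec.mean, spec.se, size=n)


def draw_parameters(specs: list[DistributionSpec], n: int, seed: int) -> pd.DataFrame:
    """Moment-matched parameter draws, one column per parameter path.

    Draws are clamped to the parameter's hard bounds; per-column clamp
    counts are reported in ``frame.attrs['clamp_counts']``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    columns: dict[str, np.ndarray] = {}
    clamps: dict[str, int] = {}
    for spec in specs:
        raw = _sample(spec, n, rng)
        lo, hi = param_bounds(spec.parameter)
        clipped = np.clip(raw, lo, hi)
        clamps[spec.parameter] = int((clipped != raw).sum())
        columns[spec.parameter] = clipped
    frame = pd.DataFrame(columns)
    frame.attrs["clamp_counts"] = clamps
    return frame


@dataclass(frozen=True)
class PSAResult:
    """Paired per-person (ΔCost, ΔQALY) draws from the probabilistic analysis."""

    n_draws: int
    seed: int
    delta_cost: np.ndarray
    delta_qaly: np.ndarray
    failures: tuple[tuple[int, str], ...] = field(default_factory=tuple)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"draw": np.arange(self.n_draws),
                             "delta_cost": self.delta_cost,
                             "delta_qaly": self.delta_qaly})


def run_psa(params: ParameterSet, specs: list[DistributionSpec], n: int,
            seed: int) -> PSAResult:
    """Rerun both arms per parameter draw; per-draw failures are recorded,
    not raised."""
    table = draw_parameters(specs, n, seed)
    dc = np.full(n, np.nan)
    dq = np.full(n, np.nan)
    failures: list[tuple[int, str]] = []
    for i in range(n):
        updates = {col: float(table.iloc[i][col]) for col in table.columns}
        try:
            candidate = with_params(params, updates)
            report = validate(candidate)
            if report:
                raise ValueError("; ".join(str(v) for v in report[:3]))
            res = run_incremental(candidate)
        except Exception as exc:
            failures.append((i, str(exc)))
            continue
        dc[i] = res.delta_cost
        dq[i] = res.delta_qaly
    return PSAResult(n_draws=n, seed=seed, delta_cost=dc, delta_qaly=dq,
                     failures=tuple(failures))


def ceac(psa: PSAResult, wtp_grid: tuple[float, ...] = DEFAULT_WTP_GRID) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve over a WTP grid.

    Probability at each WTP = fraction of draws with strictly positive net
    monetary benefit (ties count as not cost-effective); failed draws count
    in the denominator as not cost-effective.
    """
    if len(wtp_grid) == 0:
        raise ValueError("wtp_grid must be nonempty")
    probs = []
    for wtp in wtp_grid:
        net = nmb(psa.delta_cost, psa.delta_qaly, wtp)
        probs.append(float(np.sum(net > 0)) / psa.n_draws)
    return pd.DataFrame({"wtp": list(wtp_grid), "prob_cost_effective": probs})
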