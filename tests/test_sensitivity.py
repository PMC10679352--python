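"""One-way DSA (tornado), PSA draws, and the acceptability curve."""

import random

import numpy as np
import pytest

from flucea import (
    DistributionSpec,
    ParamRange,
    ceac,
    default_dsa_ranges,
    default_psa_specs,
    draw_parameters,
    one_way_dsa,
    run_incremental,
    run_psa,
)
from flucea.parameters import with_param
from flucea.sensitivity import DEFAULT_SENSITIVITY_PATHS, DistributionSpecError, PSAResult


def test_default_ranges_are_plus_minus_15_percent(params):
    ranges = {r.parameter: r for r in default_dsa_ranges(params)}
    mean = params.epi.attack_rate
    r = ranges["epi.attack_rate"]
    assert r.low == pytest.approx(0.85 * mean)
    assert r.high == pytest.approx(1.15 * mean)
    assert set(ranges) == set(DEFAULT_SENSITIVITY_PATHS)


def test_inert_parameter_has_zero_span_and_sorts_last(params):
    """Under the coded approach the cardiorespiratory rate never enters the
    pipeline, so its tornado span is exactly zero."""
    ranges = [ParamRange("epi.attack_rate", 0.05, 0.07),
              ParamRange("epi.cardioresp_hosp_rate", 0.05, 0.08)]
    table = one_way_dsa(params, ranges)
    spans = {e.parameter: e.span for e in table.entries}
    assert spans["epi.cardioresp_hosp_rate"] == 0.0
    assert table.entries[-1].parameter == "epi.cardioresp_hosp_rate"


def test_tornado_sorted_descending_and_order_invariant(cardio_params):
    ranges = default_dsa_ranges(cardio_params)
    table = one_way_dsa(cardio_params, ranges)
    spans = [e.span for e in table.entries]
    assert spans == sorted(spans, reverse=True)
    shuffled = ranges[:]
    random.Random(3).shuffle(shuffled)
    assert one_way_dsa(cardio_params, shuffled).entries == table.entries


def test_hospitalization_efficacy_monotonically_improves_the_icer(cardio_params):
    """Rerunning the engine on a 5-point grid of rVE-hosp(HD vs SD): the
    incremental comparison improves (NMB rises) as efficacy grows."""
    grid = np.linspace(0.10, 0.30, 5)
    nmbs = [run_incremental(with_param(cardio_params, "efficacy.rve_hd_vs_sd_hosp", v)
                            ).nmb_at_wtp for v in grid]
    assert all(b > a for a, b in zip(nmbs, nmbs[1:]))


def test_bounds_clamped_before_rerun(params):
    # a range deliberately exceeding [0, 1] is clamped, not an error
    table = one_way_dsa(params, [ParamRange("epi.attack_rate", -0.5, 1.5)])
    (entry,) = table.entries
    assert entry.low == 0.0
    assert entry.high == 1.0


def test_point_mass_draws_equal_the_mean():
    specs = [DistributionSpec("epi.attack_rate", "point", 0.06, 0.0),
             DistributionSpec("costs.cost_gp_visit", "gamma", 20.0, 0.0)]
    frame = draw_parameters(specs, 100, seed=0)
    assert (frame["epi.attack_rate"] == 0.06).all()
    assert (frame["costs.cost_gp_visit"] == 20.0).all()


def test_beta_draws_match_the_requested_moments():
    spec = DistributionSpec("epi.attack_rate", "beta", 0.3, 0.05)
    frame = draw_parameters([spec], 50_000, seed=11)
    x = frame["epi.attack_rate"]
    assert x.mean() == pytest.approx(0.3, abs=0.005)
    assert x.std() == pytest.approx(0.05, abs=0.005)
    assert ((x >= 0) & (x <= 1)).all()


def test_gamma_and_normal_draws_match_moments():
    specs = [DistributionSpec("costs.cost_gp_visit", "gamma", 20.0, 3.0),
             DistributionSpec("efficacy.rve_hd_vs_sd_cases", "normal", 0.242, 0.02)]
    frame = draw_parameters(specs, 50_000, seed=11)
    assert frame["costs.cost_gp_visit"].mean() == pytest.approx(20.0, rel=0.01)
    assert frame["costs.cost_gp_visit"].std() == pytest.approx(3.0, rel=0.05)
    assert frame["efficacy.rve_hd_vs_sd_cases"].mean() == pytest.approx(0.242, abs=0.001)


def test_beta_se_incompatible_with_mean_rejected():
    with pytest.raises(DistributionSpecError):
        DistributionSpec("epi.attack_rate", "beta", 0.01, 0.5)


def test_draws_are_reproducible_per_seed(params):
    specs = default_psa_specs(params)
    a = draw_parameters(specs, 200, seed=9)
    b = draw_parameters(specs, 200, seed=9)
    assert a.equals(b)


def test_degenerate_psa_equals_deterministic_result(cardio_params):
    det = run_incremental(cardio_params)
    specs = [DistributionSpec(s.parameter, "point", s.mean, 0.0)
             for s in default_psa_specs(cardio_params)]
    psa = run_psa(cardio_params, specs, 20, seed=0)
    assert psa.failures == ()
    assert np.allclose(psa.delta_cost, det.delta_cost)
    assert np.allclose(psa.delta_qaly, det.delta_qaly)


def test_psa_converges_to_deterministic_as_se_vanishes(cardio_params):
    det = run_incremental(cardio_params)
    specs = [DistributionSpec(s.parameter, s.family, s.mean, min(s.se, 1e-6))
            for s in default_psa_specs(cardio_params)]
    psa = run_psa(cardio_params, specs, 50, seed=1)
    assert np.nanmean(psa.delta_cost) == pytest.approx(det.delta_cost, rel=1e-3)
    assert np.nanmean(psa.delta_qaly) == pytest.approx(det.delta_qaly, rel=1e-3)


def test_wide_margin_dominance_survives_draw_noise(cardio_params):
    """The hidden-burden base case is dominant by a wide margin; most PSA
    draws land in the south-east quadrant."""
    psa = run_psa(cardio_params, default_psa_specs(cardio_params), 300, seed=4)
    se_frac = np.mean((psa.delta_cost < 0) & (psa.delta_qaly > 0))
    assert se_frac >= 0.90


def test_psa_is_reproducible_per_seed(cardio_params):
    specs = default_psa_specs(cardio_params)
    a = run_psa(cardio_params, specs, 50, seed=21)
    b = run_psa(cardio_params, specs, 50, seed=21)
    assert np.array_equal(a.delta_cost, b.delta_cost)
    assert np.array_equal(a.delta_qaly, b.delta_qaly)


def _single_draw_psa(dc, dq):
    return PSAResult(n_draws=1, seed=0, delta_cost=np.array([dc]),
                     delta_qaly=np.array([dq]))


def test_ceac_is_one_everywhere_when_all_draws_dominant():
    psa = PSAResult(n_draws=3, seed=0, delta_cost=np.array([-1.0, -2.0, -0.5]),
                    delta_qaly=np.array([0.001, 0.002, 0.0005]))
    curve = ceac(psa, wtp_grid=(0.0, 10_000.0, 50_000.0))
    assert (curve["prob_cost_effective"] == 1.0).all()


def test_ceac_steps_at_the_deterministic_icer():
    """A degenerate cloud at (8.67, 0.00118) flips from not-cost-effective
    to cost-effective exactly at 8.67/0.00118 ≈ €7,347.46."""
    icer = 8.67 / 0.00118
    psa = _single_draw_psa(8.67, 0.00118)
    curve = ceac(psa, wtp_grid=(icer - 1.0, icer, icer + 1.0))
    assert list(curve["prob_cost_effective"]) == [0.0, 0.0, 1.0]
    assert icer == pytest.approx(7_347.457627, abs=1e-5)


def test_ceac_nondecreasing_when_all_effect_deltas_positive(cardio_params):
    psa = run_psa(cardio_params, default_psa_specs(cardio_params), 100, seed=6)
    assert (psa.delta_qaly > 0).all()
    curve = ceac(psa, wtp_grid=tuple(range(0, 50_001, 5_000)))
    probs = list(curve["prob_cost_effective"])
    assert all(b >= a for a, b in zip(probs, probs[1:]))


def test_empty_wtp_grid_rejected():
    with pytest.raises(ValueError):
        ceac(_single_draw_psa(1.0, 0.001), wtp_grid=())
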