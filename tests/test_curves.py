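"""Sweep grids and stacked stressor-response curves."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import evdkit
from evdkit.curves import CurveError, site_response, sweep_grid
from evdkit.dataset import RunConfig, SurveyDataset
from evdkit.screening import ScreenedPredictors

from conftest import make_flat_sdm


def _tiny_dataset(env_values: dict, occ_values: dict, reference=None):
    sites = [f"s{i}" for i in range(len(next(iter(env_values.values()))))]
    env = pd.DataFrame(env_values, index=sites)
    occ = pd.DataFrame(occ_values, index=sites)
    return SurveyDataset(
        env=env, occ=occ,
        reference_ids=reference or sites[:2],
        variable_roles={v: "stressor_increase" for v in env.columns},
    )


def _identity_screen(variables):
    return ScreenedPredictors(
        kept=list(variables), dropped=[],
        means={v: 0.0 for v in variables}, sds={v: 1.0 for v in variables},
    )


# -----------------------------------------------------------------------------
# sweep grids


def test_sweep_grid_tracks_empirical_quantiles():
    rng = np.random.default_rng(4)
    env = pd.DataFrame({"s": rng.uniform(0, 100, size=5000)})
    grid = sweep_grid(env, "s", (0.01, 0.99), 101)
    lo, hi = np.quantile(env["s"], [0.01, 0.99])
    assert grid[0] == pytest.approx(lo)
    assert grid[-1] == pytest.approx(hi)
    assert grid[0] == pytest.approx(1.0, abs=1.0)  # sampling error on a U(0,100)
    assert grid[-1] == pytest.approx(99.0, abs=1.0)
    assert len(grid) == 101 and np.all(np.diff(grid) > 0)


def test_sweep_grid_full_quantiles_span_min_max_exactly():
    env = pd.DataFrame({"s": [3.0, 7.0, 1.0, 9.0, 5.0]})
    grid = sweep_grid(env, "s", (0.0, 1.0), 11)
    assert grid[0] == 1.0 and grid[-1] == 9.0


def test_sweep_grid_extends_to_cover_reference_values_and_respects_bounds():
    env = pd.DataFrame({"s": np.linspace(0.2, 0.8, 100)})
    grid = sweep_grid(env, "s", (0.05, 0.95), 51, include=[0.95])
    assert grid[-1] >= 0.95
    clipped = sweep_grid(env, "s", (0.0, 1.0), 51, bounds=(0.3, 0.7))
    assert clipped[0] >= 0.3 and clipped[-1] <= 0.7
    with pytest.raises(CurveError, match="zero-width"):
        sweep_grid(pd.DataFrame({"s": [2.0] * 10}), "s", (0.0, 1.0), 11)


# -----------------------------------------------------------------------------
# stacking


def test_all_zero_coefficients_give_flat_unit_rsr():
    ds = _tiny_dataset({"s1": [0.1, 0.5, 0.9]}, {"spA": [1, 1, 1]})
    sdm = make_flat_sdm("spA", ("s1",))
    curve = site_response(ds, "s0", "s1", [sdm], _identity_screen(["s1"]), RunConfig(sweep_points=21))
    assert np.allclose(curve.rsr, 1.0, atol=1e-12)
    assert curve.species_pool == ("spA",)


def test_opposite_responses_cancel_to_flat_assemblage_curve():
    """Two species with exactly opposite swept-variable responses and a
    symmetric point of departure: richness gains in one mirror losses in the
    other, so the stacked curve stays flat (the conductivity-like case)."""
    ds = _tiny_dataset({"s1": [0.0, 1.0, -1.0]}, {"up": [1, 1, 1], "down": [1, 1, 1]})
    up = make_flat_sdm("up", ("s1",), intercept=0.0, linear={"s1": 1.3})
    down = make_flat_sdm("down", ("s1",), intercept=0.0, linear={"s1": -1.3})
    curve = site_response(
        ds, "s0", "s1", [up, down], _identity_screen(["s1"]), RunConfig(sweep_points=41)
    )
    # at the departure point (s1=0) both sit at 0.5; expit(x)+expit(-x)=1
    assert np.allclose(curve.rsr, 1.0, atol=1e-12)


def test_single_monotone_species_matches_closed_form():
    ds = _tiny_dataset({"s1": [0.2, 1.0, -1.0]}, {"spA": [1, 1, 1]})
    b0, b1 = 0.3, 1.7
    sdm = make_flat_sdm("spA", ("s1",), intercept=b0, linear={"s1": b1})
    curve = site_response(ds, "s0", "s1", [sdm], _identity_screen(["s1"]), RunConfig(sweep_points=11))
    for g in (curve.grid[0], curve.grid[4], curve.grid[-1]):
        expected = expit(b0 + b1 * g) / expit(b0 + b1 * 0.2)
        assert curve.rsr_at(g) == pytest.approx(expected, abs=1e-12)


def test_all_species_mode_stacks_absent_species_too():
    ds = _tiny_dataset({"s1": [0.0, 0.5, 1.0]}, {"here": [1, 0, 1], "gone": [0, 1, 1]})
    sdms = [make_flat_sdm("here", ("s1",)), make_flat_sdm("gone", ("s1",), linear={"s1": 1.0})]
    cfg = RunConfig(sweep_points=11)
    default = site_response(ds, "s0", "s1", sdms, _identity_screen(["s1"]), cfg)
    assert default.species_pool == ("here",)
    cfg_all = RunConfig(sweep_points=11, all_species_mode=True)
    everything = site_response(ds, "s0", "s1", sdms, _identity_screen(["s1"]), cfg_all)
    assert everything.species_pool == ("here", "gone")


def test_empty_pool_raises():
    ds = _tiny_dataset({"s1": [0.0, 0.5, 1.0]}, {"spA": [0, 1, 1]})
    with pytest.raises(CurveError, match="no modelled species"):
        site_response(ds, "s0", "s1", [make_flat_sdm("spA", ("s1",))],
                      _identity_screen(["s1"]), RunConfig(sweep_points=11))


# -----------------------------------------------------------------------------
# invariants on a fitted landscape


def test_rsr_is_one_at_every_observed_stressor_value(small_result):
    for site_curves in small_result.curves.values():
        for curve in site_curves.values():
            assert curve.observed_value in curve.grid
            assert abs(curve.rsr_at(curve.observed_value) - 1.0) < 1e-9
            assert np.all(curve.rsr > 0)
            assert np.all(np.diff(curve.grid) > 0)


def test_perturbing_another_site_leaves_a_curve_unchanged(small_landscape, small_config, small_result):
    ds = small_landscape.dataset
    stressor = next(iter(small_result.curves))
    ref_site = next(iter(small_result.curves[stressor]))
    baseline = small_result.curves[stressor][ref_site]

    env2 = ds.env.copy()
    other = next(s for s in ds.site_ids if s not in ds.reference_ids)
    env2.loc[other] = env2.loc[other] * 3.0 + 1.0
    ds2 = SurveyDataset(env=env2, occ=ds.occ.copy(), reference_ids=list(ds.reference_ids),
                        variable_roles=dict(ds.variable_roles), coords=None)
    again = site_response(
        ds2, ref_site, stressor, small_result.sdms, small_result.screened,
        small_config, grid=baseline.grid,
    )
    assert np.array_equal(baseline.rsr, again.rsr)


def test_removing_a_species_lowers_expected_richness_pointwise(small_landscape, small_config, small_result):
    stressor = next(iter(small_result.curves))
    ref_site, full_curve = next(iter(small_result.curves[stressor].items()))
    pool_sdms = [s for s in small_result.sdms if s.species in full_curve.species_pool]
    assert len(pool_sdms) >= 2
    reduced = site_response(
        small_landscape.dataset, ref_site, stressor, pool_sdms[:-1],
        small_result.screened, small_config, grid=full_curve.grid,
    )
    full_richness = full_curve.rsr * full_curve.richness_at_reference
    reduced_richness = reduced.rsr * reduced.richness_at_reference
    assert np.all(reduced_richness < full_richness)


def test_native_and_standardized_sweeps_agree(small_landscape, small_result, small_config):
    """Standardizing a native-unit grid and pushing it through the model
    equals the curve computed by the pipeline's native sweep."""
    from evdkit.sdm import predict_matrix

    stressor = next(iter(small_result.curves))
    site, curve = next(iter(small_result.curves[stressor].items()))
    screened = small_result.screened
    predictors = small_result.sdms[0].predictors
    j = list(predictors).index(stressor)
    z_row = np.array([
        screened.standardize_values(v, float(small_landscape.dataset.env.loc[site, v]))
        for v in predictors
    ])
    Z = np.tile(z_row, (len(curve.grid), 1))
    Z[:, j] = screened.standardize_values(stressor, curve.grid)
    richness = np.zeros(len(curve.grid))
    for s in small_result.sdms:
        if s.species in curve.species_pool:
            richness += predict_matrix(s, Z)
    assert np.allclose(richness / curve.richness_at_reference, curve.rsr, atol=1e-12)
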