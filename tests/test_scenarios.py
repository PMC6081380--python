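import numpy as np
import pytest
from dataclasses import replace
from scipy import stats

from landmit.grid import BIOMES
from landmit.scenarios import (
    PROFILES,
    InfeasibleLandUseError,
    generate_ensemble,
    generate_initial_carbon,
    generate_landuse_scenario,
    generate_temperature_profile,
)
from landmit.vegetation import BIOME


# ---------------------------------------------------------------------------
# land use


@pytest.mark.parametrize(
    "preset,peak,peak_year,end",
    [("im19_like", 550.0, 2060, 430.0), ("im26_like", 325.0, 2085, 310.0)],
)
def test_preset_global_bioenergy_trajectory(small_grid, preset, peak, peak_year, end):
    """Global bioenergy area follows the scenario shape: rise to the peak
    year, then decline, matching the preset within 1 % at every year."""
    traj = generate_landuse_scenario(small_grid, preset)
    area = traj.global_area("bioenergy")
    assert area.max() == pytest.approx(peak, rel=1e-2)
    assert traj.years[area.argmax()] == peak_year
    assert area[-1] == pytest.approx(end, rel=1e-2)
    assert area[traj.years <= 2030].max() == 0.0

    from landmit.scenarios import bioenergy_area_curve, load_profile

    target = bioenergy_area_curve(traj.years, load_profile(preset))
    mask = target > 1.0
    assert np.all(np.abs(area[mask] - target[mask]) / target[mask] < 0.01)


def test_zero_peak_area_gives_no_bioenergy(small_grid):
    prof = replace(PROFILES["im19_like"], peak_area_mha=0.0, end_area_mha=0.0)
    traj = generate_landuse_scenario(small_grid, prof)
    assert np.all(traj.frac_bioenergy == 0.0)


def test_fraction_closure_everywhere(small_grid):
    traj = generate_landuse_scenario(small_grid, "im19_like")
    total = traj.frac_food_crop + traj.frac_pasture + traj.frac_bioenergy
    assert total.max() <= 1 + 1e-9
    for a in (traj.frac_food_crop, traj.frac_pasture, traj.frac_bioenergy):
        assert a.min() >= -1e-12


def test_landuse_seed_determinism(small_grid):
    a = generate_landuse_scenario(small_grid, "im26_like")
    b = generate_landuse_scenario(small_grid, "im26_like")
    assert np.array_equal(a.frac_bioenergy, b.frac_bioenergy)
    assert np.array_equal(a.frac_food_crop, b.frac_food_crop)


def test_expansion_prefers_weighted_latitudes(small_grid):
    """The ambitious preset weights mid/high latitudes: the area-weighted
    mean |latitude| of converted cells sits poleward of 35 degrees."""
    traj = generate_landuse_scenario(small_grid, "im19_like")
    peak = traj.frac_bioenergy[traj.years == 2060][0]
    w = peak * small_grid.area
    mean_lat = np.abs(small_grid.lat_center) @ w / w.sum()
    assert mean_lat > 35


def test_infeasible_peak_area_raises(small_grid):
    prof = replace(PROFILES["im19_like"], peak_area_mha=1e6, end_area_mha=1e5)
    with pytest.raises(InfeasibleLandUseError):
        generate_landuse_scenario(small_grid, prof)


def test_abandonment_is_lifo(small_grid):
    """Cells converted last are abandoned first: any cell still under
    bioenergy in 2100 was already converted at the peak."""
    traj = generate_landuse_scenario(small_grid, "im19_like")
    at_peak = traj.frac_bioenergy[traj.years == 2060][0]
    at_end = traj.frac_bioenergy[-1]
    assert np.all(at_end <= at_peak + 1e-12)


def test_netcdf_roundtrip(tmp_path, small_grid):
    import xarray as xr

    traj = generate_landuse_scenario(small_grid, "im26_like")
    path = tmp_path / "lu.nc"
    traj.to_netcdf(path)
    ds = xr.open_dataset(path)
    assert ds.attrs["preset"] == "im26_like"
    total = ds["frac_bioenergy"].isel(time=-1).values
    back = total[small_grid.land_index[:, 0], small_grid.land_index[:, 1]]
    np.testing.assert_allclose(back, traj.frac_bioenergy[-1], atol=1e-6)


# ---------------------------------------------------------------------------
# temperature


@pytest.mark.parametrize("target,lo", [(1.5, 1.45), (2.0, 1.95)])
def test_temperature_profile_reaches_target(target, lo):
    prof = generate_temperature_profile(target)
    assert lo <= prof.dT_global[-1] <= target
    assert np.all(np.diff(prof.dT_global) >= -1e-15)


def test_temperature_near_flat_limit():
    prof = generate_temperature_profile(0.9 + 1e-6, start_dT=0.9)
    assert np.ptp(prof.dT_global) < 1e-6


def test_temperature_profile_deterministic():
    a = generate_temperature_profile(1.5)
    b = generate_temperature_profile(1.5)
    assert np.array_equal(a.dT_global, b.dT_global)


def test_temperature_target_below_start_raises():
    with pytest.raises(ValueError):
        generate_temperature_profile(0.5, start_dT=0.9)


# ---------------------------------------------------------------------------
# ensemble


def test_ensemble_patterns_normalized(small_grid):
    members = generate_ensemble(34, small_grid, seed=4)
    assert len(members) == 34
    w = small_grid.area / small_grid.area.sum()
    for m in members:
        assert m.pattern_T @ w == pytest.approx(1.0, abs=1e-6)
        assert m.lambda_clim > 0


def test_ensemble_seed_behaviour(small_grid):
    one = generate_ensemble(1, small_grid, seed=0)
    assert len(one) == 1
    a = generate_ensemble(5, small_grid, seed=1)
    b = generate_ensemble(5, small_grid, seed=1)
    c = generate_ensemble(5, small_grid, seed=2)
    assert [m.lambda_clim for m in a] == [m.lambda_clim for m in b]
    assert [m.lambda_clim for m in a] != [m.lambda_clim for m in c]


def test_ensemble_lambda_distribution_matches_configured_range(small_grid):
    """Oracle: direct sampling.  The feedback-parameter draws follow the
    configured uniform distribution (Kolmogorov-Smirnov at n = 400)."""
    members = generate_ensemble(400, small_grid, seed=11)
    lam = np.array([m.lambda_clim for m in members])
    assert lam.min() >= 0.7 and lam.max() <= 1.6
    res = stats.kstest(lam, stats.uniform(loc=0.7, scale=0.9).cdf)
    assert res.pvalue > 0.01


def test_ensemble_invalid_size(small_grid):
    with pytest.raises(ValueError):
        generate_ensemble(0, small_grid)


# ---------------------------------------------------------------------------
# initial carbon


def test_initial_carbon_biome_means(small_grid, small_biomes):
    """Per-biome mean vegetation carbon within 20 % of the biome table
    (e.g. tropical forest near 10, desert near 0.3 kgC m-2), cell values
    inside the 10th-90th percentile envelopes."""
    field = generate_initial_carbon(small_grid, small_biomes, seed=5)
    dens = field.total_cveg
    for b, name in enumerate(BIOMES):
        m = small_biomes == b
        if m.sum() < 3:
            continue
        target = BIOME["cveg_mean"][b]
        assert abs(dens[m].mean() - target) / target < 0.20, name
        assert dens[m].min() >= BIOME["cveg_p10"][b] - 1e-9
        assert dens[m].max() <= BIOME["cveg_p90"][b] + 1e-9


def test_initial_soil_turnover_tracks_biome_table(small_grid, small_biomes):
    field = generate_initial_carbon(small_grid, small_biomes, seed=5)
    npp0 = (field.nu * BIOME["npp_rate"][small_biomes]).sum(axis=1)
    turnover = field.total_csoil / npp0
    for b in np.unique(small_biomes):
        m = small_biomes == b
        if m.sum() < 3:
            continue
        target = BIOME["soil_turnover"][b]
        assert abs(turnover[m].mean() - target) / target < 0.20


def test_initial_carbon_empty_and_invalid():
    import landmit.grid as gridmod

    g = gridmod.make_grid(n_lat=8, n_lon=8)
    empty = generate_initial_carbon(g, np.array([], dtype=int))
    assert empty.c_veg.shape[0] == 0
    with pytest.raises(ValueError):
        generate_initial_carbon(g, np.array([99]))
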