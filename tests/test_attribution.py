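import numpy as np
import pytest

from landmit import attribution as att
from landmit.pipeline import run_single
from landmit.scenarios import LandUseTrajectory


class _StubRun:
    """Just enough of a run for the decomposition arithmetic."""

    def __init__(self, d):
        self.total_land_carbon = np.array([0.0, float(d)])

    def delta(self, series):
        return float(series[-1] - series[0])


def _toy_traj(grid, food, bio, pasture=None):
    n = grid.n_land
    years = np.arange(2000, 2000 + len(food))
    z = np.zeros((len(food), n))
    f, b, p = z.copy(), z.copy(), z.copy()
    f[:, 0] = food
    b[:, 0] = bio
    if pasture is not None:
        p[:, 0] = pasture
    return LandUseTrajectory(
        years=years, frac_food_crop=f, frac_pasture=p, frac_bioenergy=b, grid=grid
    )


# ---------------------------------------------------------------------------
# ledger


def test_equal_split_between_expanding_classes(small_grid):
    """crop +0.1 and bioenergy +0.1 with dC = -2 splits -1 / -1."""
    traj = _toy_traj(small_grid, food=[0.2, 0.3], bio=[0.0, 0.1])
    dC = np.zeros((1, small_grid.n_land))
    dC[0, 0] = -2.0
    led = att.categorize_luc(traj, dC)
    assert led.dC[0, 0, 0] == pytest.approx(-1.0)  # food
    assert led.dC[0, 0, 1] == pytest.approx(-1.0)  # beccs


def test_decrease_attributed_to_reforestation(small_grid):
    traj = _toy_traj(small_grid, food=[0.4, 0.2], bio=[0.0, 0.0])
    dC = np.zeros((1, small_grid.n_land))
    dC[0, 0] = 0.5
    led = att.categorize_luc(traj, dC)
    assert led.dC[0, 0, 2] == pytest.approx(0.5)


def test_hand_computed_toy_ledger(small_grid):
    """Three-year toy cell with a category switch: expansion year splits
    50/50 between food and bioenergy, the later contraction switches the
    standing category to reforestation, and subsequent years accumulate
    there.  Totals frozen from a hand-computed ledger."""
    traj = _toy_traj(
        small_grid, food=[0.2, 0.3, 0.2, 0.2], bio=[0.0, 0.1, 0.1, 0.1]
    )
    dC = np.zeros((3, small_grid.n_land))
    dC[:, 0] = [-2.0, 0.5, 0.2]
    led = att.categorize_luc(traj, dC)
    np.testing.assert_allclose(led.dC[0, 0], [-1.0, -1.0, 0.0])
    np.testing.assert_allclose(led.dC[1, 0], [0.0, 0.0, 0.5])
    np.testing.assert_allclose(led.dC[2, 0], [0.0, 0.0, 0.2])
    np.testing.assert_allclose(led.totals_per_cell()[0], [-1.0, -1.0, 0.7])


def test_ledger_completeness_on_real_run(ctx_small):
    """On every cell-year with a standing category the categorized changes
    sum to the cell's total stock change, to 1e-10."""
    r = run_single(ctx_small, "1.5C_IM19", ctx_small.members[0])
    traj = ctx_small.trajectories["im19_like"]
    dC = att.annual_stock_change(r)
    led = att.categorize_luc(traj, dC)
    categorized = led.dC.sum(axis=2)
    np.testing.assert_allclose(
        categorized[led.active], dC[led.active], atol=1e-10
    )
    assert np.all(categorized[~led.active] == 0.0)


# ---------------------------------------------------------------------------
# decomposition


def test_identical_runs_give_zero_effects():
    runs = {e: _StubRun(5.0) for e in att.REQUIRED_EXPERIMENTS}
    eff = att.compute_effects(runs)
    assert eff.net == 0.0 and eff.components_sum() == 0.0


def test_additive_fixture_recovers_injected_effects():
    """Synthetic runs built from independent additive effects: each
    component recovers its injected value and the residual vanishes."""
    base, climate, co2, luc = 10.0, -7.0, 25.0, -4.0
    runs = {
        "1.5C_IM19": _StubRun(base + luc),
        "1.5C_IM26": _StubRun(base),
        "2C_IM19": _StubRun(base + climate + co2 + luc),
        "2C_IM26": _StubRun(base + climate + co2),
        "2C_IM26_1.5CO2": _StubRun(base + climate),
    }
    eff = att.compute_effects(runs)
    assert eff.co2_effect == pytest.approx(-co2, abs=1e-10)
    assert eff.climate_effect == pytest.approx(-climate, abs=1e-10)
    assert eff.luc_beccs == pytest.approx(luc, abs=1e-10)
    assert eff.residual == pytest.approx(0.0, abs=1e-10)
    assert eff.net == pytest.approx(luc - climate - co2, abs=1e-10)


def test_missing_run_named_in_error():
    runs = {e: _StubRun(1.0) for e in att.REQUIRED_EXPERIMENTS if e != "2C_IM26"}
    with pytest.raises(ValueError, match="2C_IM26"):
        att.compute_effects(runs)


def test_decomposition_closure_on_real_runs(ctx_small):
    runs = {e: run_single(ctx_small, e, ctx_small.members[0])
            for e in att.REQUIRED_EXPERIMENTS}
    ledgers = {
        e: att.categorize_luc(
            ctx_small.trajectories[r.landuse_preset], att.annual_stock_change(r)
        )
        for e, r in runs.items()
    }
    eff = att.compute_effects(runs, ledgers)
    assert eff.components_sum() == pytest.approx(eff.net, abs=1e-9)


# ---------------------------------------------------------------------------
# payback


class _StubCells:
    def __init__(self, years, beccs_cell):
        self.years = years
        self.beccs_cell = beccs_cell


def _payback_setup(grid, dC0, flux_per_year):
    n = grid.n_land
    years = np.arange(2000, 2011)
    bio = np.zeros(11)
    bio[2:] = 0.5
    traj = _toy_traj(grid, food=np.zeros(11), bio=bio)
    dC = np.zeros((10, n))
    dC[1, 0] = dC0  # conversion-year change
    led = att.categorize_luc(traj, dC)
    beccs = np.zeros((11, n))
    beccs[:, 0] = flux_per_year * np.maximum(0, np.arange(11) - 2)
    return led, _StubCells(years, beccs), traj


def test_payback_division(small_grid):
    """Deficit 10 kgC m-2 repaid at 0.1 kgC m-2 yr-1 takes 100 years."""
    led, run, traj = _payback_setup(small_grid, -10.0, 0.1)
    pb = att.payback_time(led, run, traj)
    assert pb.recovery_years[0] == pytest.approx(100.0)


def test_payback_zero_when_no_deficit(small_grid):
    led, run, traj = _payback_setup(small_grid, +3.0, 0.1)
    pb = att.payback_time(led, run, traj)
    assert pb.recovery_years[0] == 0.0
    assert pb.mean_flux[0] == pytest.approx(0.1)


def test_payback_infinite_without_flux(small_grid):
    led, run, traj = _payback_setup(small_grid, -5.0, 0.0)
    pb = att.payback_time(led, run, traj)
    assert np.isinf(pb.recovery_years[0])


def test_payback_masked_without_bioenergy(small_grid):
    led, run, traj = _payback_setup(small_grid, -5.0, 0.1)
    pb = att.payback_time(led, run, traj)
    assert not pb.has_bioenergy[1]
    assert np.isnan(pb.recovery_years[1])


def test_payback_consistency(small_grid):
    """recovery * mean flux covers the deficit at reported precision."""
    led, run, traj = _payback_setup(small_grid, -7.3, 0.04)
    pb = att.payback_time(led, run, traj)
    c = 0
    assert pb.recovery_years[c] * pb.mean_flux[c] >= pb.deficit[c] - 1e-9


# ---------------------------------------------------------------------------
# forest vs BECCS


def test_winning_fraction_monotone_in_multiplier(ctx_small):
    m = ctx_small.members[0]
    r_bio = run_single(ctx_small, "1.5C_IM19", m)
    r_for = run_single(ctx_small, "1.5C_IM26", m)
    tb = ctx_small.trajectories["im19_like"]
    tf = ctx_small.trajectories["im26_like"]
    lb = att.categorize_luc(tb, att.annual_stock_change(r_bio))
    lf = att.categorize_luc(tf, att.annual_stock_change(r_for))
    comp = att.compare_forest_vs_beccs(
        r_bio, r_for, tb, tf, lb, lf, multipliers=(0.0, 1.0, 1.5, 2.0, 3.0, 50.0)
    )
    assert comp.conflict_cells.any()
    wf = comp.curve["winning_fraction"].to_numpy()
    assert np.all(np.diff(wf) >= -1e-12)


def test_no_conflict_cells_warns(small_grid):
    traj = _toy_traj(small_grid, food=np.zeros(3), bio=np.zeros(3))
    dC = np.zeros((2, small_grid.n_land))
    led = att.categorize_luc(traj, dC)
    years = np.arange(2000, 2003)
    run = _StubCells(years, np.zeros((3, small_grid.n_land)))
    run.grid = small_grid
    run.cveg_cell = np.zeros((3, small_grid.n_land))
    run.csoil_cell = np.zeros((3, small_grid.n_land))
    run.products_cell = np.zeros((3, small_grid.n_land))
    run.tree_frac_cell = np.zeros((3, small_grid.n_land))
    with pytest.warns(UserWarning):
        out = att.compare_forest_vs_beccs(run, run, traj, traj, led, led)
    assert len(out.curve) == 0
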