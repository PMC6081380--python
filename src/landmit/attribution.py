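"""Attribution of land-carbon differences between scenarios.

Three procedures operate on completed runs:

* a per-cell ledger that tags each year's carbon-stock change with the
  land-use-change driver standing in that cell -- conversion *for food*,
  *for bioenergy (BECCS)*, or *abandonment / afforestation-reforestation*
  -- following the categorization-and-accumulate rule: when agricultural
  area increases, the year's change is split across expanding classes in
  proportion to their area increase and subsequent years accumulate under
  that category until a different kind of land-use change occurs; when
  agricultural area decreases, changes are attributed to reforestation;
* a five-way decomposition of the net difference between the ambitious
  (1.5 C, large bioenergy) and moderate (2 C, small bioenergy) worlds into
  CO2-fertilization, climate, and the three land-use drivers, with an
  explicit residual (the decomposition of a nonlinear model is never
  exactly additive, and the residual is reported rather than absorbed);
* payback (recovery) times: the carbon deficit a cell accumulated under
  bioenergy conversion divided by its mean annual flux into the geological
  reservoir, plus the grid-cell-level forest-versus-BECCS comparison with
  a capture-multiplier sweep.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

CATEGORIES = ("food", "beccs", "afforestation_reforestation")
#: Sentinel for cells whose deficit can never be repaid (no capture flux).
INFINITE_RECOVERY = np.inf


@dataclass
class AttributionLedger:
    """Per-cell, per-year carbon changes tagged by land-use driver.

    ``dC`` has shape (n_years - 1, n_land, 3) in kgC m-2 (columns follow
    :data:`CATEGORIES`); ``years`` are the years each annual change ends
    in.  Cells that never saw land-use change carry no category and stay
    zero.
    """

    years: np.ndarray
    dC: np.ndarray
    active: np.ndarray  # (n_years - 1, n_land) bool

    def totals_per_cell(self) -> np.ndarray:
        """(n_land, 3) accumulated change per category, kgC m-2."""
        return self.dC.sum(axis=0)

    def totals_gtc(self, grid) -> dict[str, float]:
        from .pipeline import KG_M2_MHA_TO_GTC

        w = grid.area * KG_M2_MHA_TO_GTC
        per = self.totals_per_cell()
        return {c: float(per[:, i] @ w) for i, c in enumerate(CATEGORIES)}


def categorize_luc(traj, dC_cell: np.ndarray, tol: float = 1e-9) -> AttributionLedger:
    """Build the attribution ledger for one run.

    ``dC_cell`` is the annual change in vegetation + soil carbon per cell,
    shape (n_years - 1, n_land), aligned with ``traj.years[1:]``.
    """
    n_years, n = traj.frac_bioenergy.shape
    if dC_cell.shape != (n_years - 1, n):
        raise ValueError("dC_cell must hold annual changes per cell")
    weights = np.zeros((n, 3))  # standing category weights per cell
    out = np.zeros((n_years - 1, n, 3))
    active_hist = np.zeros((n_years - 1, n), dtype=bool)
    food_area = traj.frac_food_crop + traj.frac_pasture
    for t in range(1, n_years):
        d_food = food_area[t] - food_area[t - 1]
        d_bio = traj.frac_bioenergy[t] - traj.frac_bioenergy[t - 1]
        d_agri = d_food + d_bio

        expanding = d_agri > tol
        if np.any(expanding):
            inc_food = np.maximum(d_food, 0.0)
            inc_bio = np.maximum(d_bio, 0.0)
            s = inc_food + inc_bio
            w_new = np.zeros((n, 3))
            with np.errstate(invalid="ignore", divide="ignore"):
                w_new[:, 0] = np.where(s > 0, inc_food / np.maximum(s, 1e-30), 0.0)
                w_new[:, 1] = np.where(s > 0, inc_bio / np.maximum(s, 1e-30), 0.0)
            weights[expanding] = w_new[expanding]
        contracting = d_agri < -tol
        if np.any(contracting):
            weights[contracting] = np.array([0.0, 0.0, 1.0])

        active = weights.sum(axis=1) > 0
        active_hist[t - 1] = active
        out[t - 1] = dC_cell[t - 1][:, None] * weights
    return AttributionLedger(years=traj.years[1:], dC=out, active=active_hist)


def annual_stock_change(run) -> np.ndarray:
    """Annual change in C_veg + C_soil per cell, (n_years - 1, n_land)."""
    stocks = run.cveg_cell + run.csoil_cell
    return np.diff(stocks, axis=0)


# ---------------------------------------------------------------------------
# Five-way decomposition


@dataclass
class EffectDecomposition:
    """Net difference in total land carbon (GtC, positive = more carbon
    in the ambitious scenario) and its drivers; components + residual sum
    to the net exactly."""

    net: float
    co2_effect: float
    climate_effect: float
    luc_food: float
    luc_beccs: float
    luc_afforest: float
    residual: float

    def components_sum(self) -> float:
        return (
            self.co2_effect
            + self.climate_effect
            + self.luc_food
            + self.luc_beccs
            + self.luc_afforest
            + self.residual
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": [
                    "net",
                    "co2_fertilization",
                    "climate",
                    "luc_food",
                    "luc_beccs",
                    "luc_afforestation_reforestation",
                    "residual",
                ],
                "gtc": [
                    self.net,
                    self.co2_effect,
                    self.climate_effect,
                    self.luc_food,
                    self.luc_beccs,
                    self.luc_afforest,
                    self.residual,
                ],
            }
        )


REQUIRED_EXPERIMENTS = (
    "1.5C_IM19",
    "1.5C_IM26",
    "2C_IM19",
    "2C_IM26",
    "2C_IM26_1.5CO2",
)


def compute_effects(
    runs: dict, ledgers: dict | None = None, trajectories: dict | None = None
) -> EffectDecomposition:
    """Decompose the net difference between the ambitious and moderate
    scenarios over the century.

    ``runs`` maps experiment ids to single runs (one ensemble member).
    The CO2 effect comes from the pair that differs only in the CO2 path;
    the climate effect from the same-land-use warming pair after removing
    the CO2 estimate; the land-use effect from the same-climate pair,
    split across drivers by the attribution ledgers when given.  The
    residual absorbs interaction terms and is reported, never rescaled.
    """
    for exp in REQUIRED_EXPERIMENTS:
        if exp not in runs:
            raise ValueError(f"missing required experiment run: {exp!r}")
    d = {k: r.delta(r.total_land_carbon) for k, r in runs.items()}
    net = d["1.5C_IM19"] - d["2C_IM26"]
    co2_effect = d["2C_IM26_1.5CO2"] - d["2C_IM26"]
    climate_effect = (d["1.5C_IM19"] - d["2C_IM19"]) - co2_effect
    luc_total = d["1.5C_IM19"] - d["1.5C_IM26"]

    if ledgers is not None:
        a = ledgers["1.5C_IM19"].totals_gtc(runs["1.5C_IM19"].grid)
        b = ledgers["1.5C_IM26"].totals_gtc(runs["1.5C_IM26"].grid)
        luc_food = a["food"] - b["food"]
        luc_beccs = (
            a["beccs"]
            - b["beccs"]
            + float(runs["1.5C_IM19"].beccs_cum[-1] - runs["1.5C_IM26"].beccs_cum[-1])
        )
        luc_afforest = (
            a["afforestation_reforestation"] - b["afforestation_reforestation"]
        )
    else:
        luc_food, luc_afforest = 0.0, 0.0
        luc_beccs = luc_total
    residual = net - (co2_effect + climate_effect + luc_food + luc_beccs + luc_afforest)
    return EffectDecomposition(
        net=net,
        co2_effect=co2_effect,
        climate_effect=climate_effect,
        luc_food=luc_food,
        luc_beccs=luc_beccs,
        luc_afforest=luc_afforest,
        residual=residual,
    )


# ---------------------------------------------------------------------------
# Payback times


@dataclass
class PaybackMap:
    """Per-cell recovery time (years) for cells that ever grew bioenergy
    crops; NaN where undefined, inf where the deficit can never be repaid.
    Where recovery is zero, ``mean_flux`` carries the mean annual capture
    flux instead (the quantity mapped in blue in the source analysis)."""

    recovery_years: np.ndarray
    mean_flux: np.ndarray  # kgC m-2 yr-1
    deficit: np.ndarray  # kgC m-2, positive = carbon lost to bioenergy LUC
    has_bioenergy: np.ndarray


def payback_time(
    ledger: AttributionLedger, run, traj, tol: float = 1e-9
) -> PaybackMap:
    """Carbon deficit attributed to bioenergy conversion divided by the
    mean annual flux into the geological reservoir, per cell, evaluated
    from the first year bioenergy crops appear until they are removed or
    the simulation ends."""
    n_years, n = traj.frac_bioenergy.shape
    bio = traj.frac_bioenergy > tol
    has_bio = bio.any(axis=0)
    recovery = np.full(n, np.nan)
    flux = np.full(n, np.nan)
    deficit = np.full(n, np.nan)
    first = np.argmax(bio, axis=0)
    for cell in np.flatnonzero(has_bio):
        f = first[cell]
        later = np.flatnonzero(~bio[f:, cell])
        end = f + later[0] if len(later) else n_years - 1
        if end <= f:
            continue
        # ledger row t covers the change during years[t+1]; the window
        # starts with the conversion-year change, row f-1
        dfc = -ledger.dC[max(f - 1, 0) : end, cell, 1].sum()
        deficit[cell] = dfc
        mean_flux = (run.beccs_cell[end, cell] - run.beccs_cell[f, cell]) / (
            run.years[end] - run.years[f]
        )
        flux[cell] = mean_flux
        if dfc <= 0:
            recovery[cell] = 0.0
        elif mean_flux <= 0:
            recovery[cell] = INFINITE_RECOVERY
        else:
            recovery[cell] = dfc / mean_flux
    return PaybackMap(
        recovery_years=recovery, mean_flux=flux, deficit=deficit, has_bioenergy=has_bio
    )


# ---------------------------------------------------------------------------
# Forest vs BECCS


@dataclass
class ForestBeccsComparison:
    conflict_cells: np.ndarray  # bool (n_land,)
    diff_default: np.ndarray  # kgC m-2 at multiplier 1, NaN off-conflict
    curve: pd.DataFrame  # multiplier -> winning fraction


def compare_forest_vs_beccs(
    run_bio,
    run_forest,
    traj_bio,
    traj_forest,
    ledger_bio: AttributionLedger,
    ledger_forest: AttributionLedger,
    multipliers=(1.0, 1.5, 2.0, 3.0),
    frac_threshold: float = 0.05,
    tree_threshold: float = 0.1,
) -> ForestBeccsComparison:
    """Difference in century carbon storage on cells where one scenario
    grows bioenergy crops while the other keeps or grows forest.

    Positive differences mean BECCS out-stored the forest.  Changes
    attributed to food production are excluded through the ledgers; the
    bioenergy run's captured carbon is scaled by each capture multiplier
    (capture is linear in the multiplier, so no re-run is needed).
    """
    if run_bio.grid is not run_forest.grid and run_bio.grid.n_land != run_forest.grid.n_land:
        raise ValueError("runs must share a grid")
    bio_max = traj_bio.frac_bioenergy.max(axis=0)
    bio_other = traj_forest.frac_bioenergy.max(axis=0)
    tree_forest = run_forest.tree_frac_cell[-1]
    conflict = (
        (bio_max > frac_threshold)
        & (tree_forest > tree_threshold)
        & (bio_max - bio_other > frac_threshold)
    )
    if not np.any(conflict):
        warnings.warn("no conflict cells between the two scenarios")
        return ForestBeccsComparison(
            conflict_cells=conflict,
            diff_default=np.full(run_bio.grid.n_land, np.nan),
            curve=pd.DataFrame({"multiplier": [], "winning_fraction": []}),
        )

    def century_change(run, ledger):
        stocks = run.cveg_cell + run.csoil_cell + run.products_cell
        return (stocks[-1] - stocks[0]) - ledger.totals_per_cell()[:, 0]

    base_bio = century_change(run_bio, ledger_bio)
    base_forest = century_change(run_forest, ledger_forest)
    capture = run_bio.beccs_cell[-1] - run_bio.beccs_cell[0]
    capture_forest = run_forest.beccs_cell[-1] - run_forest.beccs_cell[0]

    rows = []
    diff_default = np.full(run_bio.grid.n_land, np.nan)
    for m in multipliers:
        diff = (base_bio + m * capture) - (base_forest + m * capture_forest)
        if np.isclose(m, 1.0):
            diff_default[conflict] = diff[conflict]
        rows.append(
            {
                "multiplier": m,
                "winning_fraction": float(np.mean(diff[conflict] > 0)),
            }
        )
    return ForestBeccsComparison(
        conflict_cells=conflict,
        diff_default=diff_default,
        curve=pd.DataFrame(rows),
    )
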