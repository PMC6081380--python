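"""Scenario simulator and experiment orchestration.

One :class:`ScenarioRun` integrates a land-use trajectory, a warming
profile and one ensemble member's CO2 path through the reduced vegetation
/ soil / product-pool / BECCS bookkeeping at an annual step, recording
global and per-cell carbon stocks.  The experiment matrix mirrors the
study design: two land-use scenarios crossed with two warming targets,
plus a variant that takes the 2 C warming with the CO2 path of the 1.5 C
profile to isolate CO2 fertilization.

Carbon is conserved exactly: at every step the change in total stored
carbon (vegetation + soil + products + geological storage) equals
accumulated NPP minus accumulated heterotrophic respiration and
product-pool decay.  Every completed run asserts this to 1e-8 relative.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import bookkeeping, climate, grid as gridmod, scenarios, vegetation as veg
from .beccs import BECCSParams, divert_to_beccs, harvest

#: kg per m2 over one Mha, divided by kg per GtC: converts a per-cell
#: density (kgC m-2) dotted with areas (Mha) into GtC.
KG_M2_MHA_TO_GTC = 1e10 / 1e12

#: The five-experiment matrix: id -> (land-use preset, warming target,
#: warming target whose CO2 path is used).
EXPERIMENTS = {
    "1.5C_IM19": ("im19_like", 1.5, 1.5),
    "1.5C_IM26": ("im26_like", 1.5, 1.5),
    "2C_IM19": ("im19_like", 2.0, 2.0),
    "2C_IM26": ("im26_like", 2.0, 2.0),
    "2C_IM26_1.5CO2": ("im26_like", 2.0, 1.5),
}

CROP_PFTS = np.array([5, 7])  # crop_food, crop_bioenergy (harvested)


@dataclass(frozen=True)
class SimConfig:
    """Everything tunable in one place (YAML-overridable via the CLI)."""

    veg: veg.VegParams = veg.VegParams()
    beccs: BECCSParams = BECCSParams()
    ebm: climate.EBMParams = climate.EBMParams()
    ocean: climate.OceanCarbonParams = climate.OceanCarbonParams()
    q10: float = 2.0
    medium_share: float = 0.30
    slow_share: float = 0.10
    initial_biomass_to_beccs: bool = False
    conservation_rtol: float = 1e-8


@dataclass(frozen=True)
class ExperimentSpec:
    experiment_id: str
    landuse: str
    temp_target: float
    co2_source_target: float
    n_members: int = 8
    seed: int = 0


@dataclass
class ScenarioRun:
    """A completed simulation for one (experiment, ensemble member)."""

    experiment_id: str
    landuse_preset: str
    temp_target: float
    member_id: int
    years: np.ndarray
    grid: gridmod.GridDefinition
    biome_ids: np.ndarray
    # global series, GtC
    c_veg: np.ndarray
    c_soil: np.ndarray
    c_products: np.ndarray
    beccs_cum: np.ndarray
    cum_npp: np.ndarray
    cum_rh: np.ndarray
    cum_product_flux: np.ndarray
    cum_grazing: np.ndarray
    co2: np.ndarray
    dT_global: np.ndarray
    allowable_emissions: np.ndarray
    # per-cell series, kgC m-2 (cell area), shape (n_years, n_land)
    cveg_cell: np.ndarray
    csoil_cell: np.ndarray
    products_cell: np.ndarray
    beccs_cell: np.ndarray
    tree_frac_cell: np.ndarray
    cleared_bio_above_cell: np.ndarray  # cumulative aboveground carbon
    # cleared on conversions to bioenergy (for the accounting variant)
    conservation_residual: float = 0.0

    @property
    def total_land_carbon(self) -> np.ndarray:
        """C_veg + C_soil + products + geological storage, GtC."""
        return self.c_veg + self.c_soil + self.c_products + self.beccs_cum

    def delta(self, series: str) -> float:
        a = getattr(self, series) if isinstance(series, str) else series
        return float(a[-1] - a[0])


@dataclass
class StudyContext:
    """Shared inputs for a whole experiment matrix: grid, biomes, land-use
    trajectories, warming profiles, per-member CO2 paths, initial carbon."""

    grid: gridmod.GridDefinition
    biome_ids: np.ndarray
    trajectories: dict
    temp_profiles: dict
    members: list
    co2_paths: dict  # (target, member_id) -> ForcingPath with co2
    init: scenarios.InitialCarbonField
    config: SimConfig
    seed: int

    @classmethod
    def build(
        cls,
        n_lat: int = 36,
        n_lon: int = 48,
        n_members: int = 8,
        seed: int = 0,
        config: SimConfig = SimConfig(),
        presets=("im19_like", "im26_like"),
        targets=(1.5, 2.0),
    ) -> "StudyContext":
        g = gridmod.make_grid(n_lat=n_lat, n_lon=n_lon)
        biome_ids = gridmod.biome_map(g)
        trajectories = {
            name: scenarios.generate_landuse_scenario(
                g, replace(scenarios.PROFILES[name], seed=seed + 11)
            )
            for name in presets
        }
        temp_profiles = {t: scenarios.generate_temperature_profile(t) for t in targets}
        members = scenarios.generate_ensemble(n_members, g, seed=seed + 29)
        co2_paths = {
            (t, m.member_id): climate.member_forcing_and_co2(
                temp_profiles[t], m, config.ebm
            )
            for t in targets
            for m in members
        }
        init = scenarios.generate_initial_carbon(
            g, biome_ids, seed=seed + 47, params=config.veg
        )
        return cls(
            grid=g,
            biome_ids=biome_ids,
            trajectories=trajectories,
            temp_profiles=temp_profiles,
            members=members,
            co2_paths=co2_paths,
            init=init,
            config=config,
            seed=seed,
        )


# ---------------------------------------------------------------------------
# Core integration


def _initial_state(ctx: StudyContext, traj) -> tuple:
    """Vegetation, soil and product state at the scenario start: potential
    vegetation squeezed by year-0 agriculture, soil equilibrated to the
    corresponding litter flux."""
    cfg = ctx.config
    n = ctx.grid.n_land
    agri0 = np.stack(
        [traj.frac_food_crop[0], traj.frac_pasture[0], traj.frac_bioenergy[0]], axis=1
    )
    a_nat = 1.0 - agri0.sum(axis=1)
    mix = veg.BIOME["base_mix"][ctx.biome_ids]
    nu = np.zeros((n, veg.N_PFT))
    nu[:, veg.NATURAL] = mix * a_nat[:, None]
    nu[:, veg.AGRI] = agri0
    c_veg = ctx.init.c_veg.copy()  # biome equilibrium x heterogeneity
    state = veg.PFTState(nu=nu, c_veg=c_veg, nu_prev=nu.copy(), c_veg_prev=c_veg.copy())

    # soil at the discrete equilibrium of the year-0 litter flux (steady
    # state litter = Pi * nu, minus the harvested share of crop litter)
    pi0 = veg.BIOME["npp_rate"][ctx.biome_ids]
    litter0 = (pi0 * nu).sum(axis=1) - cfg.beccs.eps_harv * (
        pi0[:, CROP_PFTS] * nu[:, CROP_PFTS]
    ).sum(axis=1)
    litter0 -= cfg.veg.graze_frac * cfg.veg.aboveground_fraction * pi0[:, 6] * nu[:, 6]
    pools = veg.soil_equilibrium(
        litter0, ctx.init.turnover_years, q10=cfg.q10, local_dT=0.0
    )
    soil = veg.SoilCarbonState(
        pools=pools, turnover_years=ctx.init.turnover_years, q10=cfg.q10
    )
    products = bookkeeping.ProductPools.zeros(n)
    return state, soil, products


def _apply_transitions(state, soil, products, beccs_cell, d_food, d_past, d_bio, cfg):
    """Vectorized land-conversion bookkeeping for one year.

    Expanding agricultural classes draw area first from shrinking
    agricultural classes (pro rata when several classes expand), then from
    natural vegetation.  Class-to-class swaps between the grass-like
    managed types are reclassifications: the standing carbon moves with
    the area and nothing is emitted.  Cleared natural vegetation and
    abandoned agricultural area shed their standing carbon, split into
    aboveground (wood-product pools, or the geological reservoir for
    bioenergy conversions under the integrated-assessment accounting
    variant) and belowground (fast soil pool) parts.

    Returns the aboveground carbon cleared for bioenergy this year.
    """
    f_ag = cfg.veg.aboveground_fraction
    deltas = np.stack([d_food, d_past, d_bio], axis=1)  # (n, 3) agri classes
    gains = np.maximum(deltas, 0.0)
    losses = np.maximum(-deltas, 0.0)
    g_tot = gains.sum(axis=1)
    l_tot = losses.sum(axis=1)
    nat_cleared = np.maximum(g_tot - l_tot, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        bio_share = np.where(g_tot > 0, gains[:, 2] / np.maximum(g_tot, 1e-30), 0.0)
    bio_nat_area = bio_share * nat_cleared

    nu = state.nu.copy()
    c = state.c_veg.copy()

    # --- natural clearing, proportional across natural PFTs
    nat_nu = nu[:, veg.NATURAL]
    nat_tot = nat_nu.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac_cleared = np.where(
            nat_tot > 0, np.minimum(nat_cleared / np.maximum(nat_tot, 1e-30), 1.0), 0.0
        )
    removed = nat_nu * frac_cleared[:, None] * c[:, veg.NATURAL]  # kgC m-2 per PFT
    nu[:, veg.NATURAL] = nat_nu * (1.0 - frac_cleared[:, None])
    above = removed * f_ag
    below = removed.sum(axis=1) * (1.0 - f_ag)
    woody_above = above[:, veg.WOODY[veg.NATURAL]].sum(axis=1)
    grass_above = above.sum(axis=1) - woody_above

    with np.errstate(invalid="ignore", divide="ignore"):
        to_beccs_frac = np.where(
            nat_cleared > 0, bio_nat_area / np.maximum(nat_cleared, 1e-30), 0.0
        )
    cleared_bio_above = (woody_above + grass_above) * to_beccs_frac
    if cfg.initial_biomass_to_beccs:
        beccs_cell += cleared_bio_above
        woody_above = woody_above * (1 - to_beccs_frac)
        grass_above = grass_above * (1 - to_beccs_frac)

    alloc = np.zeros_like(products.pools)
    fast_share = 1.0 - cfg.medium_share - cfg.slow_share
    alloc[:, 0] = woody_above * fast_share + grass_above
    alloc[:, 1] = woody_above * cfg.medium_share
    alloc[:, 2] = woody_above * cfg.slow_share

    # --- shrinking agricultural classes.  The swapped share of each loss
    # carries its carbon to the expanding classes; only the abandoned
    # share (returning to natural) sheds its grass-like standing carbon,
    # aboveground to the fast pool and roots to the fast soil pool.
    swap_tot = np.minimum(g_tot, l_tot)
    with np.errstate(invalid="ignore", divide="ignore"):
        swap_share = np.where(l_tot > 0, swap_tot / np.maximum(l_tot, 1e-30), 0.0)
    v_transfer = np.zeros(len(g_tot))
    for k, p in enumerate(veg.AGRI):
        shrink = losses[:, k]
        v_out = shrink * c[:, p]
        v_transfer += v_out * swap_share
        rem = v_out * (1.0 - swap_share)
        alloc[:, 0] += rem * f_ag
        below += rem * (1.0 - f_ag)
        nu[:, p] = nu[:, p] - shrink

    # --- expanding agricultural classes: receive swapped area with its
    # carbon (pro rata by gain) plus cleared natural area with none
    for k, p in enumerate(veg.AGRI):
        gain = gains[:, k]
        with np.errstate(invalid="ignore", divide="ignore"):
            v_in = np.where(
                g_tot > 0, gain / np.maximum(g_tot, 1e-30) * v_transfer, 0.0
            )
        v_new = nu[:, p] * c[:, p] + v_in
        nu[:, p] = nu[:, p] + gain
        c[:, p] = np.where(nu[:, p] > 0, v_new / np.maximum(nu[:, p], 1e-30), 0.0)

    products = bookkeeping.ProductPools(
        pools=products.pools + alloc, tau_years=products.tau_years
    )
    soil_pools = soil.pools.copy()
    soil_pools[:, 0] += below
    soil = replace(soil, pools=soil_pools)

    # clearing happens outside the litter balance: reset the reference
    state = veg.PFTState(nu=nu, c_veg=c, nu_prev=nu.copy(), c_veg_prev=c.copy())
    return state, soil, products, beccs_cell, cleared_bio_above


def run_single(
    ctx: StudyContext,
    experiment_id: str,
    member: scenarios.EnsembleMember,
    config: SimConfig | None = None,
) -> ScenarioRun:
    """Integrate one experiment for one ensemble member."""
    if experiment_id not in EXPERIMENTS:
        raise ValueError(
            f"unknown experiment {experiment_id!r}; expected one of "
            f"{sorted(EXPERIMENTS)}"
        )
    cfg = config or ctx.config
    preset, t_clim, t_co2 = EXPERIMENTS[experiment_id]
    traj = ctx.trajectories[preset]
    temp = ctx.temp_profiles[t_clim]
    co2_path = ctx.co2_paths[(t_co2, member.member_id)]
    g = ctx.grid
    years = traj.years
    n_years, n = len(years), g.n_land

    state, soil, products = _initial_state(ctx, traj)
    beccs_cell = np.zeros(n)
    co2_ref = float(co2_path.co2[0])
    dT0 = float(temp.dT_global[0])
    area_w = g.area * KG_M2_MHA_TO_GTC  # dot with kgC m-2 gives GtC

    shape = (n_years, n)
    out = {
        k: np.zeros(shape)
        for k in (
            "cveg_cell",
            "csoil_cell",
            "products_cell",
            "beccs_cell",
            "tree_frac_cell",
            "cleared_bio_above_cell",
        )
    }
    glob = {
        k: np.zeros(n_years)
        for k in ("c_veg", "c_soil", "c_products", "beccs_cum", "cum_npp", "cum_rh",
                  "cum_product_flux", "cum_grazing")
    }

    def record(t):
        out["cveg_cell"][t] = state.total_cveg
        out["csoil_cell"][t] = soil.total
        out["products_cell"][t] = products.total
        out["beccs_cell"][t] = beccs_cell
        out["tree_frac_cell"][t] = state.nu[:, :2].sum(axis=1)
        glob["c_veg"][t] = state.total_cveg @ area_w
        glob["c_soil"][t] = soil.total @ area_w
        glob["c_products"][t] = products.total @ area_w
        glob["beccs_cum"][t] = beccs_cell @ area_w

    record(0)
    cum_npp = cum_rh = cum_pflux = cum_graze = 0.0
    for t in range(1, n_years):
        local_dT = (temp.dT_global[t] - dT0) * member.pattern_T
        co2_t = float(co2_path.co2[t])

        d_food = traj.frac_food_crop[t] - traj.frac_food_crop[t - 1]
        d_past = traj.frac_pasture[t] - traj.frac_pasture[t - 1]
        d_bio = traj.frac_bioenergy[t] - traj.frac_bioenergy[t - 1]
        state, soil, products, beccs_cell, cleared_bio = _apply_transitions(
            state, soil, products, beccs_cell, d_food, d_past, d_bio, cfg
        )
        agri_t = np.stack(
            [traj.frac_food_crop[t], traj.frac_pasture[t], traj.frac_bioenergy[t]],
            axis=1,
        )
        mix = veg.potential_mix(ctx.biome_ids, local_dT, cfg.veg)
        state = veg.step_pft_areas(state, agri_t, mix, dt=1.0, params=cfg.veg)

        npp = veg.npp_model(ctx.biome_ids, co2_t, co2_ref, local_dT, cfg.veg)
        c_eq = veg.equilibrium_density(ctx.biome_ids, co2_t, co2_ref, cfg.veg)
        npp_in = float((npp.Pi * state.nu_prev).sum(axis=1) @ area_w)
        state, lit = veg.step_vegetation(state, npp, c_eq)

        lam_crops = lit.Lambda[:, CROP_PFTS].sum(axis=1)
        h_i = harvest(lam_crops, cfg.beccs)
        nu_bio = traj.frac_bioenergy[t]
        nu_agric = traj.frac_bioenergy[t] + traj.frac_food_crop[t]
        hf = divert_to_beccs(h_i, nu_bio, np.maximum(nu_agric, 1e-12), cfg.beccs)
        beccs_cell = beccs_cell + hf.beccs_flux

        fast = products.pools.copy()
        fast[:, 0] += hf.H
        products = bookkeeping.ProductPools(pools=fast, tau_years=products.tau_years)

        # livestock respire part of the pasture aboveground litter
        grazed = cfg.veg.graze_frac * cfg.veg.aboveground_fraction * lit.Lambda[:, 6]
        litter_soil = lit.Lambda.sum(axis=1) - h_i - grazed
        soil, rh = veg.step_soil(soil, litter_soil, local_dT)
        products, pflux = bookkeeping.decay_products(products)

        cum_npp += npp_in
        cum_rh += float(rh @ area_w)
        cum_pflux += float(pflux @ area_w)
        cum_graze += float(grazed @ area_w)
        record(t)
        out["cleared_bio_above_cell"][t] = (
            out["cleared_bio_above_cell"][t - 1] + cleared_bio
        )
        glob["cum_npp"][t] = cum_npp
        glob["cum_rh"][t] = cum_rh
        glob["cum_product_flux"][t] = cum_pflux
        glob["cum_grazing"][t] = cum_graze

    # --- whole-run conservation
    stocks = glob["c_veg"] + glob["c_soil"] + glob["c_products"] + glob["beccs_cum"]
    residual = (stocks[-1] - stocks[0]) - (cum_npp - cum_rh - cum_pflux - cum_graze)
    scale = max(abs(cum_npp), abs(stocks[0]), 1.0)
    if abs(residual) > cfg.conservation_rtol * scale:
        raise RuntimeError(
            f"carbon conservation violated: residual {residual:.3e} GtC "
            f"(relative {abs(residual) / scale:.3e})"
        )

    land_uptake = np.gradient(stocks)
    budget = climate.diagnose_allowable_emissions(
        years,
        co2_path.co2,
        climate.ocean_uptake(co2_path.co2, cfg.ocean),
        land_uptake,
    )

    return ScenarioRun(
        experiment_id=experiment_id,
        landuse_preset=preset,
        temp_target=t_clim,
        member_id=member.member_id,
        years=years,
        grid=g,
        biome_ids=ctx.biome_ids,
        co2=np.asarray(co2_path.co2),
        dT_global=np.asarray(temp.dT_global),
        allowable_emissions=budget.allowable_emissions,
        conservation_residual=float(residual),
        **glob,
        **out,
    )


def run_experiment(
    ctx: StudyContext, experiment_id: str, config: SimConfig | None = None
) -> list[ScenarioRun]:
    """One ScenarioRun per ensemble member, deterministic under the
    context seed."""
    return [run_single(ctx, experiment_id, m, config) for m in ctx.members]


def run_matrix(ctx: StudyContext, experiments=None) -> dict[str, list[ScenarioRun]]:
    experiments = experiments or list(EXPERIMENTS)
    missing = [e for e in experiments if e not in EXPERIMENTS]
    if missing:
        raise ValueError(f"unknown experiments: {missing}")
    return {e: run_experiment(ctx, e) for e in experiments}


# ---------------------------------------------------------------------------
# Summaries


def summarize(runs_by_experiment: dict[str, list[ScenarioRun]]) -> pd.DataFrame:
    """Ensemble mean and standard deviation of the century changes in each
    carbon store, per experiment (GtC)."""
    rows = []
    for exp_id, runs in runs_by_experiment.items():
        if not runs:
            raise ValueError(f"experiment {exp_id} has no runs")
        deltas = {
            "dC_veg": [r.delta("c_veg") for r in runs],
            "dC_soil": [r.delta("c_soil") for r in runs],
            "beccs_cum": [float(r.beccs_cum[-1]) for r in runs],
            "dC_total": [r.delta(r.total_land_carbon) for r in runs],
        }
        row = {"experiment": exp_id, "n_members": len(runs)}
        for k, v in deltas.items():
            v = np.asarray(v, dtype=float)
            row[f"{k}_mean"] = v.mean()
            row[f"{k}_sd"] = v.std(ddof=0)
        rows.append(row)
    return pd.DataFrame(rows)


def timeseries_frame(runs: list[ScenarioRun]) -> pd.DataFrame:
    """Ensemble-mean global stock time series for one experiment."""
    years = runs[0].years
    stack = lambda attr: np.mean([getattr(r, attr) for r in runs], axis=0)
    return pd.DataFrame(
        {
            "year": years,
            "c_veg": stack("c_veg"),
            "c_soil": stack("c_soil"),
            "c_products": stack("c_products"),
            "beccs_cum": stack("beccs_cum"),
            "total": stack("total_land_carbon"),
        }
    )
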