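"""Reduced per-grid-cell vegetation and soil carbon dynamics.

The scheme keeps the carbon-balance core of a TRIFFID-style dynamic
vegetation model at an annual coupling step, without the biophysics:

* every plant functional type (PFT) carries an areal fraction ``nu`` of the
  grid cell and an area-mean carbon density ``c_veg`` (kgC per m2 of PFT
  area);
* net primary productivity accumulated over the step (``Pi``) either
  thickens the vegetation or leaves it as litter, closing the balance

      Lambda = Pi * nu_prev - (c_veg * nu - c_veg_prev * nu_prev)

  where ``Lambda`` (kgC per m2 of cell area) is the litter flux;
* agricultural PFT areas are prescribed, natural PFT areas relax toward a
  climate-dependent potential mix with per-PFT e-folding times;
* soil carbon sits in four first-order pools whose decay accelerates with
  local warming through a Q10 factor.

Vegetation growth follows an exact exponential relaxation of density
toward a per-PFT equilibrium ``c_eq`` (itself raised by CO2 fertilization),
which guarantees a non-negative litter flux whenever densities start below
equilibrium and is unconditionally stable at the annual step.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .grid import BIOMES

# ---------------------------------------------------------------------------
# PFTs

PFTS = (
    "tree_broadleaf",
    "tree_needleleaf",
    "shrub",
    "c3_grass",
    "c4_grass",
    "crop_food",
    "pasture",
    "crop_bioenergy",
)
N_PFT = len(PFTS)
NATURAL = np.arange(5)  # broadleaf .. c4 grass
AGRI = np.arange(5, 8)  # crop_food, pasture, crop_bioenergy
#: Woody PFTs route cleared biomass through the slow/medium/fast product
#: split; everything else is grass-like (100 % fast).
WOODY = np.array([True, True, True, False, False, False, False, False])

# Relative carbon density of a closed stand, per PFT (dimensionless; trees
# carry an order of magnitude more standing carbon than grasses).  Crop and
# pasture PFTs share the natural-grass parameters.
_REL_DENSITY = np.array([1.0, 0.9, 0.25, 0.08, 0.08, 0.08, 0.08, 0.08])
# Relative productivity per unit PFT area.
_REL_NPP = np.array([1.0, 0.9, 0.6, 0.8, 0.9, 0.9, 0.8, 1.0])

# ---------------------------------------------------------------------------
# Biome parameter table.  ``cveg`` columns are the biome-average vegetation
# carbon (kgC m-2 of cell area) with a 10th-90th percentile envelope
# describing spatial heterogeneity; ``soil_turnover`` is equilibrium
# C_soil / NPP (years); ``npp`` is the biome-mean NPP (kgC m-2 yr-1 of cell
# area) at potential vegetation cover and reference CO2.

BIOME_TABLE = {
    #                 cveg  p10   p90   turnover  npp
    "tropical_forest": (10.0, 1.7, 15.0, 6.0, 1.10),
    "tropical_savanna": (4.4, 0.0, 11.0, 10.0, 0.55),
    "desert": (0.3, 0.0, 0.4, 28.0, 0.07),
    "mediterranean_woodland": (1.5, 0.0, 4.3, 26.0, 0.40),
    "temperate_grassland": (1.4, 0.0, 4.3, 45.0, 0.35),
    "mixed_forest": (3.9, 0.3, 8.3, 24.0, 0.60),
    "boreal_forest": (4.6, 0.3, 7.6, 53.0, 0.35),
    "tundra": (1.5, 0.0, 5.6, 87.0, 0.14),
}

# Potential natural vegetation mix (fraction of the natural area of a cell
# occupied by each of the five natural PFTs; any remainder is bare ground).
_BASE_MIX = {
    "tropical_forest": (0.85, 0.00, 0.05, 0.00, 0.10),
    "tropical_savanna": (0.25, 0.00, 0.15, 0.00, 0.60),
    "desert": (0.00, 0.00, 0.15, 0.10, 0.00),
    "mediterranean_woodland": (0.25, 0.00, 0.40, 0.35, 0.00),
    "temperate_grassland": (0.10, 0.00, 0.10, 0.80, 0.00),
    "mixed_forest": (0.50, 0.20, 0.05, 0.25, 0.00),
    "boreal_forest": (0.00, 0.75, 0.15, 0.10, 0.00),
    "tundra": (0.00, 0.10, 0.35, 0.55, 0.00),
}
# Mix under strong local warming: the tree line advances poleward, so the
# cold biomes gain woody cover at the expense of grasses.
_WARM_MIX = dict(
    _BASE_MIX,
    tundra=(0.00, 0.35, 0.40, 0.25, 0.00),
    boreal_forest=(0.00, 0.85, 0.10, 0.05, 0.00),
)

# Productivity (and standing biomass) of managed crop/pasture PFTs relative
# to the biome's natural vegetation.  Harvested grass crops exploit only a
# short growing season, so they fall well below native evergreen forest in
# the cold biomes; elsewhere they are broadly comparable to natural grasses.
_CROP_SUITABILITY = {
    "tropical_forest": 1.0,
    "tropical_savanna": 1.0,
    "desert": 0.7,
    "mediterranean_woodland": 0.9,
    "temperate_grassland": 1.0,
    "mixed_forest": 0.9,
    "boreal_forest": 0.45,
    "tundra": 0.25,
}


def _biome_arrays():
    nb = len(BIOMES)
    cveg = np.empty(nb)
    p10 = np.empty(nb)
    p90 = np.empty(nb)
    turnover = np.empty(nb)
    npp = np.empty(nb)
    base_mix = np.zeros((nb, 5))
    warm_mix = np.zeros((nb, 5))
    c_eq = np.zeros((nb, N_PFT))
    npp_rate = np.zeros((nb, N_PFT))
    for b, name in enumerate(BIOMES):
        cveg[b], p10[b], p90[b], turnover[b], npp[b] = BIOME_TABLE[name]
        base_mix[b] = _BASE_MIX[name]
        warm_mix[b] = _WARM_MIX[name]
        dens_norm = float(base_mix[b] @ _REL_DENSITY[:5])
        npp_norm = float(base_mix[b] @ _REL_NPP[:5])
        c_eq[b] = _REL_DENSITY * cveg[b] / dens_norm
        npp_rate[b] = _REL_NPP * npp[b] / npp_norm
        suit = _CROP_SUITABILITY[name]
        c_eq[b, 5:] *= suit
        npp_rate[b, 5:] *= suit
    return {
        "cveg_mean": cveg,
        "cveg_p10": p10,
        "cveg_p90": p90,
        "soil_turnover": turnover,
        "npp_mean": npp,
        "base_mix": base_mix,
        "warm_mix": warm_mix,
        "c_eq": c_eq,  # per PFT-area equilibrium density, kgC m-2
        "npp_rate": npp_rate,  # per PFT-area NPP, kgC m-2 yr-1
    }


BIOME = _biome_arrays()


# ---------------------------------------------------------------------------
# Parameter containers


@dataclass(frozen=True)
class VegParams:
    """Tunable vegetation parameters.

    beta_co2
        Logarithmic CO2-fertilization coefficient applied to both NPP and
        the equilibrium vegetation density: ``x -> x * (1 + beta * ln(co2 /
        co2_ref))``.
    gamma_temp
        Linear NPP response to the local temperature anomaly (per K).
    aboveground_fraction
        Share of NPP (and of standing biomass at clearing) that is
        aboveground.
    tau_relax
        Per-natural-PFT e-folding times (years) for areal relaxation
        toward the potential mix; trees are slow, grasses fast.
    treeline_dT, treeline_width
        Local warming (K) at which the potential mix starts blending
        toward the warm (tree-line-advanced) mix, and the blend width.
    graze_frac
        Share of pasture aboveground litter consumed by livestock and
        respired directly to the atmosphere instead of entering the soil.
    """

    beta_co2: float = 0.5
    gamma_temp: float = 0.02
    aboveground_fraction: float = 0.5
    tau_relax: tuple = (50.0, 50.0, 20.0, 3.0, 3.0)
    treeline_dT: float = 1.0
    treeline_width: float = 1.0
    graze_frac: float = 0.5


@dataclass
class PFTState:
    """Vectorized per-cell PFT state: arrays of shape (n_cells, N_PFT)."""

    nu: np.ndarray
    c_veg: np.ndarray
    nu_prev: np.ndarray
    c_veg_prev: np.ndarray

    @classmethod
    def zeros(cls, n_cells: int) -> "PFTState":
        z = lambda: np.zeros((n_cells, N_PFT))
        return cls(z(), z(), z(), z())

    def copy(self) -> "PFTState":
        return PFTState(*(a.copy() for a in
                          (self.nu, self.c_veg, self.nu_prev, self.c_veg_prev)))

    @property
    def total_cveg(self) -> np.ndarray:
        """Cell-area vegetation carbon density, kgC m-2."""
        return (self.nu * self.c_veg).sum(axis=-1)


@dataclass
class NPPAccumulator:
    """NPP accumulated over one coupling step, per unit PFT area."""

    Pi: np.ndarray  # kgC m-2 (PFT area) per step
    anpp: np.ndarray  # kgC m-2 yr-1 aboveground


@dataclass
class LitterFlux:
    Lambda: np.ndarray  # kgC m-2 (cell area) per step, per PFT


# ---------------------------------------------------------------------------
# Operations


def litter_flux(nu_prev, c_prev, nu_new, c_new, Pi, clamp: bool = True):
    """Diagnose the litter flux closing the vegetation carbon balance.

    Returns ``(Lambda, c_new)``; when ``clamp`` is set and the raw formula
    would be negative (carbon appearing from nowhere during rapid
    expansion), Lambda is floored at zero and the density is reduced so the
    balance still holds exactly.
    """
    nu_prev, c_prev, nu_new, c_new, Pi = map(
        np.asarray, (nu_prev, c_prev, nu_new, c_new, Pi)
    )
    lam = Pi * nu_prev - (c_new * nu_new - c_prev * nu_prev)
    if not clamp:
        return lam, c_new
    neg = lam < 0
    if np.any(neg):
        c_new = np.where(
            neg & (nu_new > 0),
            (Pi * nu_prev + c_prev * nu_prev) / np.where(nu_new > 0, nu_new, 1.0),
            c_new,
        )
        lam = np.where(neg, 0.0, lam)
    return lam, c_new


def npp_model(
    biome_ids: np.ndarray,
    co2: float,
    co2_ref: float,
    local_dT: np.ndarray,
    params: VegParams = VegParams(),
    dt: float = 1.0,
) -> NPPAccumulator:
    """Reduced NPP model: biome/PFT baseline with logarithmic CO2
    fertilization and a linear local-temperature modifier.

    Returns per-PFT-area accumulated NPP of shape (n_cells, N_PFT).
    """
    if co2 <= 0:
        raise ValueError("co2 must be positive")
    base = BIOME["npp_rate"][biome_ids]  # (n, N_PFT)
    f_co2 = 1.0 + params.beta_co2 * np.log(co2 / co2_ref)
    f_t = np.maximum(0.0, 1.0 + params.gamma_temp * np.asarray(local_dT))
    rate = base * f_co2 * f_t[..., None]
    rate = np.maximum(rate, 0.0)
    return NPPAccumulator(Pi=rate * dt, anpp=params.aboveground_fraction * rate)


def equilibrium_density(
    biome_ids: np.ndarray, co2: float, co2_ref: float, params: VegParams
) -> np.ndarray:
    """CO2-adjusted equilibrium vegetation density c_eq (n, N_PFT)."""
    f = max(1.0 + params.beta_co2 * np.log(co2 / co2_ref), 0.05)
    return BIOME["c_eq"][biome_ids] * f


def step_vegetation(
    state: PFTState, npp: NPPAccumulator, c_eq: np.ndarray, dt: float = 1.0
) -> tuple[PFTState, LitterFlux]:
    """Grow vegetation density toward equilibrium and diagnose litter.

    ``state.nu`` must already hold the post-area-update fractions while
    ``nu_prev``/``c_veg_prev`` hold the start-of-step values; total
    vegetation carbon is conserved through area changes (density dilutes on
    expansion), so all carbon lost or gained over the step appears either
    in the density update or in the litter flux.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    nu_new = state.nu
    v_prev = state.c_veg_prev * state.nu_prev
    # density after V-conserving area change
    c_mid = np.where(nu_new > 0, v_prev / np.where(nu_new > 0, nu_new, 1.0), 0.0)
    # exponential relaxation toward c_eq driven by NPP
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(c_eq > 0, 1.0 - np.exp(-npp.Pi / np.where(c_eq > 0, c_eq, 1.0)), 0.0)
    c_new = c_mid + (c_eq - c_mid) * g
    c_new = np.where(nu_new > 0, c_new, 0.0)
    lam, c_new = litter_flux(state.nu_prev, state.c_veg_prev, nu_new, c_new, npp.Pi)
    if np.any(c_new < -1e-12):
        raise ValueError("negative vegetation carbon density after update")
    new = PFTState(
        nu=nu_new.copy(),
        c_veg=np.maximum(c_new, 0.0),
        nu_prev=nu_new.copy(),
        c_veg_prev=np.maximum(c_new, 0.0),
    )
    return new, LitterFlux(Lambda=lam)


def potential_mix(
    biome_ids: np.ndarray, local_dT: np.ndarray, params: VegParams = VegParams()
) -> np.ndarray:
    """Climate-dependent potential natural mix (n, 5): blends toward the
    warm mix as the local anomaly crosses the tree-line threshold."""
    w = np.clip(
        (np.asarray(local_dT) - params.treeline_dT) / params.treeline_width, 0.0, 1.0
    )
    return (1 - w[:, None]) * BIOME["base_mix"][biome_ids] + w[:, None] * BIOME[
        "warm_mix"
    ][biome_ids]


def step_pft_areas(
    state: PFTState,
    agri_fractions: np.ndarray,
    mix: np.ndarray,
    dt: float = 1.0,
    params: VegParams = VegParams(),
) -> PFTState:
    """Prescribe agricultural areas and relax natural areas toward the
    potential mix.  Total vegetation carbon per PFT is conserved (density
    adjusts); the sum of fractions never exceeds one.
    """
    agri = np.asarray(agri_fractions, dtype=float)
    if np.any(agri.sum(axis=-1) > 1 + 1e-9):
        raise ValueError("agricultural fractions exceed cell")
    nu = state.nu.copy()
    v = state.nu * state.c_veg
    nu[:, AGRI] = agri
    a_nat = np.maximum(0.0, 1.0 - agri.sum(axis=-1))
    target = mix * a_nat[:, None]
    f = 1.0 - np.exp(-dt / np.asarray(params.tau_relax))
    nat = state.nu[:, NATURAL] + (target - state.nu[:, NATURAL]) * f
    # keep closure if natural area was squeezed below current occupancy
    tot = nat.sum(axis=-1)
    over = tot > a_nat + 1e-12
    if np.any(over):
        scale = np.where(over, a_nat / np.maximum(tot, 1e-30), 1.0)
        nat *= scale[:, None]
    nu[:, NATURAL] = np.maximum(nat, 0.0)
    c = np.where(nu > 0, v / np.where(nu > 0, nu, 1.0), 0.0)
    return PFTState(nu=nu, c_veg=c, nu_prev=state.nu_prev, c_veg_prev=state.c_veg_prev)


# ---------------------------------------------------------------------------
# Soil


@dataclass
class SoilCarbonState:
    """Four first-order soil pools (fast, medium, slow, passive).

    ``pools`` has shape (n_cells, 4); ``turnover_years`` may be a (4,)
    vector or a per-cell (n_cells, 4) array (the pipeline scales turnovers
    per biome so equilibrium C_soil/NPP matches the biome table).
    """

    pools: np.ndarray
    turnover_years: np.ndarray = field(
        default_factory=lambda: np.array([1.0, 10.0, 100.0, 1000.0])
    )
    litter_split: np.ndarray = field(
        default_factory=lambda: np.array([0.6, 0.3, 0.09, 0.01])
    )
    q10: float = 2.0

    @property
    def total(self) -> np.ndarray:
        return self.pools.sum(axis=-1)


def step_soil(
    state: SoilCarbonState,
    litter_in: np.ndarray,
    local_dT: np.ndarray,
    dt: float = 1.0,
) -> tuple[SoilCarbonState, np.ndarray]:
    """One step of first-order decomposition with Q10 temperature scaling.

    Litter is split among the pools by fixed fractions; heterotrophic
    respiration ``rh`` is the sum of decayed carbon.  Carbon is conserved
    exactly: dC_soil = litter_in - rh.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    litter_in = np.asarray(litter_in, dtype=float)
    if np.any(litter_in < -1e-12):
        raise ValueError("litter_in must be non-negative")
    k = (dt / state.turnover_years) * state.q10 ** (np.asarray(local_dT)[..., None] / 10.0)
    decayed = state.pools * -np.expm1(-k)
    rh = decayed.sum(axis=-1)
    pools = state.pools - decayed + litter_in[..., None] * state.litter_split
    return replace(state, pools=pools), rh


def soil_equilibrium(
    litter_in: np.ndarray,
    turnover_years: np.ndarray,
    litter_split=None,
    q10: float = 2.0,
    local_dT=0.0,
    dt: float = 1.0,
) -> np.ndarray:
    """Discrete-step equilibrium pools for a constant litter input, i.e.
    the fixed point of :func:`step_soil`."""
    if litter_split is None:
        litter_split = np.array([0.6, 0.3, 0.09, 0.01])
    k = (dt / np.asarray(turnover_years)) * q10 ** (np.asarray(local_dT) / 10.0)
    return np.asarray(litter_in)[..., None] * np.asarray(litter_split) / -np.expm1(-k)
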