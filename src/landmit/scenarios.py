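"""Synthetic scenario inputs: land-use trajectories, temperature profiles,
emulated climate-model ensembles, and initial carbon fields.

The real study inputs are integrated-assessment land-use maps and
CMIP5-calibrated climate patterns; this module generates stand-ins with the
same structural properties (global bioenergy-area trajectories that rise to
a peak and decline, asymptotic warming profiles, an ensemble of climate
sensitivities, biome-realistic carbon stocks) so that the whole analysis
chain runs from a seed, without downloads.  The spatial placement rules are
deliberate caricatures -- weighted by latitude band, not by economics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.interpolate import CubicHermiteSpline

from .grid import BIOMES, GridDefinition
from .vegetation import BIOME, N_PFT, NATURAL, VegParams, soil_equilibrium

__all__ = [
    "LandUseProfile",
    "LandUseTrajectory",
    "TemperatureProfile",
    "EnsembleMember",
    "InitialCarbonField",
    "InfeasibleLandUseError",
    "generate_landuse_scenario",
    "generate_temperature_profile",
    "generate_ensemble",
    "generate_initial_carbon",
    "load_profile",
    "PROFILES",
]


class InfeasibleLandUseError(ValueError):
    """Requested bioenergy area exceeds the land available for conversion."""


# ---------------------------------------------------------------------------
# Land use


@dataclass(frozen=True)
class LandUseProfile:
    """Shape parameters of a bioenergy land-use scenario.

    The global bioenergy area follows a piecewise cubic-Hermite curve with
    zero end slopes through (start_year, 0), (peak_year, peak_area_mha) and
    (2100, end_area_mha).  Expansion is allocated to cells by a Gaussian
    latitude weighting (weighted sampling without replacement fixes a
    conversion priority order; abandonment retreats in reverse, LIFO).
    ``agri_displacement`` is the share of each new bioenergy fraction taken
    from existing cropland/pasture rather than from natural vegetation.
    """

    name: str = "custom"
    start_year: int = 2030
    peak_year: int = 2060
    peak_area_mha: float = 550.0
    end_area_mha: float = 430.0
    lat_center: float = 52.0
    lat_sd: float = 14.0
    agri_displacement: float = 0.25
    bio_cap: float = 0.6
    crop_area_mha: float = 1500.0
    pasture_area_mha: float = 3300.0
    seed: int = 0


#: Presets emulating the two integrated-assessment scenarios: the ambitious
#: 1.5 C-consistent pathway (large, mid/high-latitude bioenergy expansion
#: peaking at 550 Mha in 2060 and falling to 430 Mha by 2100) and the 2 C
#: pathway (smaller, more temperate expansion peaking at 325 Mha in 2085,
#: placed more on existing agricultural land).
PROFILES = {
    "im19_like": LandUseProfile(
        name="im19_like",
        peak_year=2060,
        peak_area_mha=550.0,
        end_area_mha=430.0,
        lat_center=52.0,
        lat_sd=14.0,
        agri_displacement=0.25,
    ),
    # The moderate pathway grows bioenergy predominantly on existing and
    # abandoned farmland, so its local agriculture is fully displaceable.
    "im26_like": LandUseProfile(
        name="im26_like",
        peak_year=2085,
        peak_area_mha=325.0,
        end_area_mha=310.0,
        lat_center=44.0,
        lat_sd=10.0,
        agri_displacement=1.0,
    ),
}


def load_profile(source) -> LandUseProfile:
    """Resolve a preset name, YAML file path, or mapping to a profile."""
    if isinstance(source, LandUseProfile):
        return source
    if isinstance(source, str) and source in PROFILES:
        return PROFILES[source]
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            data = yaml.safe_load(fh)
        return LandUseProfile(**data)
    return LandUseProfile(**dict(source))


@dataclass
class LandUseTrajectory:
    """Per-cell fractional land-use time series on a grid's land cells.

    Arrays have shape (n_years, n_land); the natural fraction is the
    remainder ``1 - food - pasture - bioenergy``.
    """

    years: np.ndarray
    frac_food_crop: np.ndarray
    frac_pasture: np.ndarray
    frac_bioenergy: np.ndarray
    grid: GridDefinition
    preset: str = "custom"
    seed: int = 0

    def global_area(self, which: str) -> np.ndarray:
        """Global area (Mha) per year of one class."""
        frac = getattr(self, f"frac_{which}")
        return frac @ self.grid.area

    @property
    def frac_agri(self) -> np.ndarray:
        return self.frac_food_crop + self.frac_pasture + self.frac_bioenergy

    def validate(self):
        for name in ("frac_food_crop", "frac_pasture", "frac_bioenergy"):
            a = getattr(self, name)
            if np.any(a < -1e-12) or np.any(a > 1 + 1e-12):
                raise ValueError(f"{name} outside [0, 1]")
        if np.any(self.frac_agri > 1 + 1e-9):
            raise ValueError("land-use fractions exceed cell area")

    def to_dataset(self):
        import xarray as xr

        g = self.grid
        data = {}
        for name in ("frac_food_crop", "frac_pasture", "frac_bioenergy"):
            cube = np.stack([g.to_2d(row, fill=0.0) for row in getattr(self, name)])
            data[name] = xr.DataArray(
                cube,
                dims=("time", "lat", "lon"),
                attrs={"units": "1", "long_name": name.replace("_", " ")},
            )
        lat = 0.5 * (g.lat_edges[:-1] + g.lat_edges[1:])
        lon = 0.5 * (g.lon_edges[:-1] + g.lon_edges[1:])
        ds = xr.Dataset(
            data,
            coords={"time": self.years, "lat": lat, "lon": lon},
            attrs={"preset": self.preset, "seed": self.seed, "Conventions": "CF-1.8"},
        )
        return ds

    def to_netcdf(self, path):
        self.to_dataset().to_netcdf(path, engine="scipy")

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": self.years,
                "food_crop_mha": self.global_area("food_crop"),
                "pasture_mha": self.global_area("pasture"),
                "bioenergy_mha": self.global_area("bioenergy"),
            }
        )


def bioenergy_area_curve(years: np.ndarray, profile: LandUseProfile) -> np.ndarray:
    """Global bioenergy area (Mha) per year: zero before start, then a
    monotone rise to the peak and a monotone decline to the end value, both
    cubic-Hermite segments with zero end slopes."""
    t = np.asarray(years, dtype=float)
    if profile.peak_area_mha <= 0:
        return np.zeros_like(t)
    knots = [float(profile.start_year), float(profile.peak_year)]
    vals = [0.0, profile.peak_area_mha]
    if profile.peak_year < years[-1]:
        knots.append(float(years[-1]))
        vals.append(float(profile.end_area_mha))
    spline = CubicHermiteSpline(knots, vals, np.zeros(len(knots)))
    out = np.where(
        t <= profile.start_year,
        0.0,
        spline(np.clip(t, knots[0], knots[-1])),
    )
    return np.maximum(out, 0.0)


def _background_agriculture(grid: GridDefinition, profile: LandUseProfile, rng):
    """Static food-crop and pasture fraction fields with Gaussian latitude
    suitability weights, scaled to the profile's global areas."""
    alat = np.abs(grid.lat_center)
    w_crop = np.exp(-(((alat - 30.0) / 18.0) ** 2)) + 0.5 * np.exp(
        -(((alat - 48.0) / 10.0) ** 2)
    )
    w_past = np.exp(-(((alat - 25.0) / 22.0) ** 2)) + 0.4 * np.exp(
        -(((alat - 45.0) / 15.0) ** 2)
    )
    w_crop = w_crop * rng.uniform(0.5, 1.5, grid.n_land)
    w_past = w_past * rng.uniform(0.5, 1.5, grid.n_land)
    crop = profile.crop_area_mha * w_crop / (w_crop @ grid.area)
    past = profile.pasture_area_mha * w_past / (w_past @ grid.area)
    # cap combined background agriculture at 70 % of any cell
    tot = crop + past
    over = tot > 0.7
    scale = np.where(over, 0.7 / np.maximum(tot, 1e-30), 1.0)
    return crop * scale, past * scale


def generate_landuse_scenario(
    grid: GridDefinition,
    profile,
    years=None,
) -> LandUseTrajectory:
    """Generate per-cell land-use fractions for one scenario preset.

    Deterministic for a given (grid, profile, seed).  Raises
    :class:`InfeasibleLandUseError` when the peak bioenergy area exceeds
    the convertible land under the profile's per-cell cap.
    """
    profile = load_profile(profile)
    if years is None:
        years = np.arange(2000, 2101)
    years = np.asarray(years)
    if not (years[0] <= profile.peak_year <= years[-1]):
        raise ValueError("peak_year outside the scenario period")
    if profile.peak_area_mha > grid.land_area_total:
        raise InfeasibleLandUseError("peak area exceeds total land area")

    rng = np.random.default_rng(profile.seed)
    crop0, past0 = _background_agriculture(grid, profile, rng)

    # conversion priority: weighted sampling without replacement
    alat = np.abs(grid.lat_center)
    w = np.exp(-(((alat - profile.lat_center) / profile.lat_sd) ** 2)) + 1e-4
    order = rng.choice(grid.n_land, size=grid.n_land, replace=False, p=w / w.sum())

    # Within each converted cell, bioenergy occupies existing agricultural
    # land first (up to the preset's agri_displacement share of it) and
    # clears natural vegetation only for the remainder -- mirroring
    # integrated-assessment allocation, which prefers abandoned and
    # existing farmland for bioenergy crops.
    d = profile.agri_displacement
    agri0 = crop0 + past0
    natural0 = 1.0 - agri0
    displaceable = d * agri0
    cap = np.minimum(profile.bio_cap, natural0 + displaceable)
    cap_area = cap[order] * grid.area[order]  # Mha capacity along the order
    cum_before = np.concatenate([[0.0], np.cumsum(cap_area)[:-1]])
    capacity = cap_area.sum()

    target = bioenergy_area_curve(years, profile)
    if target.max() > capacity * (1 + 1e-9):
        raise InfeasibleLandUseError(
            f"peak bioenergy area {target.max():.0f} Mha exceeds convertible "
            f"capacity {capacity:.0f} Mha under the per-cell cap"
        )

    # fill cells along the priority order up to their cap; the marginal
    # cell is partially converted so the global total matches exactly
    fill = np.clip(
        (target[:, None] - cum_before[None, :]) / np.maximum(cap_area, 1e-30),
        0.0,
        1.0,
    )
    bio = np.zeros((len(years), grid.n_land))
    bio[:, order] = fill * cap[order]

    # farmland-first displacement, split between classes pro rata
    taken = np.minimum(bio, displaceable[None, :])
    with np.errstate(invalid="ignore", divide="ignore"):
        share_crop = np.where(agri0 > 0, crop0 / np.maximum(agri0, 1e-30), 0.0)
    crop = crop0[None, :] - taken * share_crop[None, :]
    past = past0[None, :] - taken * (1.0 - share_crop[None, :])

    traj = LandUseTrajectory(
        years=years,
        frac_food_crop=crop,
        frac_pasture=past,
        frac_bioenergy=bio,
        grid=grid,
        preset=profile.name,
        seed=profile.seed,
    )
    traj.validate()
    return traj


# ---------------------------------------------------------------------------
# Temperature


@dataclass
class TemperatureProfile:
    years: np.ndarray
    dT_global: np.ndarray  # K above pre-industrial
    target: float

    def validate(self):
        if np.any(np.diff(self.dT_global) < -1e-12):
            raise ValueError("temperature profile must be non-decreasing")


def generate_temperature_profile(
    target: float,
    start_dT: float = 0.9,
    years=None,
    tau_years: float = 30.0,
) -> TemperatureProfile:
    """Smooth monotone warming that asymptotes to ``target`` by the end of
    the century: dT(t) = target - (target - start) * exp(-(t - t0)/tau)."""
    if target <= start_dT:
        raise ValueError("target must exceed the starting warming")
    if years is None:
        years = np.arange(2000, 2101)
    years = np.asarray(years)
    dT = target - (target - start_dT) * np.exp(-(years - years[0]) / tau_years)
    prof = TemperatureProfile(years=years, dT_global=dT, target=target)
    prof.validate()
    return prof


# ---------------------------------------------------------------------------
# Ensemble


@dataclass
class EnsembleMember:
    """One emulated climate model: a feedback parameter, an ocean
    heat-uptake efficiency, and normalized anomaly patterns."""

    member_id: int
    lambda_clim: float  # W m-2 K-1
    kappa_ocean: float  # W m-2 K-1
    pattern_T: np.ndarray  # (n_land,), area-weighted mean 1
    pattern_P: np.ndarray


def generate_ensemble(
    n: int,
    grid: GridDefinition,
    seed: int = 0,
    lambda_range=(0.7, 1.6),
    kappa_range=(0.5, 0.9),
    amp_range=(0.5, 1.5),
) -> list[EnsembleMember]:
    """Draw ``n`` emulated climate-sensitivity parameter sets (default
    ensemble size is 34).  Temperature patterns are polar-amplified with a
    per-member amplification factor and normalized so the area-weighted
    global mean equals one."""
    if n < 1:
        raise ValueError("ensemble size must be >= 1")
    rng = np.random.default_rng(seed)
    wts = grid.area / grid.area.sum()
    s2 = np.sin(np.deg2rad(grid.lat_center)) ** 2
    members = []
    for i in range(n):
        lam = rng.uniform(*lambda_range)
        kap = rng.uniform(*kappa_range)
        amp = rng.uniform(*amp_range)
        pat_t = 1.0 + amp * s2
        pat_t = pat_t / (pat_t @ wts)
        amp_p = rng.uniform(-0.3, 0.3)
        pat_p = 1.0 + amp_p * np.cos(np.deg2rad(grid.lat_center)) ** 2
        pat_p = pat_p / (pat_p @ wts)
        members.append(EnsembleMember(i, lam, kap, pat_t, pat_p))
    return members


def ensemble_frame(members) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "member_id": [m.member_id for m in members],
            "lambda_clim": [m.lambda_clim for m in members],
            "kappa_ocean": [m.kappa_ocean for m in members],
        }
    )


# ---------------------------------------------------------------------------
# Initial carbon


@dataclass
class InitialCarbonField:
    """Initial vegetation and soil carbon consistent with the biome table.

    ``c_veg`` is per-PFT-area density (n_land, N_PFT); ``nu`` the potential
    natural cover; ``soil_pools`` the four-pool soil state at its
    discrete-step equilibrium; ``turnover_years`` the per-cell pool
    turnovers (biome-scaled, with multiplicative heterogeneity).
    """

    biome_id: np.ndarray
    nu: np.ndarray
    c_veg: np.ndarray
    soil_pools: np.ndarray
    turnover_years: np.ndarray

    @property
    def total_cveg(self) -> np.ndarray:
        return (self.nu * self.c_veg).sum(axis=-1)

    @property
    def total_csoil(self) -> np.ndarray:
        return self.soil_pools.sum(axis=-1)


_BASE_SOIL_TAU = np.array([1.0, 10.0, 100.0, 1000.0])
_SOIL_SPLIT = np.array([0.6, 0.3, 0.09, 0.01])


def generate_initial_carbon(
    grid: GridDefinition,
    biome_ids: np.ndarray,
    seed: int = 0,
    params: VegParams = VegParams(),
) -> InitialCarbonField:
    """Draw an initial carbon field at potential vegetation cover.

    Per-cell vegetation density is the biome equilibrium scaled by a
    truncated-normal heterogeneity factor, clipped so cell values stay
    inside the biome's 10th-90th percentile envelope; soil pools start at
    the equilibrium implied by the biome turnover time (which sets a
    per-biome rescaling of the four pool turnovers) with its own
    heterogeneity factor.
    """
    biome_ids = np.asarray(biome_ids)
    if biome_ids.size and (biome_ids.min() < 0 or biome_ids.max() >= len(BIOMES)):
        raise ValueError("unknown biome id")
    n = len(biome_ids)
    rng = np.random.default_rng(seed)

    mean = BIOME["cveg_mean"][biome_ids]
    lo = BIOME["cveg_p10"][biome_ids]
    hi = BIOME["cveg_p90"][biome_ids]
    f = rng.normal(1.0, 0.3, size=n)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.clip(f, lo / np.maximum(mean, 1e-30), hi / np.maximum(mean, 1e-30))

    mix = BIOME["base_mix"][biome_ids]
    nu = np.zeros((n, N_PFT))
    nu[:, NATURAL] = mix
    c_veg = BIOME["c_eq"][biome_ids] * f[:, None]

    # soil: per-biome turnover rescale so equilibrium C_soil/NPP matches
    # the biome table, plus per-cell heterogeneity in turnover
    base_turn = float(_SOIL_SPLIT @ _BASE_SOIL_TAU)
    g = np.clip(rng.normal(1.0, 0.2, size=n), 0.4, 1.8)
    scale = BIOME["soil_turnover"][biome_ids] / base_turn * g
    turnovers = _BASE_SOIL_TAU[None, :] * scale[:, None]
    litter0 = (nu * BIOME["npp_rate"][biome_ids]).sum(axis=-1)
    pools = soil_equilibrium(litter0, turnovers, _SOIL_SPLIT)
    return InitialCarbonField(
        biome_id=biome_ids,
        nu=nu,
        c_veg=c_veg,
        soil_pools=pools,
        turnover_years=turnovers,
    )
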