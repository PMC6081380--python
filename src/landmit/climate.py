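"""Inverted global energy-balance climate emulation with pattern scaling.

Rather than prescribing CO2 and predicting warming, the emulator is run
backwards: a prescribed global-mean temperature profile is combined with a
two-box energy-balance model (mixed layer + deep ocean) to recover, per
ensemble member, the total radiative forcing consistent with that warming;
a fixed non-CO2 share and the logarithmic forcing law then yield the CO2
concentration path.  Because each member has its own climate feedback
parameter, the same temperature target maps to a different CO2 path per
member: less sensitive models (higher lambda) need more CO2 to warm the
same amount.  Local anomalies are the global warming times a fixed,
area-normalized spatial pattern.  A pulse-response ocean carbon kernel and
the atmospheric CO2 increments close the budget of "allowable" fossil
emissions for the prescribed warming.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .scenarios import EnsembleMember, TemperatureProfile

__all__ = [
    "EBMParams",
    "OceanCarbonParams",
    "ForcingPath",
    "CarbonBudget",
    "invert_ebm",
    "forward_ebm",
    "forcing_to_co2",
    "co2_to_forcing",
    "ocean_uptake",
    "diagnose_allowable_emissions",
    "pattern_scale",
    "member_forcing_and_co2",
]

#: Standard conversion between atmospheric CO2 concentration and mass.
PPM_TO_GTC = 2.124


@dataclass(frozen=True)
class EBMParams:
    """Two-box energy-balance constants.

    lambda_clim and kappa_ocean are per-member (W m-2 K-1); the heat
    capacities are in W yr m-2 K-1 (mixed layer ~ 70 m of water, deep
    ocean an order of magnitude more); dTd0_frac sets the initial
    deep-ocean temperature as a fraction of the initial surface warming,
    standing in for the historical transient.
    """

    lambda_clim: float = 1.1
    kappa_ocean: float = 0.65
    F_2x: float = 3.7
    co2_preind: float = 285.0
    nonco2_share: float = 0.2
    c_mixed: float = 8.0
    c_deep: float = 100.0
    dTd0_frac: float = 0.5
    co2_floor: float = 150.0

    def __post_init__(self):
        if min(self.lambda_clim, self.kappa_ocean, self.F_2x, self.co2_preind) <= 0:
            raise ValueError("EBM parameters must be positive")


@dataclass(frozen=True)
class OceanCarbonParams:
    """Exponential pulse-response ocean carbon kernel: a unit atmospheric
    perturbation is eventually taken up in fraction ``uptake_fraction``,
    with e-folding ``tau_years``."""

    uptake_fraction: float = 0.7
    tau_years: float = 40.0


@dataclass
class ForcingPath:
    years: np.ndarray
    Q: np.ndarray  # W m-2 total forcing
    Q_co2: np.ndarray | None = None
    co2: np.ndarray | None = None
    nonco2_share: float = 0.2


@dataclass
class CarbonBudget:
    years: np.ndarray
    d_atm: np.ndarray  # GtC yr-1
    ocean_uptake: np.ndarray
    land_uptake: np.ndarray
    allowable_emissions: np.ndarray


def _deep_ocean_series(dT: np.ndarray, p: EBMParams, dt: float) -> np.ndarray:
    dTd = np.empty_like(dT)
    dTd[0] = p.dTd0_frac * dT[0]
    a = dt * p.kappa_ocean / p.c_deep
    for n in range(len(dT) - 1):
        dTd[n + 1] = dTd[n] + a * (dT[n] - dTd[n])
    return dTd


def invert_ebm(profile: TemperatureProfile, p: EBMParams, dt: float = 1.0) -> ForcingPath:
    """Forcing path consistent with the prescribed warming:
    Q = C_ml dT/dt + lambda * dT + kappa * (dT - dT_deep), discretized to
    match :func:`forward_ebm` exactly."""
    dT = np.asarray(profile.dT_global, dtype=float)
    if np.any(np.diff(dT) < -1e-12):
        raise ValueError("temperature profile must be non-decreasing")
    dTd = _deep_ocean_series(dT, p, dt)
    Q = np.empty_like(dT)
    ddt = np.diff(dT) / dt
    n = len(dT)
    Q[: n - 1] = (
        p.c_mixed * ddt
        + p.lambda_clim * dT[: n - 1]
        + p.kappa_ocean * (dT[: n - 1] - dTd[: n - 1])
    )
    Q[n - 1] = p.lambda_clim * dT[n - 1] + p.kappa_ocean * (dT[n - 1] - dTd[n - 1])
    return ForcingPath(
        years=np.asarray(profile.years), Q=Q, nonco2_share=p.nonco2_share
    )


def forward_ebm(
    Q: np.ndarray, p: EBMParams, dT0: float, dt: float = 1.0
) -> np.ndarray:
    """Explicit-Euler forward integration of the two-box model; the
    independent check that the inverted forcing reproduces the prescribed
    warming."""
    Q = np.asarray(Q, dtype=float)
    dT = np.empty_like(Q)
    dTd = np.empty_like(Q)
    dT[0] = dT0
    dTd[0] = p.dTd0_frac * dT0
    for i in range(len(Q) - 1):
        dT[i + 1] = dT[i] + dt / p.c_mixed * (
            Q[i] - p.lambda_clim * dT[i] - p.kappa_ocean * (dT[i] - dTd[i])
        )
        dTd[i + 1] = dTd[i] + dt * p.kappa_ocean / p.c_deep * (dT[i] - dTd[i])
    return dT


def forcing_to_co2(path: ForcingPath, p: EBMParams) -> ForcingPath:
    """Fill the CO2 path from the forcing via the logarithmic law:
    co2 = co2_preind * 2 ** (Q_co2 / F_2x), with Q_co2 the CO2 share of
    the total forcing."""
    q_co2 = (1.0 - path.nonco2_share) * path.Q
    co2 = p.co2_preind * 2.0 ** (q_co2 / p.F_2x)
    if np.any(co2 < p.co2_floor):
        raise ValueError("inverted CO2 fell below the configured floor")
    return replace(path, Q_co2=q_co2, co2=co2)


def co2_to_forcing(co2: np.ndarray, p: EBMParams) -> np.ndarray:
    """Inverse of the logarithmic law (round-trip partner)."""
    return p.F_2x * np.log2(np.asarray(co2, dtype=float) / p.co2_preind)


def ocean_uptake(
    co2_ppm: np.ndarray,
    params: OceanCarbonParams = OceanCarbonParams(),
    dt: float = 1.0,
    ppm_to_gtc: float = PPM_TO_GTC,
) -> np.ndarray:
    """Ocean carbon uptake (GtC yr-1) as the convolution of atmospheric
    CO2 increments with a decaying exponential kernel."""
    co2 = np.asarray(co2_ppm, dtype=float)
    d_atm = np.diff(co2, prepend=co2[0]) * ppm_to_gtc  # GtC per step
    n = len(co2)
    u = np.arange(n) * dt
    # discrete kernel normalized so its mass is exactly uptake_fraction:
    # cumulative uptake of a pulse never exceeds fraction * perturbation
    norm = -np.expm1(-dt / params.tau_years) / dt
    kernel = params.uptake_fraction * norm * np.exp(-u / params.tau_years)
    return np.convolve(d_atm, kernel)[:n]


def diagnose_allowable_emissions(
    years: np.ndarray,
    co2_ppm: np.ndarray,
    ocean_series: np.ndarray,
    land_series: np.ndarray,
    ppm_to_gtc: float = PPM_TO_GTC,
) -> CarbonBudget:
    """Budget identity: allowable fossil emissions equal the atmospheric
    carbon change plus ocean and land uptake (uptakes positive)."""
    years = np.asarray(years)
    arrays = [np.asarray(a, dtype=float) for a in (co2_ppm, ocean_series, land_series)]
    if any(len(a) != len(years) for a in arrays):
        raise ValueError("series are not on the same time axis")
    co2, ocean, land = arrays
    d_atm = np.diff(co2, prepend=co2[0]) * ppm_to_gtc
    return CarbonBudget(
        years=years,
        d_atm=d_atm,
        ocean_uptake=ocean,
        land_uptake=land,
        allowable_emissions=d_atm + ocean + land,
    )


def pattern_scale(dT_global, member: EnsembleMember, grid=None) -> np.ndarray:
    """Local temperature anomalies: pattern times global warming.  Accepts
    a scalar (returns (n_land,)) or a series (returns (n_years, n_land))."""
    if grid is not None and len(member.pattern_T) != grid.n_land:
        raise ValueError("pattern not defined on this grid")
    dT = np.asarray(dT_global, dtype=float)
    return np.multiply.outer(dT, member.pattern_T) if dT.ndim else dT * member.pattern_T


def member_forcing_and_co2(
    profile: TemperatureProfile, member: EnsembleMember, base: EBMParams = EBMParams()
) -> ForcingPath:
    """Per-member inversion: the member's feedback and ocean-uptake
    parameters drive the EBM inversion, then the CO2 path is filled in."""
    p = replace(base, lambda_clim=member.lambda_clim, kappa_ocean=member.kappa_ocean)
    return forcing_to_co2(invert_ebm(profile, p), p)
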