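"""Harvest and BECCS (biomass energy with carbon capture and storage)
accounting.

A fixed fraction ``eps_harv`` of crop-PFT litter is harvested (H_i).  The
share of the harvest coming from bioenergy crops, ``nu_bio / nu_agric``,
is diverted to a non-decaying geological reservoir with a transfer
efficiency ``eps_beccs`` covering all losses from field to repository; the
remainder of the harvest enters the fast wood-product pool and is quickly
respired.  A capture multiplier scales the diverted flux for sensitivity
analyses (higher yields, residue feedstocks, better capture), capped so
that no more carbon is stored than was harvested from bioenergy crops.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BECCSParams",
    "HarvestFlux",
    "BECCSReservoir",
    "YieldConversion",
    "harvest",
    "divert_to_beccs",
    "efficiency_chain",
    "carbon_to_drymass",
]


@dataclass(frozen=True)
class BECCSParams:
    eps_harv: float = 0.3  # harvesting efficiency (share of crop litter)
    eps_beccs: float = 0.6  # field-to-repository transfer efficiency
    capture_multiplier: float = 1.0  # sensitivity axis: 1, 1.5, 2, 3

    def __post_init__(self):
        if not (0 < self.eps_harv <= 1 and 0 < self.eps_beccs <= 1):
            raise ValueError("efficiencies must lie in (0, 1]")
        if self.capture_multiplier <= 0:
            raise ValueError("capture_multiplier must be positive")


@dataclass
class HarvestFlux:
    H_i: np.ndarray  # initial harvest, kgC m-2
    H: np.ndarray  # residual harvest to the fast product pool
    beccs_flux: np.ndarray  # diverted to geological storage
    nu_bio: np.ndarray
    nu_agric: np.ndarray


@dataclass
class BECCSReservoir:
    """Non-decaying geological storage; cumulative per cell (kgC m-2)."""

    cumulative: np.ndarray
    annual_flux: list = field(default_factory=list)

    @classmethod
    def zeros(cls, n: int) -> "BECCSReservoir":
        return cls(cumulative=np.zeros(n))

    def add(self, flux: np.ndarray):
        if np.any(np.asarray(flux) < -1e-15):
            raise ValueError("BECCS flux must be non-negative")
        self.cumulative = self.cumulative + flux
        self.annual_flux.append(np.asarray(flux))


@dataclass(frozen=True)
class YieldConversion:
    carbon_fraction: float = 0.5
    moisture: float = 0.10
    aboveground_fraction: float = 0.5


def harvest(crop_litter, params: BECCSParams = BECCSParams()):
    """Initial harvest flux H_i = eps_harv * Lambda_crop; the remaining
    (1 - eps_harv) of the crop litter goes to the soil."""
    crop_litter = np.asarray(crop_litter, dtype=float)
    if np.any(crop_litter < 0):
        raise ValueError("crop litter must be non-negative")
    return params.eps_harv * crop_litter


def divert_to_beccs(
    H_i, nu_bio, nu_agric, params: BECCSParams = BECCSParams()
) -> HarvestFlux:
    """Split the harvest between geological storage and the fast product
    pool: BECCS = H_i * (nu_bio / nu_agric) * eps_beccs (times the capture
    multiplier, capped at the bioenergy share of the harvest itself)."""
    H_i, nu_bio, nu_agric = np.broadcast_arrays(
        *map(np.asarray, (H_i, nu_bio, nu_agric))
    )
    H_i = H_i.astype(float)
    if np.any(nu_bio > nu_agric + 1e-12):
        raise ValueError("nu_bio cannot exceed nu_agric")
    if np.any((H_i > 0) & (nu_agric <= 0)):
        raise ValueError("harvest from zero crop area")
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(nu_agric > 0, nu_bio / np.where(nu_agric > 0, nu_agric, 1.0), 0.0)
    flux = H_i * ratio * params.eps_beccs * params.capture_multiplier
    flux = np.minimum(flux, H_i * ratio)  # cannot store more than harvested
    return HarvestFlux(
        H_i=H_i,
        H=H_i - flux,
        beccs_flux=flux,
        nu_bio=np.asarray(nu_bio, dtype=float),
        nu_agric=np.asarray(nu_agric, dtype=float),
    )


def efficiency_chain(biomass, ccs_fraction, chain_efficiency):
    """Captured carbon for a given biomass under an explicit accounting
    chain: captured = biomass * (share of crops used with CCS) * (net
    field-to-repository efficiency).  Used to tabulate DGVM-style versus
    integrated-assessment-style accounting side by side."""
    biomass = np.asarray(biomass, dtype=float)
    for f in (ccs_fraction, chain_efficiency):
        if np.any(np.asarray(f) < 0) or np.any(np.asarray(f) > 1):
            raise ValueError("fractions must lie in [0, 1]")
    return biomass * ccs_fraction * chain_efficiency


def carbon_to_drymass(c, conv: YieldConversion = YieldConversion()):
    """Convert carbon mass to dry matter at the stated moisture content:
    DM = C / carbon_fraction / (1 - moisture)."""
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("carbon mass must be non-negative")
    return c / conv.carbon_fraction / (1.0 - conv.moisture)
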