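"""Land-use-change bookkeeping: cleared biomass, wood-product pools, and
transition detection.

When land is cleared, aboveground biomass from woody vegetation is split
10 % / 30 % / 60 % into slow (100 yr), medium (10 yr) and fast (1 yr)
e-folding wood-product pools; aboveground biomass from grass-like
vegetation goes entirely to the fast pool; belowground biomass goes
straight into the fast soil pool.  An optional accounting switch routes
the aboveground biomass of land cleared *for bioenergy* into the
geological BECCS reservoir instead -- the convention used by
integrated-assessment accounting, where the initial harvest itself feeds
the first bioenergy use.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ProductPools",
    "TransitionEvent",
    "ProductAllocation",
    "allocate_cleared_biomass",
    "decay_products",
    "detect_transitions",
    "CLASSES",
]

CLASSES = ("natural", "crop_food", "pasture", "bioenergy")

#: e-folding times (years) of the fast / medium / slow product pools
PRODUCT_TAU = np.array([1.0, 10.0, 100.0])


@dataclass
class ProductPools:
    """Wood-product pools, kgC m-2, shape (..., 3) = (fast, medium, slow)."""

    pools: np.ndarray
    tau_years: np.ndarray = field(default_factory=lambda: PRODUCT_TAU.copy())

    @classmethod
    def zeros(cls, n: int) -> "ProductPools":
        return cls(pools=np.zeros((n, 3)))

    @property
    def total(self) -> np.ndarray:
        return self.pools.sum(axis=-1)


@dataclass(frozen=True)
class TransitionEvent:
    """One class-to-class land conversion in one cell-year."""

    cell: int
    year: int
    from_class: str
    to_class: str
    area_delta: float  # fraction of cell moved
    cleared_above: float = 0.0  # kgC m-2 (cell area)
    cleared_below: float = 0.0


@dataclass
class ProductAllocation:
    product_delta: np.ndarray  # (3,) fast, medium, slow
    soil_fast_delta: float


def allocate_cleared_biomass(
    cleared_above: float,
    cleared_below: float,
    source_kind: str,
    medium_share: float = 0.30,
    slow_share: float = 0.10,
) -> ProductAllocation:
    """Split cleared biomass into product pools and the fast soil pool.

    Woody sources follow the slow/medium/fast split (default 0.10 / 0.30 /
    0.60); grass sources put all aboveground carbon into the fast pool.
    The total allocated always equals the total cleared.
    """
    if cleared_above < 0 or cleared_below < 0:
        raise ValueError("cleared carbon must be non-negative")
    if source_kind == "tree":
        fast = 1.0 - medium_share - slow_share
        delta = cleared_above * np.array([fast, medium_share, slow_share])
    elif source_kind == "grass":
        delta = cleared_above * np.array([1.0, 0.0, 0.0])
    else:
        raise ValueError(f"unknown source kind {source_kind!r}")
    return ProductAllocation(product_delta=delta, soil_fast_delta=cleared_below)


def decay_products(
    pools: ProductPools, dt: float = 1.0
) -> tuple[ProductPools, np.ndarray]:
    """Exponential decay of each product pool; returns the new pools and
    the flux to the atmosphere (exact conservation)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    decayed = pools.pools * -np.expm1(-dt / pools.tau_years)
    flux = decayed.sum(axis=-1)
    return ProductPools(pools=pools.pools - decayed, tau_years=pools.tau_years), flux


# ---------------------------------------------------------------------------
# Transition detection


def _decompose_cell(deltas: dict[str, float], tol: float = 1e-12):
    """Decompose per-class area deltas of one cell into from->to moves.

    Precedence: expanding classes draw first from shrinking *agricultural*
    classes (class-to-class swaps, which minimize spurious clearing
    emissions), then from natural vegetation; any leftover shrinkage is
    abandonment to natural.
    """
    total = sum(deltas.values())
    if abs(total) > 1e-9:
        raise ValueError("class deltas do not close (natural is remainder)")
    gains = {c: d for c, d in deltas.items() if c != "natural" and d > tol}
    losses = {c: -d for c, d in deltas.items() if c != "natural" and d < -tol}
    moves = []
    for to_c in sorted(gains):
        need = gains[to_c]
        for from_c in sorted(losses):
            if need <= tol:
                break
            take = min(need, losses[from_c])
            if take > tol:
                moves.append((from_c, to_c, take))
                losses[from_c] -= take
                need -= take
        if need > tol:
            moves.append(("natural", to_c, need))
    for from_c, left in sorted(losses.items()):
        if left > tol:
            moves.append((from_c, "natural", left))
    return moves


def detect_transitions(
    traj,
    year_index: int,
    veg_state=None,
    aboveground_fraction: float = 0.5,
) -> list[TransitionEvent]:
    """Detect per-cell class-to-class transitions between two consecutive
    years of a land-use trajectory.

    When a vegetation state is supplied, events carry the biomass of the
    displaced vegetation: clearing natural land removes carbon from the
    natural PFTs in proportion to their cover, split into aboveground
    (to product pools) and belowground (to the fast soil pool) parts.
    """
    from .vegetation import NATURAL

    if year_index < 1:
        raise ValueError("need consecutive years")
    fr = {
        "crop_food": traj.frac_food_crop,
        "pasture": traj.frac_pasture,
        "bioenergy": traj.frac_bioenergy,
    }
    events: list[TransitionEvent] = []
    year = int(traj.years[year_index])
    for cell in range(traj.grid.n_land):
        deltas = {
            c: float(a[year_index, cell] - a[year_index - 1, cell])
            for c, a in fr.items()
        }
        deltas["natural"] = -sum(deltas.values())
        if all(abs(d) < 1e-12 for d in deltas.values()):
            continue
        for from_c, to_c, area in _decompose_cell(deltas):
            above = below = 0.0
            if veg_state is not None and from_c == "natural":
                nat_nu = veg_state.nu[cell, NATURAL].sum()
                if nat_nu > 0:
                    dens = (
                        veg_state.nu[cell, NATURAL] * veg_state.c_veg[cell, NATURAL]
                    ).sum() / nat_nu
                    above = area * dens * aboveground_fraction
                    below = area * dens * (1 - aboveground_fraction)
            events.append(
                TransitionEvent(
                    cell=cell,
                    year=year,
                    from_class=from_c,
                    to_class=to_c,
                    area_delta=area,
                    cleared_above=above,
                    cleared_below=below,
                )
            )
    return events


def events_frame(events):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "cell": e.cell,
                "year": e.year,
                "from": e.from_class,
                "to": e.to_class,
                "area": e.area_delta,
                "cleared_above": e.cleared_above,
                "cleared_below": e.cleared_below,
            }
            for e in events
        ]
    )
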