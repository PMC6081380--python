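"""Regular latitude-longitude grid with a synthetic land mask and biome bands.

The native resolution emulated here is a coarse climate-model grid
(2.5 deg latitude x 3.75 deg longitude, 96 x 73 cells).  Smaller grids with
the same structure are used for tests and desk-scale ensembles.  The land
mask is synthetic: cells are ranked by a smooth deterministic
"continentality" score and selected until the configured global land area
is reached, which clusters land into a few contiguous masses with a
Northern-Hemisphere bias, as on Earth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

EARTH_RADIUS_KM = 6371.0
#: Global land area (Mha) of the coarse grid the study design assumes.
DEFAULT_LAND_AREA_MHA = 13345.8

#: Eight biomes, ordered from the equator poleward by the latitude-band
#: caricature used when no biome map is supplied.
BIOMES = (
    "tropical_forest",
    "tropical_savanna",
    "desert",
    "mediterranean_woodland",
    "temperate_grassland",
    "mixed_forest",
    "boreal_forest",
    "tundra",
)

# |latitude| band edges (deg) for the biome caricature, same order as BIOMES.
_BIOME_LAT_EDGES = (
    (0.0, 10.0),
    (10.0, 20.0),
    (20.0, 30.0),
    (30.0, 35.0),
    (35.0, 45.0),
    (45.0, 55.0),
    (55.0, 66.0),
    (66.0, 90.1),
)


@dataclass(frozen=True)
class GridDefinition:
    """A regular lat-lon grid restricted to its land cells.

    All per-cell arrays elsewhere in the package are 1-D over the land
    cells of this grid, in the order given by ``land_index``.
    """

    n_lat: int
    n_lon: int
    lat_edges: np.ndarray  # (n_lat + 1,) degrees, south to north
    lon_edges: np.ndarray  # (n_lon + 1,) degrees
    cell_area: np.ndarray  # (n_lat, n_lon) Mha
    land_mask: np.ndarray  # (n_lat, n_lon) bool
    land_index: np.ndarray = field(init=False)  # (n_land, 2) int
    lat_center: np.ndarray = field(init=False)  # (n_land,) degrees
    lon_center: np.ndarray = field(init=False)
    area: np.ndarray = field(init=False)  # (n_land,) Mha

    def __post_init__(self):
        idx = np.argwhere(self.land_mask)
        lat_c = 0.5 * (self.lat_edges[:-1] + self.lat_edges[1:])
        lon_c = 0.5 * (self.lon_edges[:-1] + self.lon_edges[1:])
        object.__setattr__(self, "land_index", idx)
        object.__setattr__(self, "lat_center", lat_c[idx[:, 0]])
        object.__setattr__(self, "lon_center", lon_c[idx[:, 1]])
        object.__setattr__(self, "area", self.cell_area[idx[:, 0], idx[:, 1]])

    @property
    def n_land(self) -> int:
        return len(self.area)

    @property
    def land_area_total(self) -> float:
        """Total land area in Mha."""
        return float(self.area.sum())

    def to_2d(self, values: np.ndarray, fill=np.nan) -> np.ndarray:
        """Scatter a per-land-cell vector back onto the (n_lat, n_lon) grid."""
        out = np.full((self.n_lat, self.n_lon), fill, dtype=float)
        out[self.land_index[:, 0], self.land_index[:, 1]] = values
        return out


def cell_areas_mha(lat_edges: np.ndarray, lon_edges: np.ndarray) -> np.ndarray:
    """Exact spherical areas (Mha) of the cells of a regular grid."""
    lat_r = np.deg2rad(lat_edges)
    dlon = np.deg2rad(np.diff(lon_edges))
    band = EARTH_RADIUS_KM**2 * (np.sin(lat_r[1:]) - np.sin(lat_r[:-1]))
    area_km2 = np.outer(band, dlon)
    return area_km2 / 1e4  # 1 Mha = 1e4 km2


def _continentality(lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
    """Smooth deterministic score; high values become land.

    A few low-wavenumber harmonics produce contiguous synthetic continents,
    and a hemispheric term biases land toward the Northern Hemisphere.
    """
    la, lo = np.deg2rad(lat), np.deg2rad(lon)
    score = (
        np.sin(2 * lo + 0.7) * np.cos(la)
        + 0.6 * np.cos(3 * lo - 1.1) * np.cos(2 * la)
        + 0.45 * np.sin(la)  # NH bias
        + 0.3 * np.sin(4 * lo + 2 * la)
    )
    # suppress land right at the poles (ice caps / southern ocean)
    score -= 2.0 * (np.abs(lat) > 83.0)
    return score


def make_grid(
    n_lat: int = 73,
    n_lon: int = 96,
    land_area_mha: float = DEFAULT_LAND_AREA_MHA,
) -> GridDefinition:
    """Build the synthetic grid, selecting land cells by continentality
    until the cumulative area reaches ``land_area_mha`` (scaled by the
    grid's share of the full-resolution total when the grid is coarser)."""
    lat_edges = np.linspace(-90.0, 90.0, n_lat + 1)
    lon_edges = np.linspace(-180.0, 180.0, n_lon + 1)
    areas = cell_areas_mha(lat_edges, lon_edges)

    lat_c = 0.5 * (lat_edges[:-1] + lat_edges[1:])
    lon_c = 0.5 * (lon_edges[:-1] + lon_edges[1:])
    LO, LA = np.meshgrid(lon_c, lat_c)
    score = _continentality(LA, LO)

    order = np.argsort(score.ravel())[::-1]
    cum = np.cumsum(areas.ravel()[order])
    n_sel = int(np.searchsorted(cum, land_area_mha) + 1)
    n_sel = min(n_sel, areas.size)
    mask = np.zeros(areas.size, dtype=bool)
    mask[order[:n_sel]] = True
    return GridDefinition(
        n_lat=n_lat,
        n_lon=n_lon,
        lat_edges=lat_edges,
        lon_edges=lon_edges,
        cell_area=areas,
        land_mask=mask.reshape(areas.shape),
    )


def biome_map(grid: GridDefinition) -> np.ndarray:
    """Latitude-band biome id per land cell (index into :data:`BIOMES`)."""
    ids = np.zeros(grid.n_land, dtype=int)
    alat = np.abs(grid.lat_center)
    for b, (lo, hi) in enumerate(_BIOME_LAT_EDGES):
        ids[(alat >= lo) & (alat < hi)] = b
    return ids
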