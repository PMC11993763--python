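"""Binary ranges from suitability surfaces, and range geometry.

Areas, centroids, migration distances and latitudinal shifts are computed
on the sphere (radius 6371.0088 km); the availability buffer is the set of
grid cells within a great-circle radius of any occurrence record.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ClimateGrid, OccurrenceSet
from .popgen import EARTH_RADIUS_KM, haversine_km


@dataclass
class RangeMap:
    """Binary presence on a grid, with the threshold that produced it."""

    presence: np.ndarray  # boolean, row 0 = southernmost
    origin: tuple[float, float]
    resolution: float
    threshold: float
    season: str = ""
    group: str = ""
    scenario: str = ""

    @property
    def shape(self) -> tuple[int, int]:
        return self.presence.shape

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        nr, nc = self.presence.shape
        lat = self.origin[1] + (np.arange(nr) + 0.5) * self.resolution
        lon = self.origin[0] + (np.arange(nc) + 0.5) * self.resolution
        return np.meshgrid(lon, lat)


def binary_range(grid: ClimateGrid, layer: str, threshold: float,
                 season: str = "", group: str = "") -> RangeMap:
    """Presence where suitability strictly exceeds the threshold.

    Nodata (NaN) cells are absent.
    """
    suit = grid.layers[layer]
    presence = np.where(np.isfinite(suit), suit > threshold, False)
    return RangeMap(presence=presence.astype(bool), origin=grid.origin,
                    resolution=grid.resolution, threshold=threshold,
                    season=season, group=group, scenario=grid.scenario)


def _cell_areas(r: RangeMap) -> np.ndarray:
    """Spherical cell areas (km^2), one value per row, broadcast over cols."""
    nr, nc = r.shape
    lat = r.origin[1] + (np.arange(nr) + 0.5) * r.resolution
    d = np.radians(r.resolution)
    area_row = d * d * EARTH_RADIUS_KM ** 2 * np.cos(np.radians(lat))
    return np.repeat(area_row[:, None], nc, axis=1)


def range_extent(r: RangeMap) -> float:
    """Total area (km^2) of the present cells."""
    return float(_cell_areas(r)[r.presence].sum())


def range_centroid(r: RangeMap) -> tuple[float, float]:
    """Area-weighted spherical centroid (lon, lat) of the present cells.

    Cell-center unit vectors are averaged with area weights, renormalized,
    and converted back to geographic coordinates.
    """
    if not r.presence.any():
        raise ValueError("empty range has no centroid")
    lon, lat = r.cell_centers()
    w = _cell_areas(r)[r.presence]
    lam = np.radians(lon[r.presence])
    phi = np.radians(lat[r.presence])
    vec = np.array([
        (w * np.cos(phi) * np.cos(lam)).sum(),
        (w * np.cos(phi) * np.sin(lam)).sum(),
        (w * np.sin(phi)).sum(),
    ]) / w.sum()
    norm = np.linalg.norm(vec)
    if norm == 0:
        raise ValueError("centroid undefined (antipodal symmetry)")
    vec /= norm
    return (float(np.degrees(np.arctan2(vec[1], vec[0]))),
            float(np.degrees(np.arcsin(np.clip(vec[2], -1, 1)))))


def migration_distance(breeding: RangeMap, nonbreeding: RangeMap) -> float:
    """Great-circle distance (km) between the two range centroids."""
    lon1, lat1 = range_centroid(breeding)
    lon2, lat2 = range_centroid(nonbreeding)
    return float(haversine_km(lon1, lat1, lon2, lat2))


def latitudinal_shift(r1: RangeMap, r2: RangeMap) -> float:
    """Difference (degrees) of the centroid latitudes, r2 - r1."""
    _, lat1 = range_centroid(r1)
    _, lat2 = range_centroid(r2)
    return float(lat2 - lat1)


def buffer_mask(occ: OccurrenceSet, grid: ClimateGrid,
                radius_km: float = 1500.0) -> np.ndarray:
    """Cells whose center lies within ``radius_km`` of any occurrence."""
    lon, lat = grid.cell_centers()
    mask = np.zeros(grid.shape, dtype=bool)
    olon = occ.records["lon"].to_numpy(float)
    olat = occ.records["lat"].to_numpy(float)
    if olon.size == 0:
        return mask
    flat_lon = lon.ravel()
    flat_lat = lat.ravel()
    # chunk over cells to bound memory on big grids
    step = 20000
    flat = mask.ravel()
    for s in range(0, flat_lon.size, step):
        d = haversine_km(flat_lon[s:s + step, None], flat_lat[s:s + step, None],
                         olon[None, :], olat[None, :])
        flat[s:s + step] = (d <= radius_km).any(axis=1)
    return flat.reshape(grid.shape)
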