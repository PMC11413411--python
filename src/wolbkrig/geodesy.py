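"""Great-circle distances and prediction grids over the native range.

Coordinates are unprojected (lat, lon) in decimal degrees; distances are
great-circle kilometres on a sphere, appropriate for a study region
spanning thousands of km across Eurasia.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "EARTH_RADIUS_KM",
    "DEFAULT_BBOX",
    "SiteSet",
    "Grid",
    "haversine_km",
    "distance_matrix",
    "cross_distance_matrix",
    "make_grid",
]

# IUGG mean Earth radius
EARTH_RADIUS_KM = 6371.0088

# Europe + western Russia, generous enough to cover the fly's native range
DEFAULT_BBOX = (34.0, 71.0, -11.0, 61.0)  # (lat_min, lat_max, lon_min, lon_max)


@dataclass(frozen=True)
class SiteSet:
    """An ordered set of (lat, lon) sites in decimal degrees."""

    coordinates: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        for lat, lon in self.coordinates:
            if not (-90.0 <= lat <= 90.0 and -180.0 <= lon <= 180.0):
                raise ValueError(f"coordinate ({lat}, {lon}) out of range")

    @classmethod
    def from_array(cls, arr) -> "SiteSet":
        a = np.asarray(arr, dtype=float).reshape(-1, 2)
        return cls(tuple((float(lat), float(lon)) for lat, lon in a))

    def __len__(self) -> int:
        return len(self.coordinates)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.coordinates, dtype=float).reshape(-1, 2)


@dataclass(frozen=True)
class Grid:
    """A full Cartesian lat/lon lattice over a bounding box."""

    bbox: tuple[float, float, float, float]
    resolution: float
    lats: tuple[float, ...]
    lons: tuple[float, ...]

    @property
    def points(self) -> np.ndarray:
        """(n_lat * n_lon, 2) array of (lat, lon), lat-major order."""
        la, lo = np.meshgrid(self.lats, self.lons, indexing="ij")
        return np.column_stack([la.ravel(), lo.ravel()])

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.lats), len(self.lons))

    def __len__(self) -> int:
        return len(self.lats) * len(self.lons)

    def to_csv(self, path: str | Path) -> None:
        np.savetxt(path, self.points, fmt="%.6f", delimiter=",", header="lat,lon", comments="")

    def to_geojson(self, path: str | Path) -> None:
        features = [
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [float(lon), float(lat)]},
                "properties": {},
            }
            for lat, lon in self.points
        ]
        Path(path).write_text(
            json.dumps({"type": "FeatureCollection", "features": features})
        )


def haversine_km(p1, p2) -> float:
    """Great-circle distance in km between (lat, lon) points (broadcasting)."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    lat1, lon1 = np.radians(p1[..., 0]), np.radians(p1[..., 1])
    lat2, lon2 = np.radians(p2[..., 0]), np.radians(p2[..., 1])
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
    return float(d) if d.ndim == 0 else d


def distance_matrix(sites: SiteSet | np.ndarray) -> np.ndarray:
    """Symmetric matrix of pairwise great-circle distances (km), zero diagonal."""
    arr = sites.as_array() if isinstance(sites, SiteSet) else np.asarray(sites, float).reshape(-1, 2)
    d = haversine_km(arr[:, None, :], arr[None, :, :])
    d = np.atleast_2d(d)
    np.fill_diagonal(d, 0.0)
    return 0.5 * (d + d.T)  # enforce exact symmetry


def cross_distance_matrix(a, b) -> np.ndarray:
    """(len(a), len(b)) great-circle distances between two site arrays."""
    aa = a.as_array() if isinstance(a, SiteSet) else np.asarray(a, float).reshape(-1, 2)
    bb = b.as_array() if isinstance(b, SiteSet) else np.asarray(b, float).reshape(-1, 2)
    return np.atleast_2d(haversine_km(aa[:, None, :], bb[None, :, :]))


def _axis_points(lo: float, hi: float, res: float) -> np.ndarray:
    n = int(np.floor((hi - lo) / res + 1e-9)) + 1
    pts = lo + res * np.arange(n)
    # include the upper boundary when the span is an integer multiple of res
    return np.minimum(pts, hi)


def make_grid(bbox: tuple[float, float, float, float], resolution: float) -> Grid:
    """Build the full lattice over ``bbox = (lat_min, lat_max, lon_min, lon_max)``.

    Both boundary rows/columns are included when the span is an integer
    multiple of the resolution; otherwise the lattice stops at the last
    interior point.
    """
    lat_min, lat_max, lon_min, lon_max = bbox
    if not (lat_min < lat_max and lon_min < lon_max):
        raise ValueError(f"inverted bbox {bbox}")
    if resolution <= 0:
        raise ValueError("resolution must be > 0")
    lats = _axis_points(lat_min, lat_max, resolution)
    lons = _axis_points(lon_min, lon_max, resolution)
    return Grid(bbox=tuple(map(float, bbox)), resolution=float(resolution),
                lats=tuple(lats.tolist()), lons=tuple(lons.tolist()))
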