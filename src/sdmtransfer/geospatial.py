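"""Spherical geometry and equal-area planar grids.

All metric steps of the pipeline (kernel search radii, background lattices)
are defined in kilometres, while tracking fixes and environmental grids live
in geographic coordinates.  This module provides the glue: great-circle
distances on a sphere and a Lambert azimuthal equal-area frame centred on a
population's non-breeding range, in which areas are preserved exactly and
the antimeridian causes no discontinuity.

The Earth is modelled as a sphere of radius 6371.0088 km (the IUGG mean
radius); geolocator location error (~186 km) dwarfs ellipsoidal corrections.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely

EARTH_RADIUS_KM = 6371.0088

__all__ = [
    "EARTH_RADIUS_KM",
    "GeoPoint",
    "EqualAreaFrame",
    "normalize_lon",
    "great_circle_km",
    "haversine_km",
    "grid_points",
]


def normalize_lon(lon):
    """Normalize longitudes into [-180, 180)."""
    return (np.asarray(lon, dtype=float) + 180.0) % 360.0 - 180.0


@dataclass(frozen=True)
class GeoPoint:
    """A geographic position; longitude is normalized into [-180, 180)."""

    lon: float
    lat: float

    def __post_init__(self):
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude {self.lat} outside [-90, 90]")
        object.__setattr__(self, "lon", float(normalize_lon(self.lon)))
        object.__setattr__(self, "lat", float(self.lat))


def haversine_km(lon1, lat1, lon2, lat2):
    """Vectorized great-circle distance (km) between coordinate arrays."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float))
                              for a in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    # clip guards rounding for antipodal points
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def great_circle_km(a: GeoPoint, b: GeoPoint) -> float:
    """Great-circle distance between two points, in kilometres."""
    return float(haversine_km(a.lon, a.lat, b.lon, b.lat))


@dataclass(frozen=True)
class EqualAreaFrame:
    """Lambert azimuthal equal-area projection centred on a region.

    Forward maps (lon, lat) to planar (x, y) in kilometres with the centre
    at the origin; areas are preserved exactly on the sphere.  Points at or
    beyond 90 degrees of arc from the centre (outside the centred
    hemisphere) are rejected: the projection distorts unboundedly there and
    no regional analysis should reach that far.
    """

    center_lon: float
    center_lat: float
    cell_km: float = 25.0

    def __post_init__(self):
        if self.cell_km <= 0:
            raise ValueError("cell_km must be positive")
        object.__setattr__(self, "center_lon", float(normalize_lon(self.center_lon)))

    def forward(self, lon, lat):
        """Project geographic coordinates to planar kilometres."""
        lam0 = np.radians(self.center_lon)
        phi0 = np.radians(self.center_lat)
        lam = np.radians(normalize_lon(lon))
        phi = np.radians(np.asarray(lat, dtype=float))
        cosc = np.sin(phi0) * np.sin(phi) + np.cos(phi0) * np.cos(phi) * np.cos(lam - lam0)
        if np.any(cosc <= 1e-9):
            raise ValueError("point(s) beyond the hemisphere centred on the frame")
        k = np.sqrt(2.0 / (1.0 + cosc))
        x = EARTH_RADIUS_KM * k * np.cos(phi) * np.sin(lam - lam0)
        y = EARTH_RADIUS_KM * k * (np.cos(phi0) * np.sin(phi)
                                   - np.sin(phi0) * np.cos(phi) * np.cos(lam - lam0))
        return x, y

    def inverse(self, x, y):
        """Planar kilometres back to (lon, lat); exact inverse of forward."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        lam0 = np.radians(self.center_lon)
        phi0 = np.radians(self.center_lat)
        rho = np.hypot(x, y)
        with np.errstate(invalid="ignore"):
            c = 2.0 * np.arcsin(np.clip(rho / (2.0 * EARTH_RADIUS_KM), -1.0, 1.0))
        sinc, cosc = np.sin(c), np.cos(c)
        # at rho == 0 the point is the centre itself
        safe_rho = np.where(rho == 0, 1.0, rho)
        phi = np.arcsin(np.clip(cosc * np.sin(phi0)
                                + y * sinc * np.cos(phi0) / safe_rho, -1.0, 1.0))
        lam = lam0 + np.arctan2(x * sinc,
                                safe_rho * np.cos(phi0) * cosc - y * np.sin(phi0) * sinc)
        lon = normalize_lon(np.degrees(lam))
        lat = np.degrees(phi)
        lon = np.where(rho == 0, self.center_lon, lon)
        lat = np.where(rho == 0, self.center_lat, lat)
        return lon, lat

    def project_points(self, points) -> np.ndarray:
        """Project an iterable of GeoPoint to an (n, 2) planar array."""
        lons = np.array([p.lon for p in points], dtype=float)
        lats = np.array([p.lat for p in points], dtype=float)
        x, y = self.forward(lons, lats)
        return np.column_stack([x, y])


def frame_for(lons, lats, cell_km: float = 25.0) -> EqualAreaFrame:
    """Frame centred on the spherical centroid of a point cloud."""
    lam = np.radians(normalize_lon(lons))
    phi = np.radians(np.asarray(lats, dtype=float))
    cx = np.mean(np.cos(phi) * np.cos(lam))
    cy = np.mean(np.cos(phi) * np.sin(lam))
    cz = np.mean(np.sin(phi))
    lon0 = np.degrees(np.arctan2(cy, cx))
    lat0 = np.degrees(np.arctan2(cz, np.hypot(cx, cy)))
    return EqualAreaFrame(center_lon=float(lon0), center_lat=float(lat0), cell_km=cell_km)


def grid_points(polygon, spacing_km: float) -> np.ndarray:
    """Uniform square lattice of points inside a planar polygon.

    The lattice is anchored at the polygon bounding box's lower-left corner,
    offset by half a spacing so each point represents the centre of a
    spacing x spacing cell (one point per spacing^2 of area).  Points on the
    polygon boundary are kept (closed-polygon convention).  Returns an
    (n, 2) array of planar km coordinates; deterministic for fixed inputs.
    """
    if spacing_km <= 0:
        raise ValueError("spacing_km must be positive")
    if polygon is None or polygon.is_empty:
        return np.empty((0, 2), dtype=float)
    minx, miny, maxx, maxy = polygon.bounds
    xs = np.arange(minx + spacing_km / 2.0, maxx, spacing_km)
    ys = np.arange(miny + spacing_km / 2.0, maxy, spacing_km)
    if xs.size == 0 or ys.size == 0:
        return np.empty((0, 2), dtype=float)
    gx, gy = np.meshgrid(xs, ys)
    pts = shapely.points(gx.ravel(), gy.ravel())
    keep = shapely.covered_by(pts, polygon)
    return np.column_stack([gx.ravel()[keep], gy.ravel()[keep]])
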