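"""Kernel density surfaces and point-containment utilization contours.

The use-availability design rests on two contour levels: per-month 50%
contours delimit core habitat (fixes inside become presences) and a pooled
seasonal 90% contour delimits the available range (a uniform lattice inside
becomes the background sample).

The kernel is the quartic (biweight) kernel truncated at the search radius,
the convention of the GIS tools this style of seabird analysis was developed
with: for a point at distance d <= r the contribution to the density is
3/(pi r^2) (1 - (d/r)^2)^2, so each fix integrates to one and the surface
integral equals the number of fixes.

Contours are *point-containment* contours: the threshold is the highest
density value t such that the fixes lying in cells with density >= t make up
at least the requested percentage of all fixes.  Polygons follow cell
boundaries of the density grid and are closed (boundary points count as
inside).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy import ndimage

from .geospatial import EqualAreaFrame, frame_for
from .tracks import SEASON_MONTHS, TrackSet

__all__ = [
    "UtilizationSurface",
    "ContourSet",
    "kernel_density",
    "containment_contour",
    "monthly_core_contours",
    "seasonal_availability_contour",
]


@dataclass
class UtilizationSurface:
    """Gridded kernel density in an equal-area frame.

    ``values[i, j]`` is the density (fixes per km^2) at the centre of the
    cell whose lower-left corner is ``(x0 + j*cell_km, y0 + i*cell_km)``.
    """

    frame: EqualAreaFrame
    cell_km: float
    x0: float
    y0: float
    values: np.ndarray

    def cell_index(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Row/column indices of the cells containing planar points."""
        j = np.floor((np.asarray(x) - self.x0) / self.cell_km).astype(int)
        i = np.floor((np.asarray(y) - self.y0) / self.cell_km).astype(int)
        ny, nx = self.values.shape
        return np.clip(i, 0, ny - 1), np.clip(j, 0, nx - 1)

    def value_at(self, x, y) -> np.ndarray:
        i, j = self.cell_index(x, y)
        return self.values[i, j]

    @property
    def integral(self) -> float:
        """Surface integral (should equal the number of source fixes)."""
        return float(self.values.sum() * self.cell_km**2)


@dataclass
class ContourSet:
    """Super-level-set polygons containing a stated fraction of fixes."""

    level: float
    threshold: float
    polygons: list
    contained_fraction: float
    frame: EqualAreaFrame
    mask: np.ndarray = field(repr=False, default=None)

    @property
    def union(self):
        return shapely.union_all(self.polygons)

    @property
    def area_km2(self) -> float:
        return float(sum(p.area for p in self.polygons))

    def contains_xy(self, x, y) -> np.ndarray:
        """Closed containment test for planar points (boundary is inside)."""
        pts = shapely.points(np.asarray(x, float), np.asarray(y, float))
        return shapely.covered_by(pts, self.union)

    def contains_lonlat(self, lon, lat) -> np.ndarray:
        x, y = self.frame.forward(lon, lat)
        return self.contains_xy(x, y)

    @property
    def __geo_interface__(self):
        return shapely.geometry.mapping(self.union)

    def to_geojson(self) -> dict:
        """GeoJSON Feature (planar frame coordinates, km) with metadata."""
        return {"type": "Feature",
                "geometry": shapely.geometry.mapping(self.union),
                "properties": {"level_pct": self.level,
                               "threshold": self.threshold,
                               "contained_fraction": self.contained_fraction,
                               "crs": {"type": "lambert_azimuthal_equal_area_km",
                                       "center_lon": self.frame.center_lon,
                                       "center_lat": self.frame.center_lat}}}


def kernel_density(points_xy: np.ndarray, radius_km: float, cell_km: float,
                   frame: EqualAreaFrame) -> UtilizationSurface:
    """Truncated quartic kernel density of planar points.

    Parameters
    ----------
    points_xy : (n, 2) array
        Planar coordinates (km) in ``frame``.
    radius_km : float
        Kernel truncation ("search") radius; 200 km is the analysis default.
    cell_km : float
        Output cell size; must be at most radius_km / 4 so the kernel is
        resolved by the grid.
    """
    pts = np.atleast_2d(np.asarray(points_xy, dtype=float))
    if pts.size == 0:
        raise ValueError("kernel_density requires at least one point")
    if radius_km <= 0:
        raise ValueError("radius_km must be positive")
    if cell_km > radius_km / 4.0:
        raise ValueError("cell_km must be <= radius_km / 4 to resolve the kernel")

    pad = radius_km + cell_km
    x0 = np.floor((pts[:, 0].min() - pad) / cell_km) * cell_km
    y0 = np.floor((pts[:, 1].min() - pad) / cell_km) * cell_km
    nx = int(np.ceil((pts[:, 0].max() + pad - x0) / cell_km)) + 1
    ny = int(np.ceil((pts[:, 1].max() + pad - y0) / cell_km)) + 1
    values = np.zeros((ny, nx), dtype=float)

    # cell-centre coordinate of column j is x0 + (j + 0.5) * cell
    half = int(np.ceil(radius_km / cell_km)) + 1
    norm = 3.0 / (np.pi * radius_km**2)
    for px, py in pts:
        jc = int(np.floor((px - x0) / cell_km))
        ic = int(np.floor((py - y0) / cell_km))
        j0, j1 = max(jc - half, 0), min(jc + half + 1, nx)
        i0, i1 = max(ic - half, 0), min(ic + half + 1, ny)
        cx = x0 + (np.arange(j0, j1) + 0.5) * cell_km
        cy = y0 + (np.arange(i0, i1) + 0.5) * cell_km
        d2 = ((cx[None, :] - px) ** 2 + (cy[:, None] - py) ** 2) / radius_km**2
        u = 1.0 - d2
        np.maximum(u, 0.0, out=u)
        values[i0:i1, j0:j1] += norm * u * u
    return UtilizationSurface(frame=frame, cell_km=cell_km, x0=x0, y0=y0, values=values)


def _mask_polygons(mask: np.ndarray, surface: UtilizationSurface) -> list:
    """Polygons covering the True cells, following cell boundaries."""
    ii, jj = np.nonzero(mask)
    if ii.size == 0:
        return []
    c = surface.cell_km
    boxes = shapely.box(surface.x0 + jj * c, surface.y0 + ii * c,
                        surface.x0 + (jj + 1) * c, surface.y0 + (ii + 1) * c)
    union = shapely.coverage_union_all(boxes)
    geoms = shapely.get_parts(union) if union.geom_type == "MultiPolygon" else [union]
    return [g for g in geoms if not g.is_empty]


def containment_contour(surface: UtilizationSurface, points_xy: np.ndarray,
                        level: float) -> ContourSet:
    """Smallest super-level set of the surface containing level% of points.

    The threshold is maximal among thresholds achieving the containment
    (ties broken toward the smallest area).  A degenerate surface with all
    mass in one cell yields that cell's boundary as the contour.
    """
    if not 0.0 < level < 100.0:
        raise ValueError("level must be strictly between 0 and 100 percent")
    pts = np.atleast_2d(np.asarray(points_xy, dtype=float))
    v = surface.value_at(pts[:, 0], pts[:, 1])
    n = len(v)
    order = np.sort(np.unique(v))[::-1]  # candidate thresholds, descending
    need = level / 100.0 * n
    counts = np.array([(v >= t).sum() for t in order])
    k = int(np.argmax(counts >= need))
    if counts[k] < need:  # pragma: no cover - counts end at n >= need
        k = len(order) - 1
    t = float(order[k])
    mask = surface.values >= t
    contained = float((v >= t).sum()) / n
    polys = _mask_polygons(mask, surface)
    return ContourSet(level=float(level), threshold=t, polygons=polys,
                      contained_fraction=contained, frame=surface.frame, mask=mask)


def monthly_core_contours(tracks: TrackSet, months=None, *, level: float = 50.0,
                          radius_km: float = 200.0, cell_km: float = 25.0,
                          frame: EqualAreaFrame | None = None,
                          min_points: int = 20) -> dict[int, ContourSet]:
    """Per-month core (default 50%) contours from that month's fixes only.

    Months with fewer than ``min_points`` fixes are skipped with a warning.
    All months share one frame (centred on the pooled fixes) so contours are
    mutually comparable.
    """
    months = list(months) if months is not None else tracks.months
    if frame is None:
        lon, lat = tracks.lonlat()
        frame = frame_for(lon, lat, cell_km=cell_km)
    out: dict[int, ContourSet] = {}
    for m in months:
        sub = tracks.month_subset(m)
        if len(sub) < min_points:
            warnings.warn(f"month {m}: only {len(sub)} fixes (< {min_points}); skipped")
            continue
        x, y = frame.forward(sub["lon"].to_numpy(), sub["lat"].to_numpy())
        pts = np.column_stack([x, y])
        surf = kernel_density(pts, radius_km, cell_km, frame)
        out[m] = containment_contour(surf, pts, level)
    return out


def seasonal_availability_contour(tracks: TrackSet, *, level: float = 90.0,
                                  radius_km: float = 200.0, cell_km: float = 25.0,
                                  frame: EqualAreaFrame | None = None) -> ContourSet:
    """Pooled-season availability (default 90%) contour.

    The design calls for a *contiguous* available range.  The density
    support (cells of positive density) is split into connected components;
    when the component holding the most fixes can satisfy the containment
    level on its own, the contour is built from that component alone — its
    threshold is the highest density at which the fixes inside it still
    amount to the requested share of *all* fixes, so dense outlying specks
    are excluded.  Only when no single component suffices are components
    retained in decreasing point-count order until the level is reached.
    """
    lon, lat = tracks.lonlat()
    if frame is None:
        frame = frame_for(lon, lat, cell_km=cell_km)
    x, y = frame.forward(lon, lat)
    pts = np.column_stack([x, y])
    surf = kernel_density(pts, radius_km, cell_km, frame)
    need = level / 100.0 * len(pts)

    support, nsup = ndimage.label(surf.values > 0)
    i, j = surf.cell_index(pts[:, 0], pts[:, 1])
    pt_support = support[i, j]
    sup_counts = np.bincount(pt_support, minlength=nsup + 1)[1:]
    if nsup > 1 and sup_counts.max() >= need:
        main = int(np.argmax(sup_counts)) + 1
        in_main = pt_support == main
        v = surf.value_at(pts[:, 0], pts[:, 1])
        # highest threshold whose in-main super-level fixes cover level% of all
        cand = np.sort(np.unique(v[in_main]))[::-1]
        counts = np.array([(in_main & (v >= t)).sum() for t in cand])
        t = float(cand[int(np.argmax(counts >= need))])
        mask = (surf.values >= t) & (support == main)
        contained = float((in_main & (v >= t)).sum()) / len(pts)
        return ContourSet(level=float(level), threshold=t,
                          polygons=_mask_polygons(mask, surf),
                          contained_fraction=contained, frame=frame, mask=mask)

    contour = containment_contour(surf, pts, level)
    labels, nlab = ndimage.label(contour.mask)
    if nlab > 1:
        pt_labels = labels[i, j]
        counts = np.bincount(pt_labels, minlength=nlab + 1)[1:]  # per component
        order = np.argsort(counts)[::-1] + 1
        keep, got = [], 0
        for lab in order:
            keep.append(lab)
            got += counts[lab - 1]
            if got >= need:
                break
        mask = np.isin(labels, keep)
        contained = float(np.isin(pt_labels, keep).sum()) / len(pts)
        contour = ContourSet(level=contour.level, threshold=contour.threshold,
                             polygons=_mask_polygons(mask, surf),
                             contained_fraction=contained, frame=frame, mask=mask)
    return contour
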