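"""Gridded environmental covariate stacks.

A CovariateStack is an :class:`xarray.Dataset` on a regular 0.5-degree grid
holding the habitat-model predictors: four static layers (``depth`` m,
``slope`` degrees, ``geomorph`` seafloor-class code, ``dist_seamount`` m)
on (lat, lon) and five monthly dynamic layers (``mld`` m, ``t050`` degC,
``curr`` m/s, ``eke`` (cm/s)^2, ``chl`` mg/m^3) on (month, lat, lon).

Longitude coordinates may be "unwrapped" past 180 degrees so that grids
spanning the antimeridian stay monotonic; extraction re-wraps query
longitudes accordingly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import xarray as xr

STATIC_VARS = ("depth", "slope", "geomorph", "dist_seamount")
DYNAMIC_VARS = ("mld", "t050", "curr", "eke", "chl")
COVARIATE_COLUMNS = STATIC_VARS + DYNAMIC_VARS

#: predictors treated as unordered factors in models
CATEGORICAL_COVARIATES = ("geomorph",)

GEOMORPH_CLASSES = ("plain", "basin", "hills", "ridge", "seamount")

RESOLUTION_DEG = 0.5


def validate_stack(env: xr.Dataset) -> None:
    for v in STATIC_VARS:
        if v not in env or set(env[v].dims) != {"lat", "lon"}:
            raise ValueError(f"static layer {v!r} missing or mis-dimensioned")
    for v in DYNAMIC_VARS:
        if v not in env or set(env[v].dims) != {"month", "lat", "lon"}:
            raise ValueError(f"dynamic layer {v!r} missing or mis-dimensioned")


def _wrap_to_grid(lon: np.ndarray, lon0: float) -> np.ndarray:
    """Map longitudes onto the grid's (possibly unwrapped) branch."""
    return lon0 + np.mod(np.asarray(lon, dtype=float) - lon0, 360.0)


def nearest_cell_index(env: xr.Dataset, lon, lat):
    """Nearest-cell (row, col) indices; -1 where outside the grid extent."""
    lons = env["lon"].to_numpy()
    lats = env["lat"].to_numpy()
    res_lon = float(np.median(np.diff(lons)))
    res_lat = float(np.median(np.diff(lats)))
    ql = _wrap_to_grid(lon, lons[0] - res_lon / 2.0)
    j = np.round((ql - lons[0]) / res_lon).astype(int)
    i = np.round((np.asarray(lat, dtype=float) - lats[0]) / res_lat).astype(int)
    ok = (j >= 0) & (j < lons.size) & (i >= 0) & (i < lats.size)
    return np.where(ok, i, -1), np.where(ok, j, -1)


def extract(env: xr.Dataset, lon, lat, month) -> pd.DataFrame:
    """Nearest-cell covariate values for point locations.

    ``month`` may be a scalar or a per-point array; dynamic layers are
    sampled from their month-matched slice, static layers are
    month-invariant.  Points outside the grid get NaN in every column.
    """
    lon = np.atleast_1d(np.asarray(lon, dtype=float))
    lat = np.atleast_1d(np.asarray(lat, dtype=float))
    month = np.broadcast_to(np.atleast_1d(month), lon.shape).astype(int)
    i, j = nearest_cell_index(env, lon, lat)
    inside = i >= 0
    out = {}
    for v in STATIC_VARS:
        arr = env[v].to_numpy()
        col = np.full(lon.shape, np.nan)
        col[inside] = arr[i[inside], j[inside]]
        out[v] = col
    months_axis = env["month"].to_numpy()
    for v in DYNAMIC_VARS:
        arr = env[v].to_numpy()
        col = np.full(lon.shape, np.nan)
        for m in np.unique(month):
            pos = np.nonzero(months_axis == m)[0]
            sel = inside & (month == m)
            if pos.size == 0:
                continue  # month not covered -> stays NaN
            col[sel] = arr[pos[0], i[sel], j[sel]]
        out[v] = col
    return pd.DataFrame(out)


def grid_dataframe(env: xr.Dataset, month: int) -> pd.DataFrame:
    """All grid cells as covariate rows (lon, lat + covariate columns)."""
    lons = env["lon"].to_numpy()
    lats = env["lat"].to_numpy()
    glon, glat = np.meshgrid(lons, lats)
    df = extract(env, glon.ravel(), glat.ravel(), month)
    df.insert(0, "lat", glat.ravel())
    # report longitudes re-normalized into [-180, 180)
    df.insert(0, "lon", (glon.ravel() + 180.0) % 360.0 - 180.0)
    return df
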