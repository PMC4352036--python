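"""Project fitted habitat models onto covariate grids.

A suitability raster is the per-cell predicted probability of use for one
month, masked wherever any model covariate is missing.  Rasters are pure
functions of (model, covariate stack, month) and are bit-identical on
rerun.
"""

from __future__ import annotations

import numpy as np
import xarray as xr

from . import covariates as cov
from .density import ContourSet


def predict_map(model, env: xr.Dataset, month: int) -> xr.DataArray:
    """Predicted habitat suitability on the stack's grid for one month.

    Cells with any missing covariate are NaN; all other values lie in
    (0, 1).  Raises if a model predictor has no layer in the stack.
    """
    for p in model.predictors:
        if p != "month" and p not in env:
            raise KeyError(f"covariate stack lacks model predictor {p!r}")
    if month not in set(np.atleast_1d(env["month"].to_numpy())):
        raise KeyError(f"covariate stack lacks month {month}")
    df = cov.grid_dataframe(env, month)
    df["month"] = month
    needed = [p for p in model.predictors if p != "month"]
    valid = df[needed].notna().all(axis=1)
    out = np.full(len(df), np.nan)
    if valid.any():
        out[valid.to_numpy()] = model.predict(df[valid])
    ny, nx = env["lat"].size, env["lon"].size
    da = xr.DataArray(out.reshape(ny, nx),
                      coords={"lat": env["lat"], "lon": env["lon"]},
                      dims=("lat", "lon"), name="suitability",
                      attrs={"month": int(month)})
    da.attrs["masked_fraction"] = float(np.isnan(out).mean())
    return da


def overlay_report(raster: xr.DataArray, contours: list[ContourSet]) -> list[dict]:
    """Mean/median suitability inside vs outside each contour.

    Quantifies the visual raster-vs-distribution comparison: an
    interpolating model should predict higher suitability inside a
    population's contours than outside.
    """
    lons = raster["lon"].to_numpy()
    lats = raster["lat"].to_numpy()
    glon, glat = np.meshgrid(lons, lats)
    vals = raster.to_numpy().ravel()
    ok = ~np.isnan(vals)
    reports = []
    for c in contours:
        # project only cells within the contour frame's hemisphere
        lon_ok, lat_ok = glon.ravel()[ok], glat.ravel()[ok]
        v = vals[ok]
        lam0 = np.radians(c.frame.center_lon)
        phi0 = np.radians(c.frame.center_lat)
        cosc = (np.sin(phi0) * np.sin(np.radians(lat_ok))
                + np.cos(phi0) * np.cos(np.radians(lat_ok))
                * np.cos(np.radians(lon_ok) - lam0))
        hemi = cosc > 1e-6
        inside = np.zeros(v.shape, dtype=bool)
        if hemi.any():
            inside[hemi] = c.contains_lonlat(lon_ok[hemi], lat_ok[hemi])
        rep = {"level": c.level,
               "n_inside": int(inside.sum()), "n_outside": int((~inside).sum())}
        if inside.sum() == 0:
            rep["note"] = "empty intersection between raster and contour"
            reports.append(rep)
            continue
        rep.update(
            mean_inside=float(np.mean(v[inside])),
            mean_outside=float(np.mean(v[~inside])),
            median_inside=float(np.median(v[inside])),
            median_outside=float(np.median(v[~inside])),
        )
        reports.append(rep)
    return reports
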