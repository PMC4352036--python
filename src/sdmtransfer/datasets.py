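"""Presence/background sample tables for use-availability habitat models.

Presences are tracking fixes falling inside their own month's 50% core
contour; the background is one fixed 100-km lattice over the pooled-season
90% availability contour, replicated for every month (same coordinates,
month-matched covariates).  A per-month withholding rule (20% of presences,
100 backgrounds) yields external validation sets, and multiple populations
can be concatenated into a weighted combined table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import covariates as cov
from .density import ContourSet
from .geospatial import grid_points
from .tracks import SEASON_MONTHS, TrackSet

log = logging.getLogger(__name__)

#: column order for SampleTable CSV round-trips
SAMPLE_COLUMNS = ["label", "month", "weight", "population", "lon", "lat",
                  *cov.COVARIATE_COLUMNS]


def round_half_away(x) -> np.ndarray:
    """Round to the nearest integer, halves away from zero."""
    x = np.asarray(x, dtype=float)
    return (np.sign(x) * np.floor(np.abs(x) + 0.5)).astype(int)


@dataclass(frozen=True)
class SplitSpec:
    """Per-month withholding rule for external validation."""

    presence_withhold_fraction: float = 0.20
    background_withhold_per_month: int = 100
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.presence_withhold_fraction < 1.0:
            raise ValueError("presence_withhold_fraction must be in [0, 1)")
        if self.background_withhold_per_month < 0:
            raise ValueError("background_withhold_per_month must be >= 0")


def build_presences(tracks: TrackSet, cores: dict[int, ContourSet],
                    population: str | None = None) -> pd.DataFrame:
    """Label-1 rows: one per fix inside its own month's core contour.

    Boundary fixes count as inside (closed polygons).  Raises if any month
    present in the tracks lacks a contour.
    """
    rows = []
    for m in tracks.months:
        if m not in cores:
            raise ValueError(f"no core contour supplied for month {m}")
        sub = tracks.month_subset(m)
        inside = cores[m].contains_lonlat(sub["lon"].to_numpy(), sub["lat"].to_numpy())
        kept = sub[inside]
        log.info("month %d: %d of %d fixes inside the %s%% contour",
                 m, len(kept), len(sub), cores[m].level)
        rows.append(pd.DataFrame({
            "label": 1, "month": m, "weight": 1.0,
            "population": population or ",".join(tracks.colonies),
            "lon": kept["lon"].to_numpy(), "lat": kept["lat"].to_numpy(),
        }))
    return pd.concat(rows, ignore_index=True)


def build_background(availability: ContourSet, months,
                     spacing_km: float = 100.0,
                     population: str | None = None) -> pd.DataFrame:
    """Label-0 rows: one fixed lattice in the 90% contour, per month.

    The lattice deliberately extends *throughout* the core polygons (the
    background characterizes availability, not absence).  Coordinates are
    identical across months; only the dynamic covariates will differ.
    """
    union = availability.union
    pts = grid_points(union, spacing_km)
    if len(pts) == 0:
        raise ValueError("background lattice is empty; contour too small for spacing")
    lon, lat = availability.frame.inverse(pts[:, 0], pts[:, 1])
    months = list(months)
    rows = [pd.DataFrame({
        "label": 0, "month": m, "weight": 1.0,
        "population": population or "", "lon": lon, "lat": lat,
    }) for m in months]
    return pd.concat(rows, ignore_index=True)


def annotate_covariates(table: pd.DataFrame, env) -> pd.DataFrame:
    """Attach nearest-cell covariates; drop rows with any missing value.

    Dynamic layers are month-matched (a November row samples the November
    climatology).  The number of dropped rows is logged.
    """
    vals = cov.extract(env, table["lon"].to_numpy(), table["lat"].to_numpy(),
                       table["month"].to_numpy())
    out = pd.concat([table.reset_index(drop=True), vals], axis=1)
    complete = out[list(cov.COVARIATE_COLUMNS)].notna().all(axis=1)
    n_drop = int((~complete).sum())
    if n_drop:
        log.warning("dropped %d rows with missing covariates (of %d)", n_drop, len(out))
    return out[complete].reset_index(drop=True)


def withhold_split(table: pd.DataFrame, spec: SplitSpec
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Withhold per month: round(fraction x presences) and exactly N backgrounds.

    Presence rounding is half-away-from-zero.  Train and test are disjoint
    with union equal to the input; the draw is deterministic for a fixed
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    test_idx = []
    for m in [mm for mm in SEASON_MONTHS if mm in set(table["month"])]:
        pres = table.index[(table["month"] == m) & (table["label"] == 1)]
        back = table.index[(table["month"] == m) & (table["label"] == 0)]
        n_p = int(round_half_away(spec.presence_withhold_fraction * len(pres)))
        n_b = spec.background_withhold_per_month
        if len(back) < n_b:
            raise ValueError(
                f"month {m}: {len(back)} background rows < withhold count {n_b}")
        test_idx.extend(rng.choice(pres, size=n_p, replace=False))
        test_idx.extend(rng.choice(back, size=n_b, replace=False))
    test_mask = table.index.isin(test_idx)
    return (table[~test_mask].reset_index(drop=True),
            table[test_mask].reset_index(drop=True))


def combine_populations(tables: list[pd.DataFrame],
                        balance: str = "row-balance") -> pd.DataFrame:
    """Concatenate population tables with balancing weights.

    ``balance="row-balance"`` re-weights each table by (smallest table's row
    count / its own row count), so every population contributes equal total
    weight.  ``balance="fixed:W"`` multiplies the weights of every table
    except the smallest by W (e.g. ``fixed:0.76`` to down-weight the larger
    population by a externally chosen factor).
    """
    if len(tables) < 2:
        raise ValueError("need at least two population tables to combine")
    for t in tables:
        if len(t) == 0:
            raise ValueError("cannot combine an empty population table")
    pops = [t["population"].iloc[0] for t in tables]
    if len(set(pops)) != len(pops):
        raise ValueError("population tags must be disjoint")
    sizes = np.array([len(t) for t in tables])
    out = []
    for t, n in zip(tables, sizes):
        t = t.copy()
        if balance == "row-balance":
            t["weight"] = t["weight"] * (sizes.min() / n)
        elif balance.startswith("fixed:"):
            w = float(balance.split(":", 1)[1])
            if n > sizes.min():
                t["weight"] = t["weight"] * w
        else:
            raise ValueError(f"unknown balance strategy {balance!r}")
        out.append(t)
    return pd.concat(out, ignore_index=True)


def write_sample_table(table: pd.DataFrame, path) -> None:
    cols = [c for c in SAMPLE_COLUMNS if c in table.columns]
    table[cols].to_csv(path, index=False)


def read_sample_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
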