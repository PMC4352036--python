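"""Synthetic ocean covariate stacks and geolocator-like tracking data.

The generator produces the raw material for an end-to-end transferability
experiment without any downloads: three Southern Ocean regions share one
latent habitat-suitability truth but expose *shifted covariate availability
windows* — the lever that makes a model interpolate well at home yet fail
when transferred, because each population's realized selection is learned
over its own region's slice of environmental space.

Covariate fields are Gaussian-filtered noise plus deterministic structure
(poleward-cooling temperature, a mid-region bathymetric ridge, an eddy
kinetic energy jet); dynamic layers are month-to-month autocorrelated
(rho = 0.8, climatology-like).  Tracks are sampled points, not a movement
model: at geolocator accuracy (~186 km error SD, two fixes per day) a
step-length model is unidentifiable, so bird-days draw locations with
probability proportional to truth times an isotropic availability kernel
(exponential decay, ~5000 km range) around a per-bird centroid that drifts
poleward through the season.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import xarray as xr
from scipy.ndimage import gaussian_filter

from .covariates import DYNAMIC_VARS, GEOMORPH_CLASSES
from .geospatial import haversine_km, normalize_lon
from .tracks import SEASON_MONTHS, TrackSet

KM_PER_DEG = 111.19493  # spherical degree of latitude


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


@dataclass(frozen=True)
class TruthParams:
    """Latent suitability response: logit-additive effects per covariate.

    Defaults encode a pelagic forager preferring upper-ocean temperatures
    around 10 degC (the 7-13 degC band), mixed layer depths of 50-100 m,
    moderate currents peaking near 0.2 m/s, avoidance of high eddy kinetic
    energy, a mild preference for shallower abyssal depths, and no month
    effect.
    """

    intercept: float = -6.0
    t050_opt: float = 10.0
    t050_width: float = 3.0
    t050_amp: float = 6.0
    mld_lo: float = 50.0
    mld_hi: float = 100.0
    mld_soft: float = 8.0
    mld_amp: float = 6.5
    curr_opt: float = 0.2
    curr_width: float = 0.12
    curr_amp: float = 4.0
    eke_threshold: float = 300.0
    eke_scale: float = 120.0
    eke_amp: float = -4.0
    depth_ref: float = -4500.0
    depth_scale: float = 800.0
    depth_amp: float = 1.6
    month_effect: tuple = ()  # optional ((month, logit_shift), ...)

    def __post_init__(self):
        if min(self.t050_width, self.curr_width, self.mld_soft,
               self.eke_scale, self.depth_scale) <= 0:
            raise ValueError("response widths/scales must be positive")

    def logit(self, depth, mld, t050, curr, eke, month=None):
        z = np.full(np.broadcast(depth, t050).shape, self.intercept, dtype=float)
        z += self.t050_amp * np.exp(-0.5 * ((t050 - self.t050_opt) / self.t050_width) ** 2)
        z += self.mld_amp * (_sigmoid((mld - self.mld_lo) / self.mld_soft)
                             * _sigmoid((self.mld_hi - mld) / self.mld_soft))
        z += self.curr_amp * np.exp(-0.5 * ((curr - self.curr_opt) / self.curr_width) ** 2)
        z += self.eke_amp * _sigmoid((eke - self.eke_threshold) / self.eke_scale)
        z += self.depth_amp * np.clip((depth - self.depth_ref) / self.depth_scale,
                                      -1.0, 1.0)
        if month is not None:
            z += dict(self.month_effect).get(month, 0.0)
        return z


@dataclass(frozen=True)
class GLSNoise:
    """Geolocator sampling: per-axis location error SD (km), fixes per day."""

    sd_km: float = 186.0
    fixes_per_day: int = 2

    def __post_init__(self):
        if self.sd_km < 0:
            raise ValueError("location error SD must be non-negative")


@dataclass(frozen=True)
class RegionSpec:
    """One study region: extent, colony, bird sample, covariate windows.

    ``lon_max`` may exceed 180 so extents crossing the antimeridian remain
    monotonic ("unwrapped" longitudes).  ``windows`` maps each generated
    layer to the (low, high) value range it occupies in this region — the
    transferability lever.
    """

    name: str
    colony_lon: float
    colony_lat: float
    lon_min: float
    lon_max: float
    lat_min: float
    lat_max: float
    n_birds: int
    windows: dict = field(default_factory=dict)
    months: tuple = SEASON_MONTHS

    def __post_init__(self):
        if not (-65.0 <= self.lat_min < self.lat_max <= -25.0):
            raise ValueError("region latitudes must lie in the 25-65 S band")
        if self.lon_min >= self.lon_max:
            raise ValueError("lon_min must be < lon_max (unwrap across 180 if needed)")


DEFAULT_WINDOWS = {
    # Each region's windows place *different* covariates inside the
    # informative zones of the shared truth, and park the others in zones
    # where the response is flat.  That is the transferability lever: every
    # model interpolates on the contrasts its own region exposes, and sees
    # only flat (or unseen, hence constant-extrapolated) responses in the
    # other regions.
    #
    # region A: cool temperate, shallow mixed layers, quiet eddy field -
    # temperature, MLD and depth carry the habitat contrast
    "pacific": {"depth": (-5500, -3000), "t050": (4, 16), "mld": (20, 85),
                "curr": (0.5, 0.9), "eke": (700, 1500), "chl": (0.05, 0.5)},
    # region B: warm water over the falling edge of the MLD response -
    # MLD, current speed and eddy kinetic energy carry the contrast, with
    # no overlap with the zones region A exposes
    "indian": {"depth": (-2700, -1700), "t050": (17, 25), "mld": (95, 170),
               "curr": (0.0, 0.7), "eke": (50, 600), "chl": (0.6, 1.2)},
    # region C: the small transfer-test population; every response flat, so
    # its realized distribution is availability-driven
    "atlantic": {"depth": (-6400, -5700), "t050": (18, 26), "mld": (180, 320),
                 "curr": (0.55, 0.95), "eke": (750, 1600), "chl": (1.4, 2.2)},
}


def response_range(truth: TruthParams, covariate: str,
                   window: tuple[float, float], n: int = 201) -> float:
    """Logit range of one covariate's truth response over a value window.

    Measures how much habitat contrast the covariate can express inside a
    region: the peak-to-trough span of its additive response term evaluated
    across the window, other covariates held fixed.
    """
    lo, hi = window
    grid = np.linspace(lo, hi, n)
    ref = dict(depth=truth.depth_ref, mld=0.0, t050=truth.t050_opt,
               curr=truth.curr_opt, eke=0.0)
    args = {k: np.full(n, v) for k, v in ref.items()}
    if covariate not in args:
        return 0.0
    args[covariate] = grid
    z = truth.logit(args["depth"], args["mld"], args["t050"],
                    args["curr"], args["eke"])
    return float(np.ptp(z))


def informative_predictors(region: RegionSpec, truth: TruthParams | None = None,
                           threshold: float = 0.5
                           ) -> tuple[list[str], list[str]]:
    """Split a region's covariates into informative and pure-noise sets.

    A covariate is *informative* when its truth response spans more than
    ``threshold`` logit units across the region's availability window.
    *Pure noise* covariates carry no truth response at all: chlorophyll,
    distance from seamount and month everywhere, plus slope and
    geomorphology class when depth (which they derive from) is itself
    uninformative in the region.  Truth covariates whose window sits in a
    flat zone of the response fall in neither set: they cannot be learned
    locally, but the surrounding field structure can still lend them
    spurious influence, so no retention claim is made about them.
    """
    truth = truth if truth is not None else TruthParams()
    informative = []
    for c in ("depth", "mld", "t050", "curr", "eke"):
        if response_range(truth, c, region.windows[c]) >= threshold:
            informative.append(c)
    pure_noise = ["chl", "dist_seamount", "month"]
    if "depth" not in informative:
        pure_noise.extend(["slope", "geomorph"])
    return informative, pure_noise


def default_regions() -> list[RegionSpec]:
    """Three-region design: two fitted populations and one transfer target."""
    return [
        RegionSpec("pacific", 179.0, -49.7, 165.0, 235.0, -58.0, -32.0,
                   n_birds=18, windows=DEFAULT_WINDOWS["pacific"]),
        RegionSpec("indian", 69.9, -49.4, 60.0, 130.0, -58.0, -32.0,
                   n_birds=9, windows=DEFAULT_WINDOWS["indian"]),
        RegionSpec("atlantic", 37.9, -46.6, -15.0, 55.0, -58.0, -32.0,
                   n_birds=4, windows=DEFAULT_WINDOWS["atlantic"]),
    ]


def _smooth01(rng, shape, sigma):
    f = gaussian_filter(rng.standard_normal(shape), sigma, mode="nearest")
    f -= f.min()
    ptp = np.ptp(f)
    return f / ptp if ptp > 0 else f


def generate_env(region: RegionSpec, seed: int, resolution: float = 0.5) -> xr.Dataset:
    """Covariate stack for a region: smooth random fields with structure.

    Temperature carries a dominant poleward-cooling gradient; bathymetry a
    meridional ridge; eddy kinetic energy a zonal jet.  Every layer is
    rescaled into the region's window, so value ranges are inside the
    windows by construction.  Bit-identical for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    lons = np.arange(region.lon_min + resolution / 2, region.lon_max, resolution)
    lats = np.arange(region.lat_min + resolution / 2, region.lat_max, resolution)
    ny, nx = lats.size, lons.size
    w = region.windows

    def scale(f01, key):
        lo, hi = w[key]
        return lo + (hi - lo) * f01

    latg = ((lats - region.lat_min) / (region.lat_max - region.lat_min))[:, None]
    latg = np.broadcast_to(latg, (ny, nx))

    # --- static layers ---
    lon_ridge = 0.5 * (region.lon_min + region.lon_max)
    ridge = np.exp(-0.5 * ((lons[None, :] - lon_ridge) / 5.0) ** 2)
    ridge = np.broadcast_to(ridge, (ny, nx))
    depth01 = 0.55 * _smooth01(rng, (ny, nx), 5) + 0.45 * ridge
    depth = scale(depth01 / depth01.max(), "depth")

    dzdy, dzdx = np.gradient(depth, lats * KM_PER_DEG * 1000.0,
                             lons * KM_PER_DEG * 1000.0)
    slope = np.degrees(np.arctan(1e3 * np.hypot(dzdx, dzdy)))

    n_seamounts = 350
    sm_i = rng.integers(0, ny, n_seamounts)
    sm_j = rng.integers(0, nx, n_seamounts)
    glon, glat = np.meshgrid(lons, lats)
    dist = np.full((ny, nx), np.inf)
    for i, j in zip(sm_i, sm_j):
        d = haversine_km(glon, glat, lons[j], lats[i])
        np.minimum(dist, d, out=dist)
    dist_seamount = dist * 1000.0  # metres

    q = np.quantile(depth, [0.2, 0.6])
    geomorph = np.zeros((ny, nx), dtype=float)  # plain
    geomorph[depth < q[0]] = 1  # basin
    geomorph[depth > q[1]] = 2  # hills
    geomorph[ridge > 0.6] = 3  # ridge
    geomorph[dist_seamount < 75_000] = 4  # seamount

    # --- monthly dynamic layers (AR(rho) noise, rescaled per month) ---
    rho = 0.8
    months = list(region.months)

    def monthly(key, structure=None, mix=0.4, sigma=6):
        """AR(rho) sequence of smooth fields, rescaled into a window.

        ``sigma`` (grid cells) sets the spatial correlation length: large
        for climatology-like layers, small for patchy ones.  ``key=None``
        returns the unit-range field itself.
        """
        z = gaussian_filter(rng.standard_normal((ny, nx)), sigma, mode="nearest")
        out = []
        for _ in months:
            z = rho * z + np.sqrt(1 - rho**2) * gaussian_filter(
                rng.standard_normal((ny, nx)), sigma, mode="nearest")
            f = z - z.min()
            f /= max(np.ptp(f), 1e-12)
            if structure is not None:
                f = (1 - mix) * structure + mix * f
                f = (f - f.min()) / max(np.ptp(f), 1e-12)
            out.append(scale(f, key) if key is not None else f)
        return np.stack(out)

    lat_jet = 0.5 * (region.lat_min + region.lat_max)
    jet = np.exp(-0.5 * ((lats[:, None] - lat_jet) / 3.0) ** 2)
    jet = np.broadcast_to(jet, (ny, nx))

    t050 = monthly("t050", structure=latg, mix=0.25)
    # enough large-scale patchiness that the eddy field is not a single
    # zonal band (otherwise range and habitat coincide and no contrast
    # between used and available cells survives)
    eke = monthly("eke", structure=jet, mix=0.7, sigma=7)
    lo_c, hi_c = w["curr"]
    eke01 = (eke - eke.min()) / max(np.ptp(eke), 1e-12)
    curr_noise01 = monthly(None, sigma=8)
    curr = lo_c + (hi_c - lo_c) * np.clip(0.5 * np.sqrt(eke01) + 0.5 * curr_noise01, 0, 1)
    mld = monthly("mld", sigma=8)
    chl = monthly("chl", sigma=2)  # chlorophyll is patchy at the model grain

    env = xr.Dataset(
        data_vars={
            "depth": (("lat", "lon"), depth),
            "slope": (("lat", "lon"), slope),
            "geomorph": (("lat", "lon"), geomorph),
            "dist_seamount": (("lat", "lon"), dist_seamount),
            "mld": (("month", "lat", "lon"), mld),
            "t050": (("month", "lat", "lon"), t050),
            "curr": (("month", "lat", "lon"), curr),
            "eke": (("month", "lat", "lon"), eke),
            "chl": (("month", "lat", "lon"), chl),
        },
        coords={"lat": lats, "lon": lons, "month": months},
        attrs={"region": region.name, "seed": int(seed),
               "geomorph_classes": list(GEOMORPH_CLASSES)},
    )
    return env


def true_suitability(env: xr.Dataset, truth: TruthParams, month: int) -> xr.DataArray:
    """Deterministic logistic response surface for one month."""
    sel = env.sel(month=month)
    z = truth.logit(sel["depth"].to_numpy(), sel["mld"].to_numpy(),
                    sel["t050"].to_numpy(), sel["curr"].to_numpy(),
                    sel["eke"].to_numpy(), month=month)
    da = xr.DataArray(_sigmoid(z), coords={"lat": env["lat"], "lon": env["lon"]},
                      dims=("lat", "lon"), name="true_suitability",
                      attrs={"month": int(month)})
    return da


def simulate_tracks(region: RegionSpec, truthmaps: dict[int, xr.DataArray],
                    n_birds: int | None = None, days_per_month: int = 28,
                    noise: GLSNoise = GLSNoise(), seed: int = 0,
                    kernel_range_km: float = 5000.0,
                    southward_drift_deg: float = 0.5,
                    monthly_walk_deg: float = 6.0) -> TrackSet:
    """Geolocator-like fixes drawn from truth x availability.

    Each bird keeps a monthly centroid (seeded near a high-suitability cell,
    drifting ``southward_drift_deg`` per month with a small random walk);
    every bird-day contributes ``noise.fixes_per_day`` locations sampled over
    grid cells with probability proportional to
    ``truth * exp(-distance / kernel_range_km)``, jittered within-cell and
    perturbed by per-axis Gaussian location error of SD ``noise.sd_km``.

    Months run October through February (a season spanning the new year);
    ``days_per_month`` is capped at 28 so February keeps the two-fix daily
    cadence.
    """
    if n_birds is None:
        n_birds = region.n_birds
    if n_birds < 1:
        raise ValueError("n_birds must be >= 1")
    days_per_month = min(days_per_month, 28)
    rng = np.random.default_rng(seed)
    months = [m for m in SEASON_MONTHS if m in truthmaps]
    first = months[0]
    lons = truthmaps[first]["lon"].to_numpy()
    lats = truthmaps[first]["lat"].to_numpy()
    glon, glat = np.meshgrid(lons, lats)
    cell_lon, cell_lat = glon.ravel(), glat.ravel()
    res = float(np.median(np.diff(lons)))

    suit0 = np.nan_to_num(truthmaps[first].to_numpy().ravel())
    p0 = suit0**2
    p0 /= p0.sum()
    year_of = {10: 2009, 11: 2009, 12: 2009, 1: 2010, 2: 2010}

    records = []
    for b in range(n_birds):
        start = rng.choice(cell_lon.size, p=p0)
        c_lon, c_lat = cell_lon[start], cell_lat[start]
        for mi, m in enumerate(months):
            # poleward seasonal drift plus a month-to-month foraging-patch
            # relocation; the walk keeps monthly clusters from freezing in
            # place, as successive foraging areas do for wide-ranging birds
            c_lat_m = np.clip(c_lat - southward_drift_deg * mi
                              + rng.normal(0, monthly_walk_deg / 2.0),
                              lats.min(), lats.max())
            c_lon_m = c_lon + rng.normal(0, monthly_walk_deg)
            suit = np.nan_to_num(truthmaps[m].to_numpy().ravel())
            d = haversine_km(cell_lon, cell_lat, c_lon_m, c_lat_m)
            wgt = suit * np.exp(-d / kernel_range_km)
            if wgt.sum() <= 0:
                wgt = np.ones_like(wgt)
            wgt /= wgt.sum()
            n_fix = days_per_month * noise.fixes_per_day
            cells = rng.choice(cell_lon.size, size=n_fix, p=wgt)
            lon_f = cell_lon[cells] + rng.uniform(-res / 2, res / 2, n_fix)
            lat_f = cell_lat[cells] + rng.uniform(-res / 2, res / 2, n_fix)
            if noise.sd_km > 0:
                lat_f = lat_f + rng.normal(0, noise.sd_km, n_fix) / KM_PER_DEG
                lon_f = lon_f + (rng.normal(0, noise.sd_km, n_fix)
                                 / (KM_PER_DEG * np.cos(np.radians(lat_f))))
            lat_f = np.clip(lat_f, -89.9, 89.9)
            days = np.repeat(np.arange(1, days_per_month + 1), noise.fixes_per_day)
            hours = np.tile([0, 12], days_per_month)[:n_fix]
            ts = pd.to_datetime({
                "year": np.full(n_fix, year_of[m]), "month": np.full(n_fix, m),
                "day": days, "hour": hours})
            records.append(pd.DataFrame({
                "bird_id": f"{region.name}-{b:02d}", "colony": region.name,
                "timestamp": ts, "lon": normalize_lon(lon_f), "lat": lat_f}))
    return TrackSet(pd.concat(records, ignore_index=True))


@dataclass
class Scenario:
    """A generated multi-region bundle with its provenance manifest."""

    regions: dict[str, RegionSpec]
    env: dict[str, xr.Dataset]
    truth: dict[str, dict[int, xr.DataArray]]
    tracks: dict[str, TrackSet]
    manifest: dict


def make_scenario(regions: list[RegionSpec] | None = None,
                  truth: TruthParams | None = None,
                  noise: GLSNoise = GLSNoise(),
                  days_per_month: int = 28, seed: int = 0) -> Scenario:
    """Generate the full multi-region bundle under one shared truth.

    Default design: regions A ("pacific", 18 birds) and B ("indian",
    9 birds) for model fitting and a small region C ("atlantic", 4 birds)
    reserved for the extrapolation test, mirroring a two-colonies-fitted /
    one-colony-transfer study layout.
    """
    regions = regions if regions is not None else default_regions()
    if len(regions) < 2:
        raise ValueError("a scenario needs at least two regions")
    truth = truth if truth is not None else TruthParams()
    env, truthmaps, tracksets = {}, {}, {}
    region_seeds = {}
    for i, reg in enumerate(regions):
        rseed = (seed * 7919 + 104729 * (i + 1)) % (2**31)
        region_seeds[reg.name] = rseed
        e = generate_env(reg, rseed)
        t = {m: true_suitability(e, truth, m) for m in reg.months}
        tr = simulate_tracks(reg, t, noise=noise, days_per_month=days_per_month,
                             seed=rseed + 1)
        env[reg.name], truthmaps[reg.name], tracksets[reg.name] = e, t, tr
    manifest = {
        "seed": int(seed),
        "region_seeds": region_seeds,
        "days_per_month": int(min(days_per_month, 28)),
        "noise": asdict(noise),
        "truth": asdict(truth),
        "regions": {r.name: {"n_birds": r.n_birds, "colony": [r.colony_lon, r.colony_lat],
                             "extent": [r.lon_min, r.lon_max, r.lat_min, r.lat_max],
                             "windows": {k: list(v) for k, v in r.windows.items()}}
                    for r in regions},
    }
    return Scenario(regions={r.name: r for r in regions}, env=env,
                    truth=truthmaps, tracks=tracksets, manifest=manifest)
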