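"""End-to-end orchestration: tracks -> contours -> tables -> models -> validation.

The functions here chain the library stages exactly as the analysis design
prescribes: per-month 50% core contours define presences, a pooled 90%
contour carries the 100-km background lattice, per-month withholding builds
external test sets, boosted-tree models are fitted (optionally tuned under
the nt > 1000 rule) and pruned at the 5% influence threshold, and the
validation suite crosses every model with every withheld dataset plus the
reserved transfer population.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import brt, datasets, density, validation
from .geospatial import frame_for
from .synthetic import GLSNoise, Scenario, TruthParams, default_regions, make_scenario
from .tracks import TrackSet

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Knobs for a full pipeline run (defaults follow the analysis design)."""

    months: tuple = (10, 11, 12, 1, 2)
    kde_radius_km: float = 200.0
    kde_cell_km: float = 25.0
    core_level: float = 50.0
    availability_level: float = 90.0
    month_floor: int = 20
    background_spacing_km: float = 100.0
    presence_withhold_fraction: float = 0.20
    background_withhold_per_month: int = 100
    prune_threshold_pct: float = 5.0
    tune: bool = False
    tc_grid: tuple = (4,)
    lr_schedule: tuple = (0.1, 0.05, 0.02, 0.01)
    min_trees: int = 1000
    brt_config: brt.BRTConfig = field(default_factory=lambda: brt.BRTConfig(
        tree_complexity=2, learning_rate=0.06, cv_folds=3,
        max_trees=500, tree_step=50))
    n_bins: int = 10
    combine_balance: str = "row-balance"
    fit_populations: tuple = ("pacific", "indian")
    transfer_population: str = "atlantic"
    days_per_month: int = 28
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        allowed = set(cls.__dataclass_fields__)
        unknown = set(raw) - allowed
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "brt_config" in raw:
            raw["brt_config"] = brt.BRTConfig(**raw["brt_config"])
        for key in ("months", "tc_grid", "lr_schedule", "fit_populations"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class PopulationDataset:
    """All per-population design artifacts prior to model fitting."""

    population: str
    frame: object
    cores: dict
    availability: density.ContourSet
    table: pd.DataFrame
    train: pd.DataFrame
    test: pd.DataFrame


def build_population_dataset(tracks: TrackSet, env, population: str,
                             config: RunConfig, *, split_seed: int | None = None
                             ) -> PopulationDataset:
    """Contours -> presence/background table -> covariates -> withholding."""
    lon, lat = tracks.lonlat()
    frame = frame_for(lon, lat, cell_km=config.kde_cell_km)
    cores = density.monthly_core_contours(
        tracks, level=config.core_level, radius_km=config.kde_radius_km,
        cell_km=config.kde_cell_km, frame=frame, min_points=config.month_floor)
    avail = density.seasonal_availability_contour(
        tracks, level=config.availability_level, radius_km=config.kde_radius_km,
        cell_km=config.kde_cell_km, frame=frame)
    presences = datasets.build_presences(tracks, cores, population=population)
    background = datasets.build_background(avail, sorted(cores.keys()),
                                           spacing_km=config.background_spacing_km,
                                           population=population)
    table = pd.concat([presences, background], ignore_index=True)
    table = datasets.annotate_covariates(table, env)
    spec = datasets.SplitSpec(
        presence_withhold_fraction=config.presence_withhold_fraction,
        background_withhold_per_month=config.background_withhold_per_month,
        seed=config.seed if split_seed is None else split_seed)
    train, test = datasets.withhold_split(table, spec)
    return PopulationDataset(population=population, frame=frame, cores=cores,
                             availability=avail, table=table, train=train, test=test)


def fit_population_model(train: pd.DataFrame, config: RunConfig,
                         predictors: list[str] | None = None
                         ) -> tuple[brt.FittedHabitatModel, list[str], pd.DataFrame | None]:
    """Tune (optionally), then prune predictors below the 5% threshold."""
    search_log = None
    cfg = config.brt_config
    if config.tune:
        tuned, search_log = brt.tune_brt(
            train, tc_grid=config.tc_grid, lr_schedule=config.lr_schedule,
            config=cfg, min_trees=config.min_trees, predictors=predictors)
        cfg = tuned.config
    model, dropped = brt.prune_predictors(train, cfg,
                                          threshold_pct=config.prune_threshold_pct,
                                          predictors=predictors)
    return model, dropped, search_log


def fit_all_models(pops: dict[str, PopulationDataset], config: RunConfig
                   ) -> tuple[dict[str, brt.FittedHabitatModel], pd.DataFrame]:
    """Per-population models plus the combined model on shared predictors.

    The combined model uses the predictors common to all single-population
    models (maximizing generality) and balances population contributions by
    row-count re-weighting.
    """
    models: dict[str, brt.FittedHabitatModel] = {}
    rows = []
    for name, ds in pops.items():
        model, dropped, _ = fit_population_model(ds.train, config)
        models[name] = model
        rows.append({"model": name, **model.summary(), "weight": "none",
                     "dropped": ",".join(dropped)})
        log.info("model %s: %s", name, model.summary())
    shared = sorted(set.intersection(*[set(m.predictors) for m in models.values()]))
    combined_train = datasets.combine_populations(
        [ds.train for ds in pops.values()], balance=config.combine_balance)
    cfg = config.brt_config
    combined = brt.fit_brt(combined_train, cfg, predictors=shared)
    models["combined"] = combined
    wdesc = {p: round(float(ds.train["weight"].iloc[0]), 3) if config.combine_balance
             == "row-balance" else config.combine_balance
             for p, ds in pops.items()}
    rows.append({"model": "combined", **combined.summary(),
                 "weight": json.dumps({p: round(float(
                     combined_train.loc[combined_train["population"] == p, "weight"].iloc[0]), 3)
                     for p in pops}), "dropped": ""})
    return models, pd.DataFrame(rows)


def run_transferability(scenario: Scenario, config: RunConfig
                        ) -> dict:
    """The full interpolation-vs-extrapolation experiment on a scenario.

    Fits one model per fitting population plus the combined model, builds
    the reserved population's presence/background dataset, and validates the
    full model x dataset cross.
    """
    pops = {}
    for name in config.fit_populations:
        pops[name] = build_population_dataset(
            scenario.tracks[name], scenario.env[name], name, config)
    models, summary = fit_all_models(pops, config)

    testsets = {f"{name}-withheld": ds.test for name, ds in pops.items()}
    tname = config.transfer_population
    if tname in scenario.tracks:
        transfer = build_transfer_dataset(scenario.tracks[tname],
                                          scenario.env[tname], tname, config)
        testsets[tname] = transfer
    results = validation.run_validation_suite(models, testsets, n_bins=config.n_bins)
    return {"populations": pops, "models": models, "summary": summary,
            "testsets": testsets, "results": results,
            "results_table": validation.results_frame(results)}


def build_transfer_dataset(tracks: TrackSet, env, population: str,
                           config: RunConfig) -> pd.DataFrame:
    """Presence/background table for the reserved population (no withholding):
    all fixes inside the 50% contours vs the full background lattice."""
    ds = build_population_dataset(tracks, env, population, config)
    # use the complete annotated table; single background lattice (one month
    # replicate per month as elsewhere)
    return ds.table


def write_outputs(outdir, result: dict, scenario: Scenario, config: RunConfig) -> None:
    """Persist tables, summaries, manifest, and calibration plots."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    result["summary"].to_csv(out / "model_summary.csv", index=False)
    result["results_table"].to_csv(out / "validation.csv", index=False)
    (out / "validation.json").write_text(json.dumps(
        [r.to_dict() for r in result["results"]], indent=2, default=float))
    for name, ds in result["populations"].items():
        datasets.write_sample_table(ds.train, out / f"{name}_train.csv")
        datasets.write_sample_table(ds.test, out / f"{name}_test.csv")
        contours = {"type": "FeatureCollection",
                    "features": [ds.availability.to_geojson()]
                    + [dict(c.to_geojson(),
                            properties={**c.to_geojson()["properties"],
                                        "month": m})
                       for m, c in ds.cores.items()]}
        (out / f"{name}_contours.geojson").write_text(
            json.dumps(contours, default=float))
    manifest = {"config": {k: (asdict(v) if hasattr(v, "__dataclass_fields__") else v)
                           for k, v in asdict(config).items()},
                "scenario": scenario.manifest}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    try:
        _plot_calibrations(out, result)
    except Exception as exc:  # plotting must never sink a run
        log.warning("calibration plots skipped: %s", exc)


def _plot_calibrations(out: Path, result: dict) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    results = result["results"]
    n = len(results)
    ncol = 3
    nrow = int(np.ceil(n / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(4 * ncol, 3.2 * nrow), squeeze=False)
    for ax, r in zip(axes.ravel(), results):
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.plot(r.calibration["mean_prediction"], r.calibration["observed_fraction"],
                "o-", ms=4)
        ax.set_title(f"{r.model_id} on {r.dataset_id}\n{r.mode}, "
                     f"$r_s$={r.r_s:.2f}, COR={r.cor:.2f}", fontsize=9)
        ax.set_xlim(0, 1)
        ax.set_ylim(0, 1)
    for ax in axes.ravel()[n:]:
        ax.set_visible(False)
    fig.tight_layout()
    fig.savefig(out / "calibration.png", dpi=120)
    plt.close(fig)
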