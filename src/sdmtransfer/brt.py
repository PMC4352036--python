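"""Boosted regression trees for binary use/availability data.

Habitat models here are stagewise gradient-boosted ensembles of small
regression trees fit to Bernoulli deviance on a logit link, in the style
standard for tracking-based species distribution modelling.  Three knobs
govern the fit: tree complexity ``tc`` (splits per tree, 1-4), learning
rate ``lr``, and the number of trees ``nt``.  ``nt`` is not set directly:
a stagewise scan selects the tree count minimizing k-fold cross-validated
predictive deviance, and the cross-validated AUC and percent deviance
explained reported for a model come from those held-out folds only.

Tuning follows the conventional recipe: for each candidate tree
complexity, accept the largest learning rate whose selected ``nt`` exceeds
1000, then pick the (tc, lr) pair with the best cross-validated AUC.
Predictors contributing less than 5% relative influence are pruned by
iterative refitting.

The tree ensemble itself is scikit-learn's ``GradientBoostingClassifier``
(binomial deviance, weighted), wrapped so that tree complexity maps to
``max_leaf_nodes = tc + 1`` (a tc-split tree) and categorical predictors
(month, seafloor class) enter through one-hot encoding.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .covariates import CATEGORICAL_COVARIATES, COVARIATE_COLUMNS

log = logging.getLogger(__name__)

#: predictors treated as unordered factors
CATEGORICAL_PREDICTORS = ("month",) + CATEGORICAL_COVARIATES

_EPS = 1e-12


@dataclass(frozen=True)
class BRTConfig:
    """Hyperparameters for a boosted-tree fit.

    ``min_node_size`` is the minimum number of observations per terminal
    node; generous values guard against trees memorizing individual grid
    cells through fine-grained static covariates.
    """

    tree_complexity: int = 4
    learning_rate: float = 0.05
    bag_fraction: float = 0.5
    cv_folds: int = 10
    max_trees: int = 2000
    tree_step: int = 50
    min_node_size: int = 40
    seed: int = 0

    def __post_init__(self):
        if self.tree_complexity not in (1, 2, 3, 4):
            raise ValueError("tree_complexity must be in {1, 2, 3, 4}")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0.0 < self.bag_fraction <= 1.0:
            raise ValueError("bag_fraction must be in (0, 1]")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.max_trees < self.tree_step:
            raise ValueError("max_trees must be at least tree_step")


class _Encoder:
    """Design-matrix builder: numeric passthrough + fixed-category one-hot."""

    def __init__(self, train: pd.DataFrame, predictors: list[str]):
        self.predictors = list(predictors)
        self.categories: dict[str, list] = {}
        self.columns: list[str] = []
        self.col_predictor: list[str] = []
        for p in self.predictors:
            if p in CATEGORICAL_PREDICTORS:
                levels = sorted(pd.unique(train[p]))
                self.categories[p] = levels
                for lv in levels:
                    self.columns.append(f"{p}={lv}")
                    self.col_predictor.append(p)
            else:
                self.columns.append(p)
                self.col_predictor.append(p)

    def transform(self, df: pd.DataFrame) -> np.ndarray:
        cols = []
        for p in self.predictors:
            if p in self.categories:
                vals = df[p].to_numpy()
                for lv in self.categories[p]:
                    cols.append((vals == lv).astype(float))
            else:
                cols.append(df[p].to_numpy(dtype=float))
        return np.column_stack(cols)


@dataclass
class PartialDependence:
    """Marginal (fitted-function) curve of one predictor, on the logit scale."""

    predictor: str
    grid: np.ndarray
    values: np.ndarray
    rug: np.ndarray  # data deciles of the predictor

    @property
    def peak(self):
        """Grid location of the curve maximum."""
        return self.grid[int(np.argmax(self.values))]


@dataclass
class FittedHabitatModel:
    """A fitted, cross-validated boosted-tree habitat model."""

    estimator: GradientBoostingClassifier
    encoder: _Encoder
    config: BRTConfig
    predictors: list[str]
    n_trees: int
    influence: pd.Series  # percent per predictor, sums to 100
    cv_auc: float
    cv_deviance_explained: float
    cv_curve: pd.DataFrame
    converged: bool
    train_populations: tuple[str, ...] = ()
    _train_df: pd.DataFrame = field(repr=False, default=None)
    _train_w: np.ndarray = field(repr=False, default=None)

    def predict_logit(self, df: pd.DataFrame) -> np.ndarray:
        return self.estimator.decision_function(self.encoder.transform(df))

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        """Probability of use on (0, 1)."""
        p = 1.0 / (1.0 + np.exp(-self.predict_logit(df)))
        return np.clip(p, _EPS, 1.0 - _EPS)

    def summary(self) -> dict:
        contrib = ", ".join(f"{k} ({v:.1f})" for k, v in
                            self.influence.sort_values(ascending=False).items())
        return {
            "predictors": contrib,
            "tc": self.config.tree_complexity,
            "lr": self.config.learning_rate,
            "nt": self.n_trees,
            "dev": round(self.cv_deviance_explained, 3),
            "auc": round(self.cv_auc, 3),
        }


def _bernoulli_deviance(y, score, w) -> float:
    """Mean (per unit weight) -2 log-likelihood given logit scores."""
    p = np.clip(1.0 / (1.0 + np.exp(-score)), _EPS, 1.0 - _EPS)
    ll = y * np.log(p) + (1.0 - y) * np.log(1.0 - p)
    return float(-2.0 * np.sum(w * ll) / np.sum(w))


def default_predictors(train: pd.DataFrame) -> list[str]:
    preds = [c for c in COVARIATE_COLUMNS if c in train.columns]
    if "month" in train.columns and train["month"].nunique() > 1:
        preds.append("month")
    return preds


def _make_estimator(config: BRTConfig, n_trees: int) -> GradientBoostingClassifier:
    return GradientBoostingClassifier(
        loss="log_loss",
        n_estimators=n_trees,
        learning_rate=config.learning_rate,
        subsample=config.bag_fraction,
        max_leaf_nodes=config.tree_complexity + 1,
        max_depth=None,
        min_samples_leaf=config.min_node_size,
        random_state=config.seed,
    )


def fit_brt(train: pd.DataFrame, config: BRTConfig,
            predictors: list[str] | None = None) -> FittedHabitatModel:
    """Fit a boosted-tree model with stagewise CV selection of ``nt``.

    The candidate tree counts are multiples of ``config.tree_step`` up to
    ``config.max_trees``; the count minimizing total held-out Bernoulli
    deviance is selected (smallest count on ties).  ``cv_auc`` and
    ``cv_deviance_explained`` are computed from pooled held-out predictions
    at the selected count; the latter is 1 - CV deviance / null deviance,
    with the null model being each training fold's weighted base rate.
    """
    predictors = list(predictors) if predictors is not None else default_predictors(train)
    if not predictors:
        raise ValueError("no predictors: supply a list or use covariate-named columns")
    enc = _Encoder(train, predictors)
    X = enc.transform(train)
    y = train["label"].to_numpy(dtype=float)
    w = (train["weight"].to_numpy(dtype=float) if "weight" in train.columns
         else np.ones(len(train)))
    if len(np.unique(y)) < 2:
        raise ValueError("training data contain a single class")

    candidates = np.arange(config.tree_step, config.max_trees + 1, config.tree_step)
    folds = StratifiedKFold(n_splits=config.cv_folds, shuffle=True,
                            random_state=config.seed)
    dev_total = np.zeros(len(candidates))
    held_scores = np.empty((len(candidates), len(y)))
    null_ll_sum = 0.0
    for f, (tr, va) in enumerate(folds.split(X, y)):
        clf = _make_estimator(replace(config, seed=config.seed + f), config.max_trees)
        clf.fit(X[tr], y[tr], sample_weight=w[tr])
        k = 0
        for stage, score in enumerate(clf.staged_decision_function(X[va]), start=1):
            if k < len(candidates) and stage == candidates[k]:
                s = score.ravel()
                dev_total[k] += _bernoulli_deviance(y[va], s, w[va]) * np.sum(w[va])
                held_scores[k, va] = s
                k += 1
            if k == len(candidates):
                break
        p0 = np.clip(np.average(y[tr], weights=w[tr]), _EPS, 1 - _EPS)
        null_ll_sum += -2.0 * np.sum(
            w[va] * (y[va] * np.log(p0) + (1 - y[va]) * np.log(1 - p0)))

    best = int(np.argmin(dev_total))
    n_trees = int(candidates[best])
    converged = n_trees < config.max_trees
    if not converged:
        warnings.warn(f"selected nt hit max_trees={config.max_trees}; "
                      "CV deviance may still be decreasing")

    cv_dev = dev_total[best] / np.sum(w)
    null_dev = null_ll_sum / np.sum(w)
    dev_explained = float(1.0 - cv_dev / null_dev)
    cv_auc = float(roc_auc_score(y, held_scores[best], sample_weight=w))
    curve = pd.DataFrame({"n_trees": candidates, "cv_deviance": dev_total / np.sum(w)})

    final = _make_estimator(config, n_trees)
    final.fit(X, y, sample_weight=w)

    imp = final.feature_importances_
    infl = pd.Series(0.0, index=predictors)
    for col_imp, pred in zip(imp, enc.col_predictor):
        infl[pred] += col_imp
    total = infl.sum()
    infl = infl * (100.0 / total) if total > 0 else infl

    pops = tuple(sorted(train["population"].unique())) if "population" in train.columns else ()
    return FittedHabitatModel(
        estimator=final, encoder=enc, config=config, predictors=predictors,
        n_trees=n_trees, influence=infl, cv_auc=cv_auc,
        cv_deviance_explained=dev_explained, cv_curve=curve, converged=converged,
        train_populations=pops,
        _train_df=train[predictors].reset_index(drop=True), _train_w=w.copy(),
    )


def relative_influence(model: FittedHabitatModel) -> pd.Series:
    """Percent contribution per predictor (split-improvement weighted), sum 100."""
    return model.influence.copy()


def tune_brt(train: pd.DataFrame, tc_grid=(1, 2, 3, 4),
             lr_schedule=(0.1, 0.05, 0.01, 0.005, 0.001, 0.0005),
             *, config: BRTConfig | None = None, min_trees: int = 1000,
             predictors: list[str] | None = None
             ) -> tuple[FittedHabitatModel, pd.DataFrame]:
    """Hyperparameter search under the nt > ``min_trees`` rule.

    For each tree complexity, learning rates are tried from largest to
    smallest and the first (largest) whose selected nt exceeds ``min_trees``
    is accepted; among the accepted per-complexity models the one with the
    highest cv_auc wins (cv deviance explained breaks ties).  Returns the
    winner and the full search log.
    """
    base = config or BRTConfig()
    lrs = sorted(set(lr_schedule), reverse=True)
    records, accepted = [], []
    for tc in tc_grid:
        for lr in lrs:
            cfg = replace(base, tree_complexity=tc, learning_rate=lr)
            m = fit_brt(train, cfg, predictors)
            ok = m.n_trees > min_trees
            records.append({"tc": tc, "lr": lr, "nt": m.n_trees,
                            "cv_auc": m.cv_auc, "dev": m.cv_deviance_explained,
                            "accepted": ok})
            log.info("tune tc=%d lr=%g -> nt=%d auc=%.3f%s", tc, lr, m.n_trees,
                     m.cv_auc, " (accepted)" if ok else "")
            if ok:
                accepted.append(m)
                break
    search_log = pd.DataFrame(records)
    if not accepted:
        raise RuntimeError(
            f"no (tc, lr) candidate selected more than {min_trees} trees; "
            "extend lr_schedule with smaller learning rates or raise max_trees")
    best = max(accepted, key=lambda m: (m.cv_auc, m.cv_deviance_explained))
    return best, search_log


def prune_predictors(train: pd.DataFrame, config: BRTConfig,
                     threshold_pct: float = 5.0,
                     predictors: list[str] | None = None
                     ) -> tuple[FittedHabitatModel, list[str]]:
    """Iteratively drop the weakest predictor while it contributes < threshold.

    One predictor is removed per refit (the lowest-influence one below the
    threshold); iteration stops when every remaining predictor meets the
    threshold or a single predictor remains.
    """
    preds = list(predictors) if predictors is not None else default_predictors(train)
    dropped: list[str] = []
    while True:
        model = fit_brt(train, config, preds)
        weakest = model.influence.idxmin()
        if model.influence[weakest] >= threshold_pct or len(preds) == 1:
            return model, dropped
        preds = [p for p in preds if p != weakest]
        dropped.append(weakest)
        log.info("pruned %s (%.2f%% < %.1f%%)", weakest,
                 model.influence[weakest], threshold_pct)


def partial_dependence(model: FittedHabitatModel, predictor: str,
                       grid: np.ndarray | None = None,
                       n_grid: int = 25) -> PartialDependence:
    """Fitted function: weighted-mean logit prediction over the training rows
    with the focal predictor clamped to each grid value."""
    if predictor not in model.predictors:
        raise KeyError(f"{predictor!r} is not a model predictor")
    train = model._train_df
    w = model._train_w
    if predictor in model.encoder.categories:
        grid_vals = np.asarray(model.encoder.categories[predictor])
        rug = grid_vals
    else:
        col = train[predictor].to_numpy(dtype=float)
        if grid is None:
            lo, hi = np.percentile(col, [1, 99])
            grid_vals = np.linspace(lo, hi, n_grid)
        else:
            grid_vals = np.asarray(grid, dtype=float)
        rug = np.percentile(col, np.arange(10, 100, 10))
    vals = np.empty(len(grid_vals))
    work = train.copy()
    for i, g in enumerate(grid_vals):
        work[predictor] = g
        vals[i] = np.average(model.predict_logit(work), weights=w)
    return PartialDependence(predictor=predictor, grid=grid_vals, values=vals, rug=rug)


def month_interaction_check(model: FittedHabitatModel, *, n_grid: int = 5,
                            max_rows: int = 500) -> dict:
    """Report month's influence and its strongest pairwise interaction.

    Interaction strength for (month, covariate) is the standard deviation of
    the two-way partial-dependence grid after removing additive (row/column)
    effects; zero for a purely additive model.
    """
    if "month" not in model.predictors:
        return {"month_influence": 0.0, "max_interaction": 0.0,
                "note": "month not among model predictors"}
    levels = model.encoder.categories.get("month", [])
    if len(levels) < 2:
        warnings.warn("month has a single level; dropped as constant")
        return {"month_influence": 0.0, "max_interaction": 0.0,
                "note": "month constant in training data"}
    rng = np.random.default_rng(model.config.seed)
    train = model._train_df
    if len(train) > max_rows:
        idx = rng.choice(len(train), size=max_rows, replace=False)
        train = train.iloc[idx].reset_index(drop=True)
    numeric = [p for p in model.predictors
               if p != "month" and p not in model.encoder.categories]
    strengths = {}
    for p in numeric:
        qs = np.percentile(train[p].to_numpy(dtype=float),
                           np.linspace(5, 95, n_grid))
        pd2 = np.empty((len(levels), n_grid))
        work = train.copy()
        for i, m in enumerate(levels):
            work["month"] = m
            for j, v in enumerate(qs):
                work[p] = v
                pd2[i, j] = model.predict_logit(work).mean()
            work[p] = train[p].to_numpy()
        resid = (pd2 - pd2.mean(axis=0, keepdims=True)
                 - pd2.mean(axis=1, keepdims=True) + pd2.mean())
        strengths[p] = float(resid.std())
    top = max(strengths, key=strengths.get) if strengths else None
    return {"month_influence": float(model.influence.get("month", 0.0)),
            "max_interaction": strengths.get(top, 0.0),
            "interaction_partner": top,
            "per_predictor": strengths}


def save_model(model: FittedHabitatModel, path) -> None:
    joblib.dump({"format": "sdmtransfer-brt-v1", "model": model}, path)


def load_model(path) -> FittedHabitatModel:
    payload = joblib.load(path)
    if payload.get("format") != "sdmtransfer-brt-v1":
        raise ValueError("unrecognized model file format")
    return payload["model"]
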