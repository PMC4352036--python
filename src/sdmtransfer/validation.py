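"""External validation of use-availability predictions.

Because background points are availability samples rather than true
absences, external skill is measured without thresholding: predictions for
withheld presences and backgrounds are binned into equal-interval groups
over [0, 1] and a Spearman rank correlation (r_s) is computed between bin
rank and the within-bin proportion of presences — a model with predictive
skill concentrates presences in its high-suitability bins.  The point
biserial correlation (COR, a Pearson correlation between prediction and
0/1 label) and a calibration curve complete the report.

``run_validation_suite`` crosses fitted models with named test sets and
tags each pair as interpolation (test population was in the training set)
or extrapolation (novel population) — the design used to contrast
within-region and transferred predictive performance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


def bin_predictions(preds, labels, n_bins: int = 10,
                    min_count: int = 1) -> pd.DataFrame:
    """Equal-interval bins of [0, 1] with per-bin presence proportions.

    The top bin is right-closed (a prediction of exactly 1.0 lands in it).
    Bins holding fewer than ``min_count`` locations get a NaN proportion —
    empty bins always, and with a larger ``min_count`` also bins too sparse
    for their presence proportion to carry rank information — and NaN bins
    are excluded from downstream correlations.
    """
    preds = np.asarray(preds, dtype=float)
    labels = np.asarray(labels)
    if preds.size == 0:
        raise ValueError("no predictions to bin")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    idx = np.minimum((preds * n_bins).astype(int), n_bins - 1)
    pres = np.bincount(idx[labels == 1], minlength=n_bins)
    back = np.bincount(idx[labels == 0], minlength=n_bins)
    total = pres + back
    ok = total >= max(min_count, 1)
    prop = np.where(ok, pres / np.where(total > 0, total, 1), np.nan)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    return pd.DataFrame({
        "bin": np.arange(1, n_bins + 1),
        "lo": edges[:-1], "hi": edges[1:],
        "n_presence": pres, "n_background": back,
        "proportion": prop,
    })


def spearman_bin_test(bins: pd.DataFrame) -> tuple[float, float]:
    """Spearman r_s between bin rank and presence proportion (mid-rank ties).

    Two-sided p-value from the t approximation.  Requires at least three
    non-empty bins; fewer leaves the statistic undefined.
    """
    ok = bins["proportion"].notna()
    if ok.sum() < 3:
        raise ValueError("fewer than 3 non-empty bins; r_s undefined")
    r, p = stats.spearmanr(bins.loc[ok, "bin"], bins.loc[ok, "proportion"])
    return float(r), float(p)


def point_biserial(preds, labels) -> float:
    """Pearson correlation between continuous predictions and 0/1 labels."""
    preds = np.asarray(preds, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("point biserial correlation requires both classes")
    return float(stats.pearsonr(preds, labels).statistic)


def calibration_curve(preds, labels, n_bins: int = 10) -> pd.DataFrame:
    """Per-bin (mean prediction, observed presence fraction, count).

    A perfectly calibrated model lies on the identity line.
    """
    preds = np.asarray(preds, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("calibration requires both classes")
    idx = np.minimum((preds * n_bins).astype(int), n_bins - 1)
    rows = []
    for b in range(n_bins):
        sel = idx == b
        if not sel.any():
            continue
        rows.append({"bin": b + 1,
                     "mean_prediction": float(preds[sel].mean()),
                     "observed_fraction": float(labels[sel].mean()),
                     "count": int(sel.sum())})
    return pd.DataFrame(rows)


@dataclass
class ValidationResult:
    """Validation statistics for one (model, test set) pairing.

    ``degenerate`` marks pairings whose predictions collapse into fewer
    than three occupied suitability bins, leaving the binned rank test
    undefined (``r_s`` NaN) — the strongest possible failure of binned
    validation, typical when a model is transferred far outside its
    training covariate ranges and predicts a near-constant suitability.
    """

    model_id: str
    dataset_id: str
    mode: str  # "interpolation" | "extrapolation"
    bins: pd.DataFrame = field(repr=False)
    r_s: float
    p_value: float
    cor: float
    calibration: pd.DataFrame = field(repr=False)
    degenerate: bool = False

    @property
    def n_informative_bins(self) -> int:
        return int(self.bins["proportion"].notna().sum())

    @property
    def significantly_positive(self) -> bool:
        """Whether binned validation demonstrated positive predictive skill.

        Requires at least five informative bins besides r_s > 0 and
        p < 0.05: under the exact permutation null of Spearman's rho, the
        smallest attainable two-sided p with k ranked points is 2/k!, so
        with fewer than five points even a perfect ranking cannot reach
        the 0.05 level (2/4! ≈ 0.083) and the t-approximation's tiny
        p-values there are artefacts.
        """
        return (not self.degenerate and self.n_informative_bins >= 5
                and self.r_s > 0 and self.p_value < 0.05)

    def to_dict(self) -> dict:
        return {"model": self.model_id, "dataset": self.dataset_id,
                "mode": self.mode, "r_s": self.r_s, "p_value": self.p_value,
                "cor": self.cor, "degenerate": self.degenerate,
                "n_bins_occupied": int(self.bins["proportion"].notna().sum())}


#: bins with fewer locations than this carry no rank information and are
#: excluded from suite-level correlations (a one-point presence proportion
#: is pure noise)
MIN_BIN_COUNT = 5


def validate_pair(model, test: pd.DataFrame, *, model_id: str, dataset_id: str,
                  mode: str, n_bins: int = 10,
                  min_bin_count: int = MIN_BIN_COUNT) -> ValidationResult:
    preds = model.predict(test)
    labels = test["label"].to_numpy()
    bins = bin_predictions(preds, labels, n_bins, min_count=min_bin_count)
    try:
        r, p = spearman_bin_test(bins)
        degenerate = False
    except ValueError:
        r, p, degenerate = float("nan"), float("nan"), True
    cor = point_biserial(preds, labels)
    cal = calibration_curve(preds, labels, n_bins)
    return ValidationResult(model_id=model_id, dataset_id=dataset_id, mode=mode,
                            bins=bins, r_s=r, p_value=p, cor=cor, calibration=cal,
                            degenerate=degenerate)


def run_validation_suite(models: dict, testsets: dict[str, pd.DataFrame],
                         n_bins: int = 10) -> list[ValidationResult]:
    """Full cross of models over test sets with interpolation/extrapolation tags.

    A pairing counts as interpolation when every population in the test set
    was among the model's training populations, and extrapolation otherwise
    — so a single-population model is interpolated on its own withheld data,
    extrapolated to the other population's withheld data and to the reserved
    third population, and a combined model is interpolated on both of its
    source populations.  Raises if a test set lacks a model covariate.
    """
    results = []
    for mid, model in models.items():
        trained_on = set(model.train_populations)
        for did, test in testsets.items():
            missing = [p for p in model.predictors if p not in test.columns]
            if missing:
                raise ValueError(f"test set {did!r} lacks covariates {missing}")
            pops = set(test["population"].unique()) if "population" in test.columns else set()
            mode = "interpolation" if pops and pops <= trained_on else "extrapolation"
            results.append(validate_pair(model, test, model_id=mid, dataset_id=did,
                                         mode=mode, n_bins=n_bins))
    return results


def results_frame(results: list[ValidationResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in results])
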