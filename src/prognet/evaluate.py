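"""External-validation and clinical-relevance evaluation of the models.

Continuous metrics are R^2 against the evaluation set's own outcome mean
(which can go negative for miscentred constant predictions), RMSE and MAE.
Binary metrics are AUC (rank / Mann-Whitney formulation with ties handled)
and the Brier score. Clinical-relevance summaries: calibration bins of 50
patients ordered by predicted score, severity-category remission tables on
the standard depressive-total cut-offs (0-13 minimal, 14-19 mild, 20-28
moderate, 29-63 severe), and the inter-model prediction correlation matrix.
Internal 10-fold cross-validation re-runs the entire pipeline for a model
inside every training fold and pools the held-out predictions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .models import ModelSpec
from .variables import SEVERITY_CATEGORIES


@dataclass
class MetricSet:
    scope: str  # combined_test | per_study:<id> | internal_cv
    r_squared: float | None = None
    rmse: float | None = None
    mae: float | None = None
    auc: float | None = None
    brier: float | None = None
    flags: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "scope": self.scope,
            "r_squared": self.r_squared,
            "rmse": self.rmse,
            "mae": self.mae,
            "auc": self.auc,
            "brier": self.brier,
            "flags": list(self.flags),
        }


def continuous_metrics(observed, predicted, scope: str = "combined_test") -> MetricSet:
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.shape != yhat.shape or y.size < 2:
        raise ValueError("observed and predicted must have equal length >= 2")
    resid = y - yhat
    rmse = float(np.sqrt(np.mean(resid**2)))
    mae = float(np.mean(np.abs(resid)))
    ss_tot = float(((y - y.mean()) ** 2).sum())
    flags = []
    if ss_tot == 0:
        r2 = None
        flags.append("constant_observed_r2_undefined")
    else:
        r2 = float(1.0 - (resid**2).sum() / ss_tot)
    return MetricSet(scope, r_squared=r2, rmse=rmse, mae=mae, flags=flags)


def binary_metrics(observed, predicted_prob, scope: str = "combined_test") -> MetricSet:
    y = np.asarray(observed, dtype=float)
    p = np.asarray(predicted_prob, dtype=float)
    if y.shape != p.shape:
        raise ValueError("observed and predicted must have equal length")
    if np.any((y != 0) & (y != 1)):
        raise ValueError("observed must be binary 0/1")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("predicted probabilities must lie in [0, 1]")
    brier = float(np.mean((p - y) ** 2))
    flags = []
    if len(np.unique(y)) < 2:
        auc = None
        flags.append("single_class_auc_undefined")
    else:
        auc = float(roc_auc_score(y, p))
    return MetricSet(scope, auc=auc, brier=brier, flags=flags)


@dataclass
class CalibrationBins:
    bin_size: int
    mean_predicted: np.ndarray
    mean_observed: np.ndarray
    remission_fraction: np.ndarray
    bin_counts: np.ndarray
    partial_last_bin: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin": np.arange(1, len(self.bin_counts) + 1),
                "n": self.bin_counts,
                "mean_predicted": self.mean_predicted,
                "mean_observed": self.mean_observed,
                "remission_fraction": self.remission_fraction,
            }
        )


def calibration_bins(observed, predicted, remission, bin_size: int = 50) -> CalibrationBins:
    """Sort patients by predicted score ascending and form consecutive bins
    of ``bin_size``; a trailing remainder is kept as a flagged partial bin."""
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    rem = np.asarray(remission, dtype=float)
    if not (len(y) == len(yhat) == len(rem)):
        raise ValueError("inputs must have equal length")
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    order = np.argsort(yhat, kind="stable")
    edges = list(range(0, len(y), bin_size)) + [len(y)]
    mp, mo, rf, counts = [], [], [], []
    for a, b in zip(edges[:-1], edges[1:]):
        idx = order[a:b]
        counts.append(len(idx))
        mp.append(float(yhat[idx].mean()))
        mo.append(float(y[idx].mean()))
        rf.append(float(rem[idx].mean()))
    partial = counts[-1] != bin_size if counts else False
    return CalibrationBins(
        bin_size, np.array(mp), np.array(mo), np.array(rf), np.array(counts), partial
    )


@dataclass
class SeverityTable:
    categories: list[str]
    bounds: list[tuple[int, int]]
    counts: np.ndarray
    remission_fraction: np.ndarray  # NaN for empty categories

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "category": self.categories,
                "lower": [b[0] for b in self.bounds],
                "upper": [b[1] for b in self.bounds],
                "n": self.counts,
                "remission_fraction": self.remission_fraction,
            }
        )


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5)


def severity_category_remission(predicted, remission) -> SeverityTable:
    """Observed remission fraction within severity categories of the
    (rounded) predicted follow-up total."""
    yhat = _round_half_up(np.asarray(predicted, dtype=float))
    rem = np.asarray(remission, dtype=float)
    if np.any(yhat < 0) or np.any(yhat > 63):
        warnings.warn("predicted scores outside [0, 63] clamped", stacklevel=2)
        yhat = np.clip(yhat, 0, 63)
    names, bounds, counts, fracs = [], [], [], []
    for name, lo, hi in SEVERITY_CATEGORIES:
        mask = (yhat >= lo) & (yhat <= hi)
        names.append(name)
        bounds.append((lo, hi))
        counts.append(int(mask.sum()))
        fracs.append(float(rem[mask].mean()) if mask.any() else float("nan"))
    return SeverityTable(names, bounds, np.array(counts), np.array(fracs))


def prediction_correlations(predictions: dict[int, np.ndarray]) -> pd.DataFrame:
    """Pearson correlation matrix of per-model prediction vectors; constant
    vectors (the null model) yield NaN rows, flagged via a warning."""
    if len(predictions) < 2:
        raise ValueError("need at least two models to correlate")
    frame = pd.DataFrame({k: np.asarray(v, dtype=float) for k, v in predictions.items()})
    constant = [k for k in frame.columns if frame[k].nunique() <= 1]
    if constant:
        warnings.warn(f"constant prediction vector(s), correlation undefined: {constant}",
                      stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        return frame.corr()


def internal_cross_validation(
    train_tables,
    spec: ModelSpec,
    folds: int = 10,
    seed: int = 0,
    pipeline_options=None,
) -> MetricSet:
    """Pooled-prediction k-fold internal cross-validation of one modelling
    approach: weight estimation, elastic-net tuning and the final fit are
    all re-run inside each training fold; metrics are computed once on the
    pooled held-out predictions."""
    from .pipeline import cross_validated_predictions  # deferred: avoids cycle

    y, yhat = cross_validated_predictions(
        train_tables, [spec], folds=folds, seed=seed, options=pipeline_options
    )[(spec.model_id, spec.outcome)]
    if spec.outcome == "continuous":
        return continuous_metrics(y, yhat, scope="internal_cv")
    return binary_metrics(y, yhat, scope="internal_cv")
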