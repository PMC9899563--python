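"""Predictor-set construction for the nine modelling approaches.

Three forms: weighted sum scores (centrality- or factor-weighted), plain
unweighted totals, and the full 32-variable item-level set. Weights are
always frozen from the training fit and merely applied to any table they
score — nothing here re-estimates anything.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .centrality import WeightVector
from .synthetic import StudyTable
from .variables import ANX_SUBSCALES, AUX_TOTALS, BASELINE_VARS, BDI_ITEMS, STUDY_ID

SUM_SCORE_LABELS = ["bdi_score", "anxiety_score"] + AUX_TOTALS


@dataclass
class ScoreSet:
    model_form: str  # weighted_sums | unweighted_sums | item_level
    predictor_labels: list[str]
    X: pd.DataFrame  # patients x predictors
    study_ids: pd.Series
    weights_used: WeightVector | None = None

    def __post_init__(self) -> None:
        if list(self.X.columns) != self.predictor_labels:
            raise ValueError("predictor matrix columns must match predictor_labels")

    def to_csv(self, path) -> None:
        out = self.X.copy()
        out.insert(0, STUDY_ID, self.study_ids.to_numpy())
        out.to_csv(path, index=False)


def _pool(tables: list[StudyTable]) -> pd.DataFrame:
    return pd.concat([t.data for t in tables], ignore_index=True)


def weighted_scores(tables: list[StudyTable], weights: WeightVector) -> ScoreSet:
    """Five predictors: weighted depressive sum, weighted anxiety sum, and
    each auxiliary total multiplied by its weight."""
    w = weights.as_series()
    missing = [v for v in BASELINE_VARS if v not in w.index]
    if missing:
        raise ValueError(f"weight vector lacks labels: {missing}")
    pooled = _pool(tables)
    X = pd.DataFrame(index=pooled.index)
    X["bdi_score"] = pooled[BDI_ITEMS].to_numpy() @ w[BDI_ITEMS].to_numpy()
    X["anxiety_score"] = pooled[ANX_SUBSCALES].to_numpy() @ w[ANX_SUBSCALES].to_numpy()
    for v in AUX_TOTALS:
        X[v] = w[v] * pooled[v].to_numpy()
    return ScoreSet("weighted_sums", SUM_SCORE_LABELS, X, pooled[STUDY_ID], weights)


def unweighted_scores(tables: list[StudyTable]) -> ScoreSet:
    """Five predictors: plain depressive total (0-63), anxiety subscale
    total, and the three auxiliary totals."""
    pooled = _pool(tables)
    X = pd.DataFrame(index=pooled.index)
    X["bdi_score"] = pooled[BDI_ITEMS].sum(axis=1).astype(float)
    X["anxiety_score"] = pooled[ANX_SUBSCALES].sum(axis=1).astype(float)
    for v in AUX_TOTALS:
        X[v] = pooled[v].astype(float)
    return ScoreSet("unweighted_sums", SUM_SCORE_LABELS, X, pooled[STUDY_ID])


def item_level_predictors(tables: list[StudyTable]) -> ScoreSet:
    """All 32 baseline variables as individual predictors, fixed order."""
    pooled = _pool(tables)
    X = pooled[BASELINE_VARS].astype(float)
    return ScoreSet("item_level", list(BASELINE_VARS), X, pooled[STUDY_ID])


def outcome_vectors(tables: list[StudyTable]) -> tuple[np.ndarray, np.ndarray]:
    """Pooled (continuous outcome, remission flag) arrays, aligned with the
    score-set rows."""
    pooled = _pool(tables)
    return pooled["outcome_bdi"].to_numpy(dtype=float), pooled["remission"].to_numpy(dtype=float)
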