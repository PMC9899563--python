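"""Missing-data policy: iterative random-forest imputation with a <30% rule.

Baseline variables with a missing fraction below the policy bound are filled
by iterative tree-ensemble imputation in the style of missForest: each
incomplete variable is regressed on all the others (plus study indicators),
cycling until the change in imputed values starts increasing or the
iteration cap is hit. Variables at or above the bound are left untouched
and flagged. Training-set outcomes may be imputed when configured;
test-set outcomes are never imputed — test patients without an outcome are
excluded from evaluation instead.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .synthetic import StudyTable
from .variables import BASELINE_VARS, OUTCOME, REMISSION, REMISSION_THRESHOLD, VALUE_RANGES


@dataclass
class ImputePolicy:
    max_missing_fraction: float = 0.30  # exclusive bound
    max_iterations: int = 10
    convergence: float = 1e-5  # relative change floor on imputed values
    n_trees: int = 100
    seed: int = 0
    impute_training_outcome: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.max_missing_fraction <= 1.0:
            raise ValueError("max_missing_fraction must lie in (0, 1]")


@dataclass
class ImputationReport:
    missing_fractions: dict[str, float] = field(default_factory=dict)
    imputed_cells: dict[str, int] = field(default_factory=dict)
    skipped_variables: list[str] = field(default_factory=list)
    iterations: int = 0

    @property
    def total_imputed(self) -> int:
        return sum(self.imputed_cells.values())

    def to_json(self) -> str:
        return json.dumps(
            {
                "missing_fractions": self.missing_fractions,
                "imputed_cells": self.imputed_cells,
                "skipped_variables": self.skipped_variables,
                "iterations": self.iterations,
            },
            indent=2,
        )


def _round_to_range(values: np.ndarray, col: str) -> np.ndarray:
    lo, hi = VALUE_RANGES[col]
    return np.clip(np.round(values), lo, hi)


def impute_tables(
    tables: list[StudyTable], role: str, policy: ImputePolicy
) -> tuple[list[StudyTable], ImputationReport]:
    """Impute a collection of same-role study tables, pooled across studies.

    Study membership enters the imputation models as one-hot indicators so
    between-study mean differences inform the fills. Returns new tables and
    a report; the input is not modified. Deterministic given the policy seed.
    """
    if role not in ("train", "test"):
        raise ValueError("role must be 'train' or 'test'")
    report = ImputationReport()

    pooled = pd.concat([t.data for t in tables], ignore_index=True)
    target_cols = list(BASELINE_VARS)
    if role == "train" and policy.impute_training_outcome:
        target_cols.append(OUTCOME)

    frac = pooled[target_cols].isna().mean()
    report.missing_fractions = {c: float(frac[c]) for c in target_cols}
    fully_missing = [c for c in target_cols if frac[c] >= 1.0]
    if fully_missing:
        raise ValueError(f"variable(s) entirely missing: {fully_missing}")
    impute_cols = [c for c in target_cols if 0 < frac[c] < policy.max_missing_fraction]
    report.skipped_variables = [c for c in target_cols if frac[c] >= policy.max_missing_fraction]
    report.imputed_cells = {c: int(pooled[c].isna().sum()) for c in impute_cols}

    if impute_cols:
        feature_cols = list(BASELINE_VARS)
        if role == "train" and policy.impute_training_outcome and OUTCOME in impute_cols:
            feature_cols = feature_cols + [OUTCOME]
        filled = _miss_forest(
            pooled[feature_cols].astype(float), impute_cols, policy, report,
            study=pooled["study_id"],
        )
        for c in impute_cols:
            pooled[c] = _round_to_range(filled[c].to_numpy(), c)

    if role == "train" and policy.impute_training_outcome and OUTCOME in impute_cols:
        pooled[REMISSION] = (pooled[OUTCOME] <= REMISSION_THRESHOLD).astype(float)

    out: list[StudyTable] = []
    offset = 0
    for t in tables:
        chunk = pooled.iloc[offset : offset + len(t.data)].reset_index(drop=True)
        if role == "test":
            # test outcomes are contractually untouched
            chunk[OUTCOME] = t.data[OUTCOME].to_numpy()
            chunk[REMISSION] = t.data[REMISSION].to_numpy()
        out.append(StudyTable(t.study_id, t.role, chunk))
        offset += len(t.data)
    return out, report


def _miss_forest(
    frame: pd.DataFrame,
    impute_cols: list[str],
    policy: ImputePolicy,
    report: ImputationReport,
    study: pd.Series,
) -> pd.DataFrame:
    """missForest-style loop: mean-initialise, cycle RF fits per incomplete
    variable (ascending missingness), stop when the sum of squared changes
    in the imputed values increases or drops below the convergence floor."""
    na_mask = frame.isna()
    current = frame.copy()
    for c in current.columns:
        if na_mask[c].any():
            current.loc[na_mask[c], c] = current[c].mean()

    dummies = pd.get_dummies(study, prefix="study", dtype=float)
    order = sorted(impute_cols, key=lambda c: na_mask[c].sum())
    rng = np.random.default_rng(policy.seed)
    prev_diff = np.inf
    best = current.copy()
    for it in range(policy.max_iterations):
        previous = current.copy()
        for c in order:
            miss = na_mask[c].to_numpy()
            predictors = pd.concat([current.drop(columns=[c]), dummies], axis=1)
            rf = RandomForestRegressor(
                n_estimators=policy.n_trees,
                random_state=int(rng.integers(2**31 - 1)),
                n_jobs=1,
            )
            rf.fit(predictors[~miss], current.loc[~miss, c])
            current.loc[miss, c] = rf.predict(predictors[miss])
        num = sum(
            float(((current[c] - previous[c])[na_mask[c]] ** 2).sum()) for c in order
        )
        den = sum(float((current[c][na_mask[c]] ** 2).sum()) for c in order)
        diff = num / den if den > 0 else 0.0
        report.iterations = it + 1
        if diff >= prev_diff:
            current = previous  # change increased: keep the previous iterate
            break
        best = current.copy()
        prev_diff = diff
        if diff < policy.convergence:
            break
    else:
        current = best
    return current


def filter_test_outcomes(tables: list[StudyTable]) -> tuple[list[StudyTable], int]:
    """Drop test patients with missing outcomes; return retained tables and
    the number excluded."""
    out: list[StudyTable] = []
    n_excluded = 0
    for t in tables:
        keep = t.data[OUTCOME].notna()
        n_excluded += int((~keep).sum())
        out.append(StudyTable(t.study_id, t.role, t.data[keep].reset_index(drop=True)))
    if all(t.n == 0 for t in out):
        warnings.warn("all test outcomes missing: empty analysis set", stacklevel=2)
    return out, n_excluded
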