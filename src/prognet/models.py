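"""The nine prognostic modelling approaches and their fitting routines.

Model registry (per outcome; the same nine are fitted for the continuous
follow-up total and for remission, 18 fits in all):

1. OLS/logistic on one-step expected-influence weighted sum scores
2. OLS/logistic on two-step expected-influence weighted sum scores
3. OLS/logistic on PC/PR-geometric-mean weighted sum scores
4. OLS/logistic on CFA-loading weighted sum scores
5. elastic net on the unweighted sum scores
6. OLS/logistic on the unweighted sum scores
7. elastic net on the 32 individual items/totals
8. OLS/logistic on the 32 individual items/totals
9. null model (training outcome mean / training remission proportion)

Elastic-net fits standardize predictors internally, search an
(alpha, lambda) grid by study-stratified 10-fold cross-validation, refit
at the selected pair on the full training data, and back-transform the
coefficients to the natural predictor scale.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.linear_model import ElasticNet, LinearRegression, LogisticRegression

from .scores import ScoreSet

WEIGHTED_METHODS = {1: "EI1", 2: "EI2", 3: "PCPR", 4: "CFA"}

#: model_id -> (weighting, predictor form, estimator family)
MODEL_REGISTRY: dict[int, tuple[str, str, str]] = {
    1: ("EI1", "weighted_sums", "regression"),
    2: ("EI2", "weighted_sums", "regression"),
    3: ("PCPR", "weighted_sums", "regression"),
    4: ("CFA", "weighted_sums", "regression"),
    5: ("none", "unweighted_sums", "ENR"),
    6: ("none", "unweighted_sums", "regression"),
    7: ("none", "item_level", "ENR"),
    8: ("none", "item_level", "regression"),
    9: ("none", "null", "null"),
}

MODEL_IDS = tuple(MODEL_REGISTRY)
OUTCOMES = ("continuous", "remission")


@dataclass(frozen=True)
class ModelSpec:
    model_id: int
    weighting: str
    form: str
    estimator: str  # OLS | logistic | ENR | null
    outcome: str  # continuous | remission


def model_spec(model_id: int, outcome: str) -> ModelSpec:
    if model_id not in MODEL_REGISTRY:
        raise ValueError(f"model_id must be 1..9, got {model_id}")
    if outcome not in OUTCOMES:
        raise ValueError(f"outcome must be one of {OUTCOMES}")
    weighting, form, est = MODEL_REGISTRY[model_id]
    if est == "regression":
        est = "OLS" if outcome == "continuous" else "logistic"
    return ModelSpec(model_id, weighting, form, est, outcome)


@dataclass
class FittedModel:
    spec: ModelSpec
    intercept: float = 0.0
    coefficients: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    enr_alpha: float | None = None
    enr_lambda: float | None = None
    null_value: float | None = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "spec": self.spec.__dict__,
                "intercept": self.intercept,
                "coefficients": self.coefficients.to_dict(),
                "enr_alpha": self.enr_alpha,
                "enr_lambda": self.enr_lambda,
                "null_value": self.null_value,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "FittedModel":
        d = json.loads(text)
        return cls(
            spec=ModelSpec(**d["spec"]),
            intercept=d["intercept"],
            coefficients=pd.Series(d["coefficients"], dtype=float),
            enr_alpha=d["enr_alpha"],
            enr_lambda=d["enr_lambda"],
            null_value=d["null_value"],
        )


@dataclass
class EnrOptions:
    alpha_grid: list[float] = field(
        default_factory=lambda: list(np.round(np.arange(0.05, 1.0001, 0.05), 2))
    )
    n_lambda: int = 100
    lambda_min_ratio: float = 1e-3
    lambda_grid: list[float] | None = None  # overrides the auto path
    folds: int = 10


def stratified_fold_labels(
    study_ids: pd.Series, folds: int, rng: np.random.Generator
) -> np.ndarray:
    """Fold assignment stratified by study: round-robin within each study
    over a shuffled order."""
    labels = np.empty(len(study_ids), dtype=int)
    for sid in pd.unique(study_ids):
        idx = np.flatnonzero((study_ids == sid).to_numpy())
        lab = np.arange(len(idx)) % folds
        rng.shuffle(lab)
        labels[idx] = lab
    return labels


def fit_regression(scores: ScoreSet, outcome: np.ndarray, family: str) -> FittedModel:
    """Unpenalised maximum-likelihood fit: OLS (gaussian) or logistic
    (binomial) with an intercept."""
    spec_outcome = "continuous" if family == "gaussian" else "remission"
    X_full = scores.X.to_numpy(dtype=float)
    y = np.asarray(outcome, dtype=float)
    # a zero-weighted (constant) predictor carries no information: fit
    # without it and report a zero coefficient
    keep = X_full.std(axis=0) > 0
    if not keep.all():
        dropped = [l for l, k in zip(scores.predictor_labels, keep) if not k]
        warnings.warn(f"constant predictor(s) excluded: {dropped}", stacklevel=2)
    X = sm.add_constant(X_full[:, keep], has_constant="add")
    if family == "gaussian":
        if len(y) <= X.shape[1]:
            raise ValueError("need more observations than predictors for OLS")
        res = sm.OLS(y, X).fit()
    elif family == "binomial":
        res = sm.Logit(y, X).fit(disp=0, maxiter=100)
        if not res.mle_retvals.get("converged", True):
            raise RuntimeError("logistic regression did not converge")
    else:
        raise ValueError(f"unknown family: {family!r}")
    params = np.asarray(res.params)
    coef = np.zeros(len(scores.predictor_labels))
    coef[keep] = params[1:]
    spec = ModelSpec(0, "none", scores.model_form,
                     "OLS" if family == "gaussian" else "logistic", spec_outcome)
    return FittedModel(
        spec=spec,
        intercept=float(params[0]),
        coefficients=pd.Series(coef, index=scores.predictor_labels),
    )


def _lambda_path(Xs: np.ndarray, y: np.ndarray, alpha: float, opts: EnrOptions,
                 family: str) -> np.ndarray:
    if opts.lambda_grid is not None:
        return np.asarray(sorted(opts.lambda_grid, reverse=True), dtype=float)
    n = len(y)
    resid = y - y.mean()
    lam_max = np.max(np.abs(Xs.T @ resid)) / (n * max(alpha, 1e-3))
    lam_max = max(lam_max, 1e-6)
    return np.logspace(np.log10(lam_max), np.log10(lam_max * opts.lambda_min_ratio),
                       opts.n_lambda)


def _enr_fit_std(Xs: np.ndarray, y: np.ndarray, alpha: float, lam: float,
                 family: str, seed: int) -> tuple[float, np.ndarray]:
    """Fit one elastic-net candidate on standardized predictors; returns
    (intercept, coefficients) on that scale."""
    if lam <= 0:
        if family == "gaussian":
            m = LinearRegression().fit(Xs, y)
        else:
            m = LogisticRegression(C=np.inf, max_iter=2000).fit(Xs, y)
    elif family == "gaussian":
        m = ElasticNet(alpha=lam, l1_ratio=alpha, max_iter=20000, tol=1e-7).fit(Xs, y)
    else:
        m = LogisticRegression(
            solver="saga",
            l1_ratio=alpha,
            C=1.0 / (len(y) * lam),
            max_iter=5000,
            tol=1e-6,
            random_state=seed,
        ).fit(Xs, y)
    coef = np.ravel(m.coef_)
    intercept = float(np.ravel(m.intercept_)[0]) if family != "gaussian" else float(m.intercept_)
    return intercept, coef


def _held_out_loss(intercept: float, coef: np.ndarray, Xs: np.ndarray,
                   y: np.ndarray, family: str) -> float:
    eta = intercept + Xs @ coef
    if family == "gaussian":
        return float(np.mean((y - eta) ** 2))
    p = 1.0 / (1.0 + np.exp(-eta))
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(-2.0 * np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def fit_enr(
    scores: ScoreSet,
    outcome: np.ndarray,
    family: str,
    options: EnrOptions | None = None,
    seed: int = 0,
) -> FittedModel:
    """Cross-validated elastic net: minimum mean held-out MSE (gaussian) or
    deviance (binomial) over the (alpha, lambda) grid; refit on the full
    training data at the selected pair. Deterministic given the seed."""
    opts = options or EnrOptions()
    if not opts.alpha_grid:
        raise ValueError("alpha grid must be non-empty")
    y = np.asarray(outcome, dtype=float)
    X = scores.X.to_numpy(dtype=float)
    mu, sd = X.mean(axis=0), X.std(axis=0)
    keep = sd > 0
    if not keep.all():
        dropped = [l for l, k in zip(scores.predictor_labels, keep) if not k]
        warnings.warn(f"constant predictor(s) excluded from elastic net: {dropped}",
                      stacklevel=2)
    Xs = (X[:, keep] - mu[keep]) / sd[keep]

    rng = np.random.default_rng(seed)
    fold = stratified_fold_labels(scores.study_ids, opts.folds, rng)
    best = (np.inf, None, None)
    for alpha in opts.alpha_grid:
        lam_path = _lambda_path(Xs, y, alpha, opts, family)
        losses = np.zeros(len(lam_path))
        for f in range(opts.folds):
            tr, ho = fold != f, fold == f
            for i, lam in enumerate(lam_path):
                b0, b = _enr_fit_std(Xs[tr], y[tr], alpha, lam, family, seed)
                losses[i] += _held_out_loss(b0, b, Xs[ho], y[ho], family)
        losses /= opts.folds
        i = int(np.argmin(losses))
        if losses[i] < best[0]:
            best = (losses[i], float(alpha), float(lam_path[i]))
    _, alpha_sel, lam_sel = best
    b0, b = _enr_fit_std(Xs, y, alpha_sel, lam_sel, family, seed)

    coef = np.zeros(len(scores.predictor_labels))
    coef[keep] = b / sd[keep]
    intercept = b0 - float((b * mu[keep] / sd[keep]).sum())
    spec_outcome = "continuous" if family == "gaussian" else "remission"
    spec = ModelSpec(0, "none", scores.model_form, "ENR", spec_outcome)
    return FittedModel(
        spec=spec,
        intercept=intercept,
        coefficients=pd.Series(coef, index=scores.predictor_labels),
        enr_alpha=alpha_sel,
        enr_lambda=lam_sel,
    )


def fit_null(outcome: np.ndarray, family: str) -> FittedModel:
    """Constant prediction: training outcome mean (gaussian) or training
    remission proportion (binomial)."""
    y = np.asarray(outcome, dtype=float)
    if y.size < 1:
        raise ValueError("need at least one outcome value")
    spec_outcome = "continuous" if family == "gaussian" else "remission"
    spec = ModelSpec(9, "none", "null", "null", spec_outcome)
    return FittedModel(spec=spec, null_value=float(y.mean()))


def predict(model: FittedModel, scores: ScoreSet | None) -> np.ndarray:
    """Predictions on a score set: linear predictor, passed through the
    inverse logit for remission models; the null model returns its stored
    constant."""
    if model.spec.estimator == "null":
        if scores is None:
            raise ValueError("null prediction needs a score set for its length")
        return np.full(len(scores.X), model.null_value)
    if list(scores.X.columns) != list(model.coefficients.index):
        raise ValueError("score-set labels do not match the fitted model")
    eta = model.intercept + scores.X.to_numpy(dtype=float) @ model.coefficients.to_numpy()
    if model.spec.outcome == "remission" :
        return 1.0 / (1.0 + np.exp(-eta))
    return eta
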