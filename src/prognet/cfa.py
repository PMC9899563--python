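"""Unidimensional confirmatory factor analysis by maximum likelihood.

Fits the model Sigma(theta) = lambda lambda' + diag(psi) with the factor
variance fixed at 1, minimising the ML discrepancy

    F_ML = log|Sigma| + tr(S Sigma^-1) - log|S| - p

over standardized loadings and residual variances with an analytic
gradient (quasi-Newton). The standardized loadings are then min-max
rescaled to [0, 1] with the same block convention as the network
centralities, yielding the factor-based item weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .centrality import WeightVector, rescale_by_block
from .synthetic import StudyTable
from .variables import BASELINE_VARS

_PSI_FLOOR = 1e-6


@dataclass
class FactorLoadings:
    node_labels: list[str]
    loadings: np.ndarray
    residual_variances: np.ndarray
    fit_value: float
    converged: bool
    heywood: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": self.node_labels,
                "loading": self.loadings,
                "residual_variance": self.residual_variances,
            }
        )

    def summary_json(self) -> str:
        import json

        return json.dumps(
            {
                "fit_value": self.fit_value,
                "converged": self.converged,
                "heywood": self.heywood,
                "n_variables": len(self.node_labels),
            }
        )


def _discrepancy_and_grad(
    params: np.ndarray, S: np.ndarray, logdet_S: float
) -> tuple[float, np.ndarray]:
    p = S.shape[0]
    lam, psi = params[:p], params[p:]
    sigma = np.outer(lam, lam) + np.diag(psi)
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        return np.inf, np.zeros_like(params)
    sigma_inv = np.linalg.inv(sigma)
    f = logdet + float(np.trace(S @ sigma_inv)) - logdet_S - p
    G = sigma_inv - sigma_inv @ S @ sigma_inv
    grad = np.concatenate([2.0 * G @ lam, np.diag(G)])
    return f, grad


def fit_one_factor_from_cov(
    S: np.ndarray, node_labels: list[str] | None = None, tol: float = 1e-10
) -> FactorLoadings:
    """ML one-factor solution for a covariance/correlation matrix.

    Deterministic: started from the leading eigenvector scaled to explain
    the leading eigenvalue. Residual variances hitting the positivity
    floor are clamped and flagged (Heywood case).
    """
    S = np.asarray(S, dtype=float)
    p = S.shape[0]
    if p < 3:
        raise ValueError("one-factor model needs at least 3 variables")
    node_labels = node_labels or list(BASELINE_VARS)[:p]
    sign, logdet_S = np.linalg.slogdet(S)
    if sign <= 0:
        raise ValueError("input covariance matrix is not positive definite")

    eigval, eigvec = np.linalg.eigh(S)
    lam0 = np.sqrt(max(eigval[-1], 1e-3)) * eigvec[:, -1]
    if lam0.sum() < 0:
        lam0 = -lam0
    psi0 = np.clip(np.diag(S) - lam0**2, 0.05, None)

    bounds = [(None, None)] * p + [(_PSI_FLOOR, None)] * p
    res = optimize.minimize(
        _discrepancy_and_grad,
        np.concatenate([lam0, psi0]),
        args=(S, logdet_S),
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": 2000, "ftol": tol, "gtol": 1e-10},
    )
    lam, psi = res.x[:p], res.x[p:]
    if np.sum(lam > 0) < np.sum(lam < 0):  # sign convention: majority positive
        lam = -lam
    heywood = bool(np.any(psi <= _PSI_FLOOR * 1.01))
    if not res.success and res.status != 0:
        # tolerate precision-loss terminations with a small gradient
        if np.max(np.abs(res.jac)) > 1e-4:
            raise RuntimeError(f"one-factor ML did not converge: {res.message}")
    return FactorLoadings(
        node_labels=node_labels,
        loadings=lam,
        residual_variances=psi,
        fit_value=float(res.fun),
        converged=True,
        heywood=heywood,
    )


def fit_one_factor(tables: list[StudyTable], columns: list[str] | None = None) -> FactorLoadings:
    """Fit on the pooled, within-study standardized training data."""
    columns = columns or BASELINE_VARS
    chunks = []
    for t in tables:
        X = t.data[columns].to_numpy(dtype=float)
        sd = X.std(axis=0, ddof=1)
        if np.any(sd == 0):
            bad = columns[int(np.flatnonzero(sd == 0)[0])]
            raise ValueError(f"zero-variance variable {bad!r} in study {t.study_id}")
        chunks.append((X - X.mean(axis=0)) / sd)
    Z = np.vstack(chunks)
    S = np.corrcoef(Z, rowvar=False)
    return fit_one_factor_from_cov(S, list(columns))


def loadings_to_weights(fit: FactorLoadings) -> WeightVector:
    """Convert standardized loadings into [0, 1] weights (block-wise
    min-max rescale, same convention as the centrality weights)."""
    if not fit.converged:
        raise ValueError("cannot build weights from a non-converged factor fit")
    rescaled = rescale_by_block(fit.loadings, fit.node_labels)
    return WeightVector("CFA", list(fit.node_labels), fit.loadings.copy(), rescaled)
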