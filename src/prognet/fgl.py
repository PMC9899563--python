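"""Fused graphical lasso over multiple studies, solved by ADMM.

Jointly estimates one sparse Gaussian graphical model per study while
shrinking corresponding precision entries toward equality across studies:

    min_{Theta_k > 0}  sum_k n_k [ -log det Theta_k + tr(S_k Theta_k) ]
                       + lambda1 * sum_k sum_{i != j} |theta_ij^(k)|
                       + lambda2 * sum_{k<k'} sum_{i,j} |theta_ij^(k) - theta_ij^(k')|

The fused network reported to downstream centrality code is the
across-study mean of the per-study partial correlations
-theta_ij / sqrt(theta_ii * theta_jj).

The ADMM split introduces consensus variables Z_k; the Z-update is the
proximal operator of the combined fused + L1 penalty, computed exactly
elementwise: solve the pure fusion problem over the K values (closed form
for K <= 2; exact enumeration of contiguous partitions of the sorted
values otherwise) and then soft-threshold, which is valid because
soft-thresholding commutes with the fusion proximal map.

Penalty pairs are selected by cross-validation on held-out Gaussian
log-likelihood with patients partitioned into folds stratified by study.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import StudyTable
from .variables import BASELINE_VARS


class FGLConvergenceError(RuntimeError):
    pass


@dataclass
class AdmmOptions:
    rho: float = 1.0
    tol: float = 1e-6
    max_iter: int = 5000
    adaptive_rho: bool = True


@dataclass
class NetworkModel:
    node_labels: list[str]
    precisions: list[np.ndarray]  # one symmetric PD matrix per study
    fused_edges: np.ndarray  # mean partial correlations, zero diagonal
    lambda1: float
    lambda2: float
    sample_sizes: list[int]
    n_iter: int = 0

    def validate(self) -> None:
        W = self.fused_edges
        if not np.allclose(W, W.T):
            raise ValueError("fused_edges must be symmetric")
        if np.any(np.diag(W) != 0):
            raise ValueError("fused_edges diagonal must be zero")
        if np.any(np.abs(W) >= 1):
            raise ValueError("fused partial correlations must have |w| < 1")
        for k, theta in enumerate(self.precisions):
            if np.min(np.linalg.eigvalsh(theta)) <= 0:
                raise ValueError(f"precision matrix {k} not positive definite")

    def to_json(self) -> str:
        return json.dumps(
            {
                "node_labels": self.node_labels,
                "precisions": [t.tolist() for t in self.precisions],
                "fused_edges": self.fused_edges.tolist(),
                "lambda1": self.lambda1,
                "lambda2": self.lambda2,
                "sample_sizes": self.sample_sizes,
                "n_iter": self.n_iter,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "NetworkModel":
        d = json.loads(text)
        return cls(
            node_labels=d["node_labels"],
            precisions=[np.asarray(t) for t in d["precisions"]],
            fused_edges=np.asarray(d["fused_edges"]),
            lambda1=d["lambda1"],
            lambda2=d["lambda2"],
            sample_sizes=d["sample_sizes"],
            n_iter=d.get("n_iter", 0),
        )

    def edge_list(self) -> pd.DataFrame:
        rows = []
        p = len(self.node_labels)
        for i in range(p):
            for j in range(i + 1, p):
                w = self.fused_edges[i, j]
                if w != 0:
                    rows.append((self.node_labels[i], self.node_labels[j], w))
        return pd.DataFrame(rows, columns=["node_i", "node_j", "weight"])


def standardized_covariances(
    tables: list[StudyTable], columns: list[str] | None = None
) -> tuple[list[np.ndarray], list[int]]:
    """Per-study sample correlation matrices of the baseline variables
    (each variable standardized within its study)."""
    columns = columns or BASELINE_VARS
    S_list, n_list = [], []
    for t in tables:
        X = t.data[columns].to_numpy(dtype=float)
        if X.shape[0] < 2:
            raise ValueError(f"{t.study_id}: need at least 2 patients")
        sd = X.std(axis=0, ddof=1)
        zero = np.flatnonzero(sd == 0)
        if zero.size:
            raise ValueError(
                f"zero-variance variable {columns[zero[0]]!r} in study {t.study_id}"
            )
        Z = (X - X.mean(axis=0)) / sd
        S_list.append((Z.T @ Z) / (X.shape[0] - 1))
        n_list.append(X.shape[0])
    return S_list, n_list


# -- proximal operator of the fused (+ L1) penalty ---------------------------


def _fuse_prox_k2(A: np.ndarray, gamma: float) -> np.ndarray:
    a1, a2 = A[0], A[1]
    d = a1 - a2
    shift = np.clip(d / 2.0, -gamma, gamma)
    return np.stack([a1 - shift, a2 + shift])


def _contiguous_partitions(K: int) -> list[list[tuple[int, int]]]:
    """All ways to split range(K) into contiguous groups, as (start, stop)."""
    parts = []
    for cuts in itertools.product([0, 1], repeat=K - 1):
        groups, start = [], 0
        for i, c in enumerate(cuts, start=1):
            if c:
                groups.append((start, i))
                start = i
        groups.append((start, K))
        parts.append(groups)
    return parts


def _fuse_prox_general(A: np.ndarray, gamma: float) -> np.ndarray:
    """Exact prox of gamma * sum_{k<k'} |z_k - z_k'| at each element of the
    K x m array A, by enumerating contiguous partitions of the sorted values.

    The optimum is order-preserving and constant on its fused groups, so it
    appears among the candidates; picking the candidate with the smallest
    exact objective is therefore exact.
    """
    K, m = A.shape
    order = np.argsort(A, axis=0)
    As = np.take_along_axis(A, order, axis=0)
    best_obj = np.full(m, np.inf)
    best_z = np.empty_like(As)
    for groups in _contiguous_partitions(K):
        z = np.empty_like(As)
        for start, stop in groups:
            n_g = stop - start
            n_below, n_above = start, K - stop
            v = As[start:stop].mean(axis=0) - gamma * (n_below - n_above)
            z[start:stop] = v
        obj = 0.5 * ((z - As) ** 2).sum(axis=0)
        for i in range(K):
            for j in range(i + 1, K):
                obj += gamma * np.abs(z[i] - z[j])
        better = obj < best_obj
        best_obj[better] = obj[better]
        best_z[:, better] = z[:, better]
    out = np.empty_like(A)
    np.put_along_axis(out, order, best_z, axis=0)
    return out


def _soft(x: np.ndarray, t: float) -> np.ndarray:
    return np.sign(x) * np.maximum(np.abs(x) - t, 0.0)


def _z_update(
    A: np.ndarray, lambda1: float, lambda2: float, rho: float, offdiag: np.ndarray
) -> np.ndarray:
    """Prox of (lambda1 * L1 on off-diagonals + lambda2 * fusion)/rho at A
    (shape K x p x p)."""
    K, p, _ = A.shape
    if K == 1:
        Z = A.copy()
    elif lambda2 == 0:
        Z = A.copy()
    elif K == 2:
        Z = _fuse_prox_k2(A.reshape(2, -1), lambda2 / rho).reshape(A.shape)
    else:
        Z = _fuse_prox_general(A.reshape(K, -1), lambda2 / rho).reshape(A.shape)
    if lambda1 > 0:
        Z = np.where(offdiag[None], _soft(Z, lambda1 / rho), Z)
    # exact symmetry guards against drift from elementwise tie-breaking
    return (Z + np.transpose(Z, (0, 2, 1))) / 2.0


def fgl_objective(
    thetas: list[np.ndarray] | np.ndarray,
    S_list: list[np.ndarray],
    n_list: list[int],
    lambda1: float,
    lambda2: float,
) -> float:
    """The penalised negative log-likelihood; +inf if any Theta_k is not PD."""
    thetas = [np.asarray(t) for t in thetas]
    total = 0.0
    for theta, S, n in zip(thetas, S_list, n_list):
        sign, logdet = np.linalg.slogdet(theta)
        if sign <= 0 or np.min(np.linalg.eigvalsh(theta)) <= 0:
            return np.inf
        total += n * (-logdet + np.trace(S @ theta))
        total += lambda1 * (np.abs(theta).sum() - np.abs(np.diag(theta)).sum())
    for a, b in itertools.combinations(thetas, 2):
        total += lambda2 * np.abs(a - b).sum()
    return float(total)


def fit_fgl(
    S_list: list[np.ndarray],
    n_list: list[int],
    lambda1: float,
    lambda2: float,
    options: AdmmOptions | None = None,
    node_labels: list[str] | None = None,
) -> NetworkModel:
    """Solve the fused graphical lasso by ADMM.

    Raises :class:`FGLConvergenceError` (reporting residuals) if the
    primal/dual residuals do not fall below tolerance within the cap.
    """
    opts = options or AdmmOptions()
    if lambda1 < 0 or lambda2 < 0:
        raise ValueError("penalties must be non-negative")
    K = len(S_list)
    p = S_list[0].shape[0]
    n_arr = np.asarray(n_list, dtype=float)
    S = np.stack(S_list)
    offdiag = ~np.eye(p, dtype=bool)

    rho = opts.rho
    Theta = np.stack([np.eye(p) for _ in range(K)])
    Z = Theta.copy()
    U = np.zeros_like(Theta)

    n_iter = 0
    for n_iter in range(1, opts.max_iter + 1):
        # Theta-update: eigen solve of rho*Theta - n_k*inv(Theta) = M_k
        for k in range(K):
            M = rho * (Z[k] - U[k]) - n_arr[k] * S[k]
            M = (M + M.T) / 2.0
            d, V = np.linalg.eigh(M)
            theta_eigs = (d + np.sqrt(d**2 + 4.0 * rho * n_arr[k])) / (2.0 * rho)
            Theta[k] = (V * theta_eigs) @ V.T
        Z_old = Z
        Z = _z_update(Theta + U, lambda1, lambda2, rho, offdiag)
        U = U + Theta - Z

        r_norm = np.linalg.norm(Theta - Z)
        s_norm = rho * np.linalg.norm(Z - Z_old)
        scale = max(1.0, np.linalg.norm(Theta), np.linalg.norm(Z))
        if r_norm < opts.tol * scale and s_norm < opts.tol * scale:
            break
        if opts.adaptive_rho and n_iter % 10 == 0:
            if r_norm > 10 * s_norm:
                rho *= 2.0
                U /= 2.0
            elif s_norm > 10 * r_norm:
                rho /= 2.0
                U *= 2.0
    else:
        raise FGLConvergenceError(
            f"ADMM did not converge in {opts.max_iter} iterations "
            f"(primal residual {r_norm:.3e}, dual residual {s_norm:.3e})"
        )

    precisions = []
    for k in range(K):
        theta = (Z[k] + Z[k].T) / 2.0
        if np.min(np.linalg.eigvalsh(theta)) <= 0:
            theta = (Theta[k] + Theta[k].T) / 2.0  # smooth iterate is always PD
        precisions.append(theta)

    W = np.zeros((p, p))
    for theta in precisions:
        d = np.sqrt(np.diag(theta))
        W += -theta / np.outer(d, d)
    W /= K
    np.fill_diagonal(W, 0.0)
    W = np.clip((W + W.T) / 2.0, -0.999999, 0.999999)

    model = NetworkModel(
        node_labels=node_labels or list(BASELINE_VARS)[:p],
        precisions=precisions,
        fused_edges=W,
        lambda1=float(lambda1),
        lambda2=float(lambda2),
        sample_sizes=[int(n) for n in n_list],
        n_iter=n_iter,
    )
    return model


# -- penalty selection -------------------------------------------------------


def _study_stratified_folds(
    tables: list[StudyTable], folds: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Per-study arrays of fold labels, round-robin over a shuffled order."""
    assignments = []
    for t in tables:
        lab = np.arange(t.n) % folds
        rng.shuffle(lab)
        assignments.append(lab)
    return assignments


def select_penalties(
    tables: list[StudyTable],
    lambda1_grid: list[float] | None = None,
    lambda2_grid: list[float] | None = None,
    folds: int = 10,
    seed: int = 0,
    options: AdmmOptions | None = None,
    columns: list[str] | None = None,
) -> tuple[float, float]:
    """Pick (lambda1, lambda2) maximising mean held-out Gaussian
    log-likelihood over study-stratified patient folds."""
    lambda1_grid = list(lambda1_grid if lambda1_grid is not None
                        else np.logspace(np.log10(0.01), 0.0, 10))
    lambda2_grid = list(lambda2_grid if lambda2_grid is not None
                        else [0.0, 0.01, 0.05, 0.1, 0.5])
    if not lambda1_grid or not lambda2_grid:
        raise ValueError("penalty grids must be non-empty")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if len(lambda1_grid) == 1 and len(lambda2_grid) == 1:
        return float(lambda1_grid[0]), float(lambda2_grid[0])

    columns = columns or BASELINE_VARS
    rng = np.random.default_rng(seed)
    fold_labels = _study_stratified_folds(tables, folds, rng)

    scores = np.full((len(lambda1_grid), len(lambda2_grid)), -np.inf)
    for i, l1 in enumerate(lambda1_grid):
        for j, l2 in enumerate(lambda2_grid):
            total = 0.0
            ok = True
            for f in range(folds):
                train = [
                    StudyTable(t.study_id, t.role, t.data[lab != f].reset_index(drop=True))
                    for t, lab in zip(tables, fold_labels)
                ]
                hold = [
                    StudyTable(t.study_id, t.role, t.data[lab == f].reset_index(drop=True))
                    for t, lab in zip(tables, fold_labels)
                ]
                try:
                    S_tr, n_tr = standardized_covariances(train, columns)
                    S_ho, n_ho = standardized_covariances(hold, columns)
                    model = fit_fgl(S_tr, n_tr, l1, l2, options, columns)
                except (FGLConvergenceError, ValueError) as exc:
                    warnings.warn(
                        f"penalty pair ({l1:.4g}, {l2:.4g}) failed: {exc}", stacklevel=2
                    )
                    ok = False
                    break
                for theta, S_h, n_h in zip(model.precisions, S_ho, n_ho):
                    sign, logdet = np.linalg.slogdet(theta)
                    total += n_h * (logdet - np.trace(S_h @ theta))
            if ok:
                scores[i, j] = total / folds
    best = np.unravel_index(np.argmax(scores), scores.shape)
    if not np.isfinite(scores[best]):
        raise FGLConvergenceError("no penalty pair converged on any fold")
    return float(lambda1_grid[best[0]]), float(lambda2_grid[best[1]])


def save_network(model: NetworkModel, path: str | Path) -> None:
    Path(path).write_text(model.to_json())


def load_network(path: str | Path) -> NetworkModel:
    return NetworkModel.from_json(Path(path).read_text())
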