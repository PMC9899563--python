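"""Network centrality statistics and their conversion to [0, 1] item weights.

Three centralities are computed on the fused partial-correlation network:
one-step expected influence (signed strength), two-step expected influence
(one-step plus edge-weighted neighbour one-step influence), and the
geometric mean of the participation coefficient and participation ratio
computed against a Walktrap community partition. Raw centralities are
min-max rescaled to [0, 1] separately within each instrument block
(depressive items, anxiety subscales, auxiliary totals).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import igraph as ig
import numpy as np
import pandas as pd

from .fgl import NetworkModel
from .variables import BLOCKS, block_of


@dataclass
class WeightVector:
    method: str  # EI1 | EI2 | PCPR | CFA
    node_labels: list[str]
    raw: np.ndarray
    rescaled: np.ndarray

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        self.rescaled = np.asarray(self.rescaled, dtype=float)
        if not (len(self.node_labels) == len(self.raw) == len(self.rescaled)):
            raise ValueError("labels, raw and rescaled must have equal length")

    def as_series(self) -> pd.Series:
        return pd.Series(self.rescaled, index=self.node_labels, name=self.method)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": self.node_labels,
                "method": self.method,
                "raw": self.raw,
                "rescaled": self.rescaled,
            }
        )


def expected_influence_one_step(W: np.ndarray) -> np.ndarray:
    """EI1_i = signed sum of all edges incident to node i."""
    W = np.asarray(W, dtype=float)
    return W.sum(axis=1)


def expected_influence_two_step(W: np.ndarray) -> np.ndarray:
    """EI2_i = EI1_i + sum_j w_ij * EI1_j (neighbour influence carried over
    the connecting edge, back-edges included)."""
    ei1 = expected_influence_one_step(W)
    return ei1 + np.asarray(W, dtype=float) @ ei1


def walktrap_communities(W: np.ndarray, steps: int = 4) -> np.ndarray:
    """Walktrap community partition of the network using absolute edge
    weights as random-walk affinities; the merge dendrogram is cut at
    maximum modularity. Returns integer community labels per node."""
    A = np.abs(np.asarray(W, dtype=float))
    p = A.shape[0]
    g = ig.Graph.Weighted_Adjacency(A.tolist(), mode="undirected", attr="weight", loops=False)
    if g.ecount() == 0:
        return np.arange(p)
    dendro = g.community_walktrap(weights=g.es["weight"], steps=steps)
    membership = np.asarray(dendro.as_clustering().membership)
    return membership


def participation_metrics(
    W: np.ndarray, partition: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Participation coefficient, participation ratio and their geometric
    mean for every node.

    PC_i = 1 - sum_c (kappa_ic / kappa_i)^2 on absolute weights, where
    kappa_ic is node i's strength into community c. PR_i is the inverse
    Herfindahl index of the normalised absolute edge weights, i.e. the
    effective number of connections (sum|w|)^2 / sum w^2. Zero-strength
    nodes get PC = PR = 0.
    """
    A = np.abs(np.asarray(W, dtype=float))
    partition = np.asarray(partition)
    p = A.shape[0]
    if partition.shape != (p,):
        raise ValueError("partition must cover all nodes")
    strength = A.sum(axis=1)
    pc = np.zeros(p)
    pr = np.zeros(p)
    for i in range(p):
        if strength[i] <= 0:
            continue
        kappa_c = np.bincount(partition, weights=A[i], minlength=partition.max() + 1)
        pc[i] = 1.0 - float(((kappa_c / strength[i]) ** 2).sum())
        pr[i] = strength[i] ** 2 / float((A[i] ** 2).sum())
    gm = np.sqrt(np.clip(pc, 0.0, None) * pr)
    return pc, pr, gm


def minmax_rescale(raw: np.ndarray) -> np.ndarray:
    """Affine map of the raw vector onto [0, 1]; errors on a constant
    vector (weights would be undefined)."""
    raw = np.asarray(raw, dtype=float)
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        raise ValueError("cannot rescale a constant vector to [0, 1]")
    return (raw - lo) / (hi - lo)


def rescale_by_block(
    raw: np.ndarray, node_labels: list[str], fallback: np.ndarray | None = None
) -> np.ndarray:
    """Min-max rescale within each instrument block separately.

    If a block's raw values are constant (undefined weights) and a
    ``fallback`` vector is supplied, that block is rescaled on the fallback
    instead, with a warning; without a usable fallback the error propagates.
    """
    raw = np.asarray(raw, dtype=float)
    out = np.empty_like(raw)
    labels = np.asarray([block_of(lab) for lab in node_labels])
    for block in BLOCKS:
        mask = labels == block
        if not mask.any():
            continue
        try:
            out[mask] = minmax_rescale(raw[mask])
        except ValueError:
            if fallback is None:
                raise
            warnings.warn(
                f"constant raw centrality in block {block!r}; "
                "falling back to the secondary statistic",
                stacklevel=2,
            )
            out[mask] = minmax_rescale(np.asarray(fallback, dtype=float)[mask])
    return out


def centrality_weight_vector(
    network: NetworkModel, method: str, walktrap_steps: int = 4
) -> WeightVector:
    """Compute one of the three centrality-based weight vectors on the
    fused network, rescaled block-wise to [0, 1]."""
    W = network.fused_edges
    fallback = None
    if method == "EI1":
        raw = expected_influence_one_step(W)
    elif method == "EI2":
        raw = expected_influence_two_step(W)
    elif method == "PCPR":
        partition = walktrap_communities(W, steps=walktrap_steps)
        _, pr, raw = participation_metrics(W, partition)
        fallback = pr  # PC degenerates to 0 when a block sits in one community
    else:
        raise ValueError(f"unknown centrality method: {method!r}")
    rescaled = rescale_by_block(raw, network.node_labels, fallback)
    return WeightVector(method, list(network.node_labels), raw, rescaled)
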