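"""Weighted co-expression network construction.

The network is fully connected: every gene pair gets a Pearson
correlation coefficient (PCC) edge weight.  Distances are the inverse of
the absolute PCC, and a hard-thresholded binary graph (|w| > r) supports
the local-maximum search that fixes the cluster count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ValidationError
from .io import ExpressionMatrix

__all__ = [
    "WeightedNetwork",
    "ThresholdedGraph",
    "correlation_network",
    "distance_from_weights",
    "threshold_graph",
]


@dataclass
class WeightedNetwork:
    """A fully connected weighted network over named nodes.

    ``W`` holds symmetric edge weights (signed PCCs in [-1, 1] for
    co-expression networks, or generic weights) with zero diagonal;
    ``mass`` is the strictly positive per-node mass vector (all ones for
    TPSC-1, prior-knowledge scores such as gene-disease-association
    values for TPSC-w); ``r`` is the hard-threshold weight cutoff.
    """

    node_ids: list
    W: np.ndarray
    mass: np.ndarray = None
    r: float = 0.3

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=float)
        n = len(self.node_ids)
        if self.W.shape != (n, n):
            raise ValidationError(f"weight matrix shape {self.W.shape} != ({n}, {n})")
        if not np.allclose(self.W, self.W.T, atol=1e-10):
            raise ValidationError("weight matrix must be symmetric")
        self.W = (self.W + self.W.T) / 2.0
        np.fill_diagonal(self.W, 0.0)
        if self.mass is None:
            self.mass = np.ones(n)
        self.mass = np.asarray(self.mass, dtype=float)
        if self.mass.shape != (n,):
            raise ValidationError("mass vector length must equal node count")
        if not (self.mass > 0).all():
            raise ValidationError("node masses must be strictly positive")
        if not 0 < self.r < 1:
            raise ValidationError(f"weight cutoff r must be in (0, 1), got {self.r}")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)


@dataclass
class ThresholdedGraph:
    """Binary graph from hard-thresholding |w| > r, with frozen degrees."""

    adjacency: np.ndarray
    degree: np.ndarray = field(init=False)

    def __post_init__(self):
        A = np.asarray(self.adjacency)
        if not np.array_equal(A, A.T):
            raise ValidationError("adjacency must be symmetric")
        self.adjacency = A.astype(np.int8)
        np.fill_diagonal(self.adjacency, 0)
        self.degree = self.adjacency.sum(axis=1).astype(int)


def correlation_network(
    expr: ExpressionMatrix,
    r: float = 0.3,
    mass: np.ndarray = None,
    correlation_mode: str = "absolute",
) -> WeightedNetwork:
    """Build the PCC co-expression network from an expression matrix.

    Parameters
    ----------
    expr : ExpressionMatrix
        Genes x samples; >= 3 samples, no zero-variance gene.
    r : float
        Hard-threshold cutoff carried on the network.
    mass : ndarray, optional
        Node masses (defaults to all ones, i.e. TPSC-1).
    correlation_mode : {"absolute", "positive-only"}
        ``"absolute"`` keeps signed PCCs (downstream uses |w|);
        ``"positive-only"`` zeroes negative PCCs.
    """
    if expr.n_samples < 3:
        raise ValidationError("need >= 3 samples to estimate correlations")
    if correlation_mode not in ("absolute", "positive-only"):
        raise ValidationError(f"unknown correlation_mode {correlation_mode!r}")
    sd = expr.values.std(axis=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = [expr.gene_ids[i] for i in dead[:5]]
        raise ValidationError(f"zero-variance genes (correlation undefined): {names}")
    W = np.corrcoef(expr.values)
    W = np.clip(W, -1.0, 1.0)
    if correlation_mode == "positive-only":
        W[W < 0] = 0.0
    np.fill_diagonal(W, 0.0)
    return WeightedNetwork(list(expr.gene_ids), W, mass=mass, r=r)


def distance_from_weights(net: WeightedNetwork) -> np.ndarray:
    """Distance matrix d_ij = 1 / |w_ij|, with d_ii = 0.

    A zero weight maps to an infinite distance, which contributes
    exactly zero potential energy downstream.
    """
    with np.errstate(divide="ignore"):
        D = 1.0 / np.abs(net.W)
    np.fill_diagonal(D, 0.0)
    return D


def threshold_graph(net: WeightedNetwork) -> ThresholdedGraph:
    """Hard-threshold the network: edge iff |w_ij| > r (strict)."""
    A = (np.abs(net.W) > net.r).astype(np.int8)
    np.fill_diagonal(A, 0)
    return ThresholdedGraph(A)
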