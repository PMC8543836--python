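"""Cluster-count selection by greedy local-maximum search.

A fully connected weighted network has a single global potential
maximum, so local maxima are sought on the hard-thresholded binary
graph instead.  The greedy loop repeatedly takes the highest-energy
remaining node; if that node's degree in the thresholded graph is below
d_min the search terminates, otherwise the node becomes a center and it
plus its first-order neighbors leave the candidate pool.  The number of
centers is the cluster count k, and the centers seed the spectral
k-means stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import NoCentersError, ValidationError
from .network import ThresholdedGraph

__all__ = ["LocalMaximaResult", "find_local_maxima", "k_vs_dmin_profile"]


@dataclass
class LocalMaximaResult:
    """Centers chosen by the greedy search, in selection order."""

    centers: list
    d_min: int

    @property
    def k(self) -> int:
        return len(self.centers)


def find_local_maxima(
    graph: ThresholdedGraph,
    score: np.ndarray,
    d_min: int = 5,
    skip_low_degree: bool = False,
    dynamic_degree: bool = False,
) -> LocalMaximaResult:
    """Greedy selection of local-maximum nodes.

    Parameters
    ----------
    graph : ThresholdedGraph
        Binary graph whose (frozen) degrees gate candidate centers.
    score : ndarray
        Per-node ranking score — the total potential energy ESigma.
        Ties broken by smallest node index.
    d_min : int
        Minimum degree a center must have.  A top-scoring candidate
        below d_min terminates the whole search (default) or is merely
        skipped when ``skip_low_degree`` is set.
    dynamic_degree : bool
        Recompute degrees on the shrinking candidate subgraph instead
        of using the frozen full-graph degrees.  Off by default: frozen
        degrees make k(d_min) monotonically non-increasing.

    Raises
    ------
    NoCentersError
        If no node qualifies as a center.
    """
    score = np.asarray(score, dtype=float)
    A = graph.adjacency
    n = A.shape[0]
    if score.shape != (n,):
        raise ValidationError("score length must equal node count")
    if not np.isfinite(score).all():
        raise ValidationError("scores must be finite")
    if d_min < 0:
        raise ValidationError("d_min must be nonnegative")

    alive = np.ones(n, dtype=bool)
    centers: list = []
    # argsort on (-score, index): stable ascending sort of -score breaks
    # ties by smallest index
    order = np.argsort(-score, kind="stable")
    for _ in range(n):
        if not alive.any():
            break
        candidates = order[alive[order]]
        top = int(candidates[0])
        if dynamic_degree:
            deg = int(A[top, alive].sum())
        else:
            deg = int(graph.degree[top])
        if deg < d_min:
            if skip_low_degree:
                alive[top] = False
                continue
            break
        centers.append(top)
        alive[top] = False
        alive[A[top] == 1] = False

    if not centers:
        raise NoCentersError(
            f"no node reaches degree {d_min} in the thresholded graph; "
            "decrease d_min or the weight cutoff r"
        )
    return LocalMaximaResult(centers=centers, d_min=int(d_min))


def k_vs_dmin_profile(graph: ThresholdedGraph, score, d_min_values) -> list:
    """Cluster count k for each d_min in ``d_min_values`` (ascending).

    With frozen degrees k is non-increasing in d_min.  A d_min that
    yields no centers reports k = 0 instead of raising.
    """
    d_min_values = list(d_min_values)
    if d_min_values != sorted(d_min_values):
        raise ValidationError("d_min_values must be sorted ascending")
    profile = []
    for d in d_min_values:
        try:
            k = find_local_maxima(graph, score, d_min=d).k
        except NoCentersError:
            k = 0
        profile.append((int(d), k))
    return profile
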