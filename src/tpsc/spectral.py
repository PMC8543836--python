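"""Spectral partitioning on the corrected Laplacian, and the end-to-end
TPSC pipeline.

The spectral stage is the standard symmetric-normalized-Laplacian
pipeline: take the eigenvectors of the k smallest eigenvalues, normalize
the embedding rows to unit length, and run k-means — with the k-means
centroids initialized at the embedding rows of the local-maximum nodes,
which makes the assignment deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from sklearn.cluster import KMeans

from .cluster_count import find_local_maxima
from .exceptions import TPSCError, ValidationError
from .io import ExpressionMatrix
from .network import (
    WeightedNetwork,
    correlation_network,
    distance_from_weights,
    threshold_graph,
)
from .potential import build_field, corrected_laplacian, sigma_from_threshold

logger = logging.getLogger(__name__)

__all__ = ["SpectralEmbedding", "ModulePartition", "TPSCResult", "embed",
           "assign_modules", "tpsc"]

_EIG_CLAMP = 1e-8  # eigenvalues within this of [0, 2] are clamped into range


@dataclass
class SpectralEmbedding:
    """Rows of U embed the n nodes in R^k (smallest-k eigenvectors of L)."""

    U: np.ndarray
    eigenvalues: np.ndarray
    row_normalized: bool


@dataclass
class ModulePartition:
    """Complete assignment of every node to exactly one module.

    Modules are numbered 1..k in decreasing size order, ties broken by
    the lexicographically smallest member node id; module i is named
    ``"M<i>"``.
    """

    node_ids: list
    labels: np.ndarray
    k: int
    centers: list = field(default=None)

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != (len(self.node_ids),):
            raise ValidationError("one label per node required")
        present = set(np.unique(self.labels))
        if present != set(range(1, self.k + 1)):
            raise ValidationError(
                f"labels must cover 1..{self.k} with no empty module"
            )

    def members(self, label: int) -> list:
        return [g for g, l in zip(self.node_ids, self.labels) if l == label]

    def module_sizes(self) -> dict:
        return {f"M{l}": int((self.labels == l).sum()) for l in range(1, self.k + 1)}

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"gene_id": self.node_ids,
             "module_label": [f"M{l}" for l in self.labels]}
        )


def _rename_by_size(node_ids, raw_labels, centers=None) -> ModulePartition:
    """Canonical module numbering: size-descending, ties by smallest id."""
    raw_labels = np.asarray(raw_labels)
    uniq = np.unique(raw_labels)
    keys = []
    for lab in uniq:
        members = [node_ids[i] for i in np.flatnonzero(raw_labels == lab)]
        keys.append((-len(members), min(members), lab))
    mapping = {lab: rank + 1 for rank, (_, _, lab) in enumerate(sorted(keys))}
    labels = np.array([mapping[l] for l in raw_labels])
    return ModulePartition(list(node_ids), labels, k=len(uniq), centers=centers)


def embed(L: np.ndarray, k: int, row_normalize: bool = True) -> SpectralEmbedding:
    """Eigenvectors of the k algebraically smallest eigenvalues of L."""
    L = np.asarray(L, dtype=float)
    n = L.shape[0]
    if not 1 <= k <= n:
        raise ValidationError(f"k must be in [1, {n}], got {k}")
    vals, vecs = scipy.linalg.eigh(L, subset_by_index=[0, k - 1])
    if vals[0] < -_EIG_CLAMP or vals[-1] > 2 + _EIG_CLAMP:
        raise TPSCError(
            f"Laplacian spectrum outside [0, 2]: [{vals[0]:.3g}, {vals[-1]:.3g}]"
        )
    vals = np.clip(vals, 0.0, 2.0)
    U = vecs
    if row_normalize:
        norms = np.linalg.norm(U, axis=1, keepdims=True)
        nz = norms[:, 0] > 0
        U = U.copy()
        U[nz] /= norms[nz]
    return SpectralEmbedding(U=U, eigenvalues=vals, row_normalized=row_normalize)


def assign_modules(
    emb: SpectralEmbedding,
    k: int,
    node_ids,
    seed: int = 0,
    centers=None,
) -> ModulePartition:
    """k-means on the embedding rows.

    With ``centers`` (indices of local-maximum nodes) the centroids are
    initialized at those embedding rows and a single deterministic run
    is performed; otherwise k-means++ with 10 restarts at fixed seed.
    """
    X = emb.U
    if len(np.unique(X, axis=0)) < k:
        raise ValidationError(
            f"only {len(np.unique(X, axis=0))} distinct embedding rows; "
            f"cannot form {k} modules — reduce k"
        )
    if centers is not None:
        if len(centers) != k:
            raise ValidationError("number of centers must equal k")
        km = KMeans(n_clusters=k, init=X[list(centers)], n_init=1,
                    random_state=seed)
    else:
        km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
    raw = km.fit_predict(X)
    if len(np.unique(raw)) < k:  # pragma: no cover - kmeans reassigns internally
        raise TPSCError("k-means produced an empty module")
    return _rename_by_size(list(node_ids), raw, centers=list(centers) if centers is not None else None)


@dataclass
class TPSCResult:
    """Everything the end-to-end run produced."""

    partition: ModulePartition
    k: int
    centers: list
    sigma: float
    r: float
    d_min: int
    variant: str
    eigenvalues: np.ndarray = None


def tpsc(
    expr: ExpressionMatrix = None,
    network: WeightedNetwork = None,
    node_masses=None,
    r: float = 0.3,
    d_min: int = 5,
    seed: int = 0,
    sigma: float = None,
    correlation_mode: str = "absolute",
    row_normalize: bool = True,
    skip_low_degree: bool = False,
    dynamic_degree: bool = False,
) -> TPSCResult:
    """Run the full TPSC pipeline.

    Stages: correlation network (unless ``network`` is given) ->
    inverse-|PCC| distances -> sigma from r -> potential field ->
    corrected Laplacian -> greedy local maxima (fixes k and the seeds)
    -> spectral embedding -> seeded k-means.

    ``node_masses`` may be a dict (node id -> mass) or a vector aligned
    to the nodes; omitted masses run the unit-mass TPSC-1 variant,
    otherwise TPSC-w.
    """
    if (expr is None) == (network is None):
        raise ValidationError("provide exactly one of expr or network")

    def _stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except TPSCError as exc:
            raise type(exc)(f"[stage {name}] {exc}") from exc

    if network is None:
        node_ids = list(expr.gene_ids)
    else:
        node_ids = list(network.node_ids)

    mass = None
    if node_masses is not None:
        if isinstance(node_masses, dict):
            missing = [g for g in node_ids if g not in node_masses]
            if missing:
                raise ValidationError(
                    f"node_masses missing for {len(missing)} nodes, e.g. {missing[:3]}"
                )
            mass = np.array([float(node_masses[g]) for g in node_ids])
        else:
            mass = np.asarray(node_masses, dtype=float)
    variant = "tpsc1" if node_masses is None else "tpscw"

    if network is None:
        net = _stage("network", correlation_network, expr, r=r, mass=mass,
                     correlation_mode=correlation_mode)
    else:
        net = network
        if mass is not None:
            net = WeightedNetwork(node_ids, net.W, mass=mass, r=r)

    D = _stage("distance", distance_from_weights, net)
    if sigma is None:
        sigma = sigma_from_threshold(net.r)
    elif abs(sigma - sigma_from_threshold(net.r)) > 1e-9:
        logger.warning(
            "sigma=%.4g differs from sqrt(2)/(3r)=%.4g; cluster-count "
            "determination and module detection may be inconsistent",
            sigma, sigma_from_threshold(net.r),
        )
    fld = _stage("potential", build_field, net, D, sigma)
    L = _stage("laplacian", corrected_laplacian, fld)
    graph = _stage("threshold", threshold_graph, net)
    maxima = _stage(
        "cluster-count", find_local_maxima, graph, fld.ESigma, d_min,
        skip_low_degree=skip_low_degree, dynamic_degree=dynamic_degree,
    )
    k = maxima.k
    logger.info("selected k=%d module centers (d_min=%d)", k, d_min)
    emb = _stage("embedding", embed, L, k, row_normalize=row_normalize)
    part = _stage("assignment", assign_modules, emb, k, node_ids,
                  seed=seed, centers=maxima.centers)
    return TPSCResult(
        partition=part, k=k, centers=maxima.centers, sigma=float(sigma),
        r=float(net.r), d_min=int(d_min), variant=variant,
        eigenvalues=emb.eigenvalues,
    )
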