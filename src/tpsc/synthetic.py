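"""Synthetic planted-module fixtures with known ground truth.

Expression matrices follow a latent-factor block design: each block b
has a factor f_b over samples, and gene g in block b is

    x_g = sqrt(within_cor) * f_b + sqrt(1 - within_cor) * eps_g
          + noise_sd * eta_g

with independent standard-normal eps and eta.  Block factors share a
common component so that corr(f_a, f_b) = between_cor for a != b; with
noise_sd = 0 the population gene-gene correlation is exactly within_cor
inside a block and within_cor * between_cor across blocks.  Networks
can also be emitted directly (exact block weights, no sampling) for
hand-traceable tests, and exponential survival data with a group
hazard ratio supports the survival-analysis stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .io import ExpressionMatrix
from .network import WeightedNetwork

__all__ = [
    "PlantedDesign",
    "make_planted_expression",
    "make_planted_network",
    "make_survival",
]


@dataclass
class PlantedDesign:
    """Parameters of a planted-module fixture.

    within_cor is the population gene-gene correlation inside a block
    (the study default 0.81 corresponds to a factor loading of 0.9);
    between_cor is the correlation between block factors.
    """

    block_sizes: list
    within_cor: float = 0.81
    between_cor: float = 0.0
    n_samples: int = 200
    noise_sd: float = 0.0
    mass_profile: list = field(default=None)
    seed: int = 0

    def __post_init__(self):
        if any(b < 2 for b in self.block_sizes):
            raise ValidationError("block sizes must be >= 2")
        if self.n_samples < 3:
            raise ValidationError("need >= 3 samples")
        if not 0 <= self.within_cor <= 1:
            raise ValidationError("within_cor must be in [0, 1]")
        if not 0 <= self.between_cor <= self.within_cor or (
            self.between_cor == self.within_cor and self.within_cor > 0
        ):
            raise ValidationError("need 0 <= between_cor < within_cor")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be nonnegative")
        if self.mass_profile is not None:
            if len(self.mass_profile) != len(self.block_sizes):
                raise ValidationError("one mass level per block required")
            if any(not 0 < m <= 1 for m in self.mass_profile):
                raise ValidationError("mass levels must be in (0, 1]")

    @property
    def n_genes(self) -> int:
        return sum(self.block_sizes)


def _labels_and_masses(design: PlantedDesign):
    labels = np.repeat(np.arange(len(design.block_sizes)), design.block_sizes)
    if design.mass_profile is None:
        masses = np.ones(design.n_genes)
    else:
        masses = np.repeat(np.asarray(design.mass_profile, float),
                           design.block_sizes)
    return labels, masses


def make_planted_expression(design: PlantedDesign):
    """Sample an expression matrix from the planted design.

    Returns ``(ExpressionMatrix, true_labels, true_masses)``; gene ids
    are g0001, g0002, ... and sample ids s001, s002, ...  Deterministic
    given ``design.seed``.
    """
    rng = np.random.default_rng(design.seed)
    n_blocks = len(design.block_sizes)
    ns = design.n_samples
    shared = rng.standard_normal(ns)
    factors = np.empty((n_blocks, ns))
    b = design.between_cor
    for i in range(n_blocks):
        factors[i] = np.sqrt(b) * shared + np.sqrt(1 - b) * rng.standard_normal(ns)

    labels, masses = _labels_and_masses(design)
    w = design.within_cor
    X = np.empty((design.n_genes, ns))
    for g, blk in enumerate(labels):
        eps = rng.standard_normal(ns)
        X[g] = np.sqrt(w) * factors[blk] + np.sqrt(1 - w) * eps
        if design.noise_sd > 0:
            X[g] += design.noise_sd * rng.standard_normal(ns)

    gene_ids = [f"g{i + 1:04d}" for i in range(design.n_genes)]
    sample_ids = [f"s{j + 1:03d}" for j in range(ns)]
    expr = ExpressionMatrix(gene_ids, sample_ids, X)
    return expr, labels, masses


def make_planted_network(design: PlantedDesign, r: float = 0.3):
    """Emit the exact block weight matrix (no sampling).

    Within-block weights equal ``within_cor``, between-block weights
    equal ``between_cor``; masses follow ``mass_profile``.  Useful for
    hand-traceable tests of the potential, cluster-count and spectral
    stages.  Returns ``(WeightedNetwork, true_labels)``.
    """
    labels, masses = _labels_and_masses(design)
    same = labels[:, None] == labels[None, :]
    W = np.where(same, design.within_cor, design.between_cor).astype(float)
    np.fill_diagonal(W, 0.0)
    node_ids = [f"g{i + 1:04d}" for i in range(design.n_genes)]
    return WeightedNetwork(node_ids, W, mass=masses, r=r), labels


def make_survival(
    groups: dict,
    hazard_ratio: float = 1.0,
    baseline_hazard: float = 1.0,
    censoring_rate: float = 0.2,
    seed: int = 0,
) -> pd.DataFrame:
    """Exponential survival data with a between-group hazard ratio.

    ``groups`` maps sample id -> 0/1; group 1 has hazard
    ``baseline_hazard * hazard_ratio``.  Censoring is an independent
    exponential clock with rate ``censoring_rate`` (0 disables it).
    Returns a survival DataFrame indexed by sample id with columns
    ``time`` and ``event``.
    """
    if hazard_ratio <= 0 or baseline_hazard <= 0:
        raise ValidationError("hazards must be strictly positive")
    if censoring_rate < 0:
        raise ValidationError("censoring_rate must be nonnegative")
    rng = np.random.default_rng(seed)
    ids = list(groups)
    g = np.array([int(groups[s]) for s in ids])
    if not np.isin(g, [0, 1]).all():
        raise ValidationError("group labels must be 0 or 1")
    rate = baseline_hazard * np.where(g == 1, hazard_ratio, 1.0)
    t_event = rng.exponential(1.0 / rate)
    if censoring_rate > 0:
        t_cens = rng.exponential(1.0 / censoring_rate, size=len(ids))
    else:
        t_cens = np.full(len(ids), np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return pd.DataFrame({"time": time, "event": event}, index=pd.Index(ids))
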