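"""Topology potential field and the energy-corrected normalized Laplacian.

Every node carries a mass m_i > 0 and exerts a Gaussian-decaying field on
the others.  The pairwise *topology potential energy*

    e_p(i, j) = m_i * m_j * exp(-(d_ij / sigma)^2),    e_p(i, i) = 0

is symmetric in i and j even when masses differ — unlike the one-sided
potential component m_i * exp(-(d_ij/sigma)^2) — so the normalized
Laplacian built from it stays symmetric.  With E_p the pairwise energy
matrix and E_sigma = diag(row sums of E_p), the corrected Laplacian is

    L = I - E_sigma^{-1/2} E_p E_sigma^{-1/2}.

The impact factor sigma is tied to the weight cutoff r by requiring the
inverse of the influence range 3*sigma/sqrt(2) to equal r.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import IsolatedNodeError, ValidationError
from .network import WeightedNetwork

__all__ = [
    "PotentialField",
    "sigma_from_threshold",
    "potential_energy",
    "build_field",
    "corrected_laplacian",
]

# below this total energy a node is numerically isolated and cannot be
# normalized without producing infinities
_ENERGY_FLOOR = 1e-300


@dataclass
class PotentialField:
    """Pairwise potential energies and per-node totals for one network.

    Attributes
    ----------
    sigma : float
        Gaussian impact factor (distance units).
    Ep : ndarray (n, n)
        Symmetric pairwise energies, zero diagonal.
    ESigma : ndarray (n,)
        Row sums of ``Ep`` — the total energy of each node, the
        quantity the Laplacian normalizes by and the score used to rank
        candidate module centers.
    phi : ndarray (n,)
        Classical topology potential of each node,
        phi_i = m_i * sum_{j != i} exp(-(d_ij/sigma)^2).  Kept for
        diagnostics; the pipeline ranks nodes by ``ESigma``.
    """

    sigma: float
    Ep: np.ndarray
    ESigma: np.ndarray
    phi: np.ndarray


def sigma_from_threshold(r: float) -> float:
    """Impact factor sigma such that the inverse influence range equals r.

    The field's influence range is 3*sigma/sqrt(2); setting its inverse
    equal to the weight cutoff r gives sigma = sqrt(2) / (3 r).  For the
    conventional co-expression cutoff r = 0.3 this is ~1.57.
    """
    if r <= 0:
        raise ValidationError(f"weight cutoff must be positive, got {r}")
    return np.sqrt(2.0) / (3.0 * r)


def potential_energy(m_i: float, m_j: float, d_ij: float, sigma: float) -> float:
    """Pairwise topology potential energy m_i*m_j*exp(-(d_ij/sigma)^2).

    Infinite distance returns exactly 0.  The i == j case is the
    caller's responsibility (the field builder zeroes the diagonal).
    """
    if m_i <= 0 or m_j <= 0:
        raise ValidationError("masses must be strictly positive")
    if sigma <= 0:
        raise ValidationError("sigma must be strictly positive")
    if d_ij < 0:
        raise ValidationError("distance must be nonnegative")
    if np.isinf(d_ij):
        return 0.0
    return float(m_i * m_j * np.exp(-((d_ij / sigma) ** 2)))


def _gaussian_kernel(D: np.ndarray, sigma: float) -> np.ndarray:
    """exp(-(d/sigma)^2) with infinite distances mapped exactly to 0."""
    K = np.zeros_like(D)
    finite = np.isfinite(D)
    K[finite] = np.exp(-((D[finite] / sigma) ** 2))
    np.fill_diagonal(K, 0.0)
    return K


def build_field(net: WeightedNetwork, D: np.ndarray, sigma: float) -> PotentialField:
    """Evaluate the potential field of a network at impact factor sigma."""
    if sigma <= 0:
        raise ValidationError("sigma must be strictly positive")
    D = np.asarray(D, dtype=float)
    n = net.n_nodes
    if D.shape != (n, n):
        raise ValidationError("distance matrix shape mismatch")
    K = _gaussian_kernel(D, sigma)
    m = net.mass
    Ep = np.outer(m, m) * K
    ESigma = Ep.sum(axis=1)
    isolated = np.flatnonzero(ESigma < _ENERGY_FLOOR)
    if isolated.size:
        names = [net.node_ids[i] for i in isolated[:5]]
        raise IsolatedNodeError(
            f"nodes with zero total potential energy: {names}; "
            "they cannot be normalized — remove them or lower r"
        )
    phi = m * K.sum(axis=1)
    return PotentialField(sigma=float(sigma), Ep=Ep, ESigma=ESigma, phi=phi)


def corrected_laplacian(field: PotentialField) -> np.ndarray:
    """Symmetric normalized Laplacian corrected by potential energies.

    L = I - E_sigma^{-1/2} E_p E_sigma^{-1/2}.  Because ESigma is
    exactly the row sum of the symmetric Ep, L has unit diagonal,
    eigenvalues in [0, 2], and sqrt(ESigma) in its null space; a global
    rescaling of all masses cancels and leaves L unchanged.
    """
    s = 1.0 / np.sqrt(field.ESigma)
    L = -(s[:, None] * field.Ep * s[None, :])
    np.fill_diagonal(L, 1.0)
    return (L + L.T) / 2.0
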