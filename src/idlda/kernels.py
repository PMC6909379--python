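"""Interaction-profile kernels, lncRNA functional similarity, and ensembles.

The Gaussian interaction-profile kernel compares two entities by their binary
association vectors ("interaction profiles"): diseases by rows of the
adjacency A, lncRNAs by columns.  The bandwidth gamma is a nominal bandwidth
gamma' (default 1) divided by the mean squared profile norm, so it adapts to
the density of the network:

    gamma = gamma' / mean_i ||IP_i||^2
    K_ij  = exp(-gamma * ||IP_i - IP_j||^2)

lncRNA functional similarity FS scores two lncRNAs by best-match semantic
similarity between their associated disease sets D(l_i), D(l_j):

    FS_ij = [ sum_{t in D(l_i)} max_{d in D(l_j)} SS(t, d)
            + sum_{t in D(l_j)} max_{d in D(l_i)} SS(t, d) ]
            / (|D(l_i)| + |D(l_j)|)

The ensemble similarities average the semantic/functional channel with the
kernel wherever the former is nonzero, and fall back to the kernel alone
where it is zero (no MeSH coverage, empty disease sets):

    DS = (SS + KD) / 2 where SS != 0, else KD
    LS = (FS + KL) / 2 where FS != 0, else KL
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import AssociationNetwork, MeshForest
from .semantic import DEFAULT_DELTA, semantic_similarity_matrix

__all__ = [
    "gaussian_kernel",
    "functional_similarity",
    "ensemble",
    "EnsembleSimilarity",
    "compute_similarities",
]


def gaussian_kernel(profiles: np.ndarray, gamma_prime: float = 1.0) -> np.ndarray:
    """Gaussian interaction-profile kernel over the rows of ``profiles``.

    Raises if every profile is all-zero (the bandwidth is then undefined).
    """
    if gamma_prime <= 0:
        raise ValueError(f"gamma_prime must be positive, got {gamma_prime}")
    X = np.asarray(profiles, dtype=float)
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValueError("profiles must be a non-empty 2-D matrix")
    sq_norms = (X * X).sum(axis=1)
    mean_sq = sq_norms.mean()
    if mean_sq == 0.0:
        raise ValueError("bandwidth undefined: all interaction profiles are zero")
    gamma = gamma_prime / mean_sq
    # ||x - y||^2 = ||x||^2 + ||y||^2 - 2 x.y, clipped against rounding
    sq_dist = sq_norms[:, None] + sq_norms[None, :] - 2.0 * (X @ X.T)
    np.clip(sq_dist, 0.0, None, out=sq_dist)
    K = np.exp(-gamma * sq_dist)
    K = (K + K.T) / 2.0
    np.fill_diagonal(K, 1.0)
    return K


def functional_similarity(A: np.ndarray, SS: np.ndarray) -> np.ndarray:
    """lncRNA-lncRNA functional similarity from best-match disease semantics.

    ``A`` is the diseases x lncRNAs adjacency, ``SS`` the disease semantic
    similarity matrix.  Pairs where either lncRNA has an empty disease set
    score 0 (the ensemble then falls back to the kernel).
    """
    A = np.asarray(A, dtype=float)
    SS = np.asarray(SS, dtype=float)
    n_d, n_l = A.shape
    if SS.shape != (n_d, n_d):
        raise ValueError(f"SS shape {SS.shape} does not match {n_d} diseases")
    deg = A.sum(axis=0)
    # M[t, j] = best SS between disease t and lncRNA j's disease set
    M = np.zeros((n_d, n_l))
    for j in range(n_l):
        members = A[:, j] > 0
        if members.any():
            M[:, j] = SS[:, members].max(axis=1)
    # cross[i, j] = sum over t in D(l_i) of M[t, j]
    cross = A.T @ M
    denom = deg[:, None] + deg[None, :]
    FS = np.zeros((n_l, n_l))
    np.divide(cross + cross.T, denom, out=FS, where=denom > 0)
    FS[deg == 0, :] = 0.0
    FS[:, deg == 0] = 0.0
    return FS


def ensemble(primary: np.ndarray, fallback: np.ndarray) -> np.ndarray:
    """Average primary and fallback where primary is nonzero, else fallback."""
    primary = np.asarray(primary, dtype=float)
    fallback = np.asarray(fallback, dtype=float)
    if primary.shape != fallback.shape:
        raise ValueError(f"shape mismatch: {primary.shape} vs {fallback.shape}")
    return np.where(primary != 0.0, (primary + fallback) / 2.0, fallback)


@dataclass
class EnsembleSimilarity:
    """All similarity channels computed from one training adjacency."""

    disease_names: list[str]
    lncrna_names: list[str]
    SS: np.ndarray
    KD: np.ndarray
    KL: np.ndarray
    FS: np.ndarray
    DS: np.ndarray = field(init=False)
    LS: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.DS = ensemble(self.SS, self.KD)
        self.LS = ensemble(self.FS, self.KL)

    def frame(self, which: str) -> pd.DataFrame:
        m = getattr(self, which)
        labels = self.disease_names if m.shape[0] == len(self.disease_names) else self.lncrna_names
        return pd.DataFrame(m, index=labels, columns=labels)


def compute_similarities(
    net: AssociationNetwork,
    forest: MeshForest | None = None,
    *,
    delta: float = DEFAULT_DELTA,
    gamma_d: float = 1.0,
    gamma_l: float = 1.0,
    SS: np.ndarray | None = None,
    A: np.ndarray | None = None,
) -> EnsembleSimilarity:
    """Compute SS, KD, KL, FS (and hence DS, LS) for one training adjacency.

    ``A`` overrides the network's adjacency (used by cross-validation, which
    re-derives every similarity from the masked training matrix) and ``SS``
    short-circuits the semantic matrix, which depends only on the MeSH forest
    and can be shared across folds.
    """
    if A is None:
        A = net.A
    if SS is None:
        if forest is None:
            SS = np.zeros((net.n_diseases, net.n_diseases))
        else:
            SS = semantic_similarity_matrix(net.disease_names, forest, delta).to_numpy()
    KD = gaussian_kernel(A, gamma_d)
    KL = gaussian_kernel(A.T, gamma_l)
    FS = functional_similarity(A, SS)
    return EnsembleSimilarity(net.disease_names, net.lncrna_names, SS, KD, KL, FS)
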