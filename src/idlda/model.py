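"""The IDLDA scoring model: ensemble associations and two-pass diffusion.

The ensemble similarities smooth the raw adjacency into two "ensemble
association" matrices,

    DA = DS @ A        (disease-side smoothing)
    LA = A  @ LS       (lncRNA-side smoothing)

and candidate scores for a seed disease u are obtained by a two-pass
resource-allocation diffusion across the bipartite graph.  Pass one moves
each lncRNA i's seed resource (LA_ui, resp. DA_ui) to diseases j in
proportion to column i of that matrix; pass two returns disease j's received
resource to lncRNAs in proportion to row j:

    g(j|u)     = alpha * sum_i LA_ji / (sum_j' LA_j'i) * LA_ui
               + (1-alpha) * sum_i DA_ji / (sum_j' DA_j'i) * DA_ui
    score(i|u) = beta * sum_j LA_ji / (sum_i' LA_ji') * g(j|u)
               + (1-beta) * sum_j DA_ji / (sum_i' DA_ji') * g(j|u)

alpha and beta weight the lncRNA-side against the disease-side channel in
each pass.  A zero column or row sum transmits no resource (its term is 0),
which keeps scores finite on degenerate networks.  Because the seed
resources come from DA/LA rather than the raw adjacency, a disease with no
known associations still seeds the diffusion through its semantic
similarity to covered diseases, so brand-new diseases receive predictions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import AssociationNetwork, MeshForest, read_associations, read_mesh_forest
from .kernels import EnsembleSimilarity, compute_similarities
from .semantic import DEFAULT_DELTA

__all__ = [
    "DiffusionParams",
    "ensemble_associations",
    "score_disease",
    "score_all",
    "IDLDA",
    "IDLDAResults",
]

DEFAULT_ALPHA = 0.3
DEFAULT_BETA = 0.5


@dataclass(frozen=True)
class DiffusionParams:
    """Mixing weights of the two diffusion passes, both in [0, 1]."""

    alpha: float = DEFAULT_ALPHA
    beta: float = DEFAULT_BETA

    def __post_init__(self) -> None:
        for name in ("alpha", "beta"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


def ensemble_associations(A: np.ndarray, DS: np.ndarray, LS: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Similarity-smoothed association matrices ``DA = DS @ A``, ``LA = A @ LS``."""
    A = np.asarray(A, dtype=float)
    DS = np.asarray(DS, dtype=float)
    LS = np.asarray(LS, dtype=float)
    n_d, n_l = A.shape
    if DS.shape != (n_d, n_d) or LS.shape != (n_l, n_l):
        raise ValueError(
            f"dimension mismatch: A is {A.shape}, DS is {DS.shape}, LS is {LS.shape}"
        )
    return DS @ A, A @ LS


def _column_shares(M: np.ndarray) -> np.ndarray:
    """M normalized so each column sums to 1; all-zero columns stay zero."""
    sums = M.sum(axis=0)
    out = np.zeros_like(M)
    np.divide(M, sums[None, :], out=out, where=sums[None, :] > 0)
    return out


def _row_shares(M: np.ndarray) -> np.ndarray:
    """M normalized so each row sums to 1; all-zero rows stay zero."""
    sums = M.sum(axis=1)
    out = np.zeros_like(M)
    np.divide(M, sums[:, None], out=out, where=sums[:, None] > 0)
    return out


def diffuse(DA: np.ndarray, LA: np.ndarray, params: DiffusionParams, seeds: np.ndarray | None = None) -> np.ndarray:
    """Two-pass diffusion for a block of seed-resource rows.

    ``seeds`` selects disease indices (default: all); returns the matrix of
    scores with one row per seed and one column per lncRNA.
    """
    a, b = params.alpha, params.beta
    WL_col, WD_col = _column_shares(LA), _column_shares(DA)
    WL_row, WD_row = _row_shares(LA), _row_shares(DA)
    LA_u = LA if seeds is None else LA[seeds]
    DA_u = DA if seeds is None else DA[seeds]
    # G[u, j] = resources arriving at disease j from seed u after pass one
    G = a * (LA_u @ WL_col.T) + (1.0 - a) * (DA_u @ WD_col.T)
    return b * (G @ WL_row) + (1.0 - b) * (G @ WD_row)


def score_disease(
    u: int,
    DA: np.ndarray,
    LA: np.ndarray,
    params: DiffusionParams = DiffusionParams(),
) -> np.ndarray:
    """Diffusion scores of every lncRNA for seed disease index ``u``."""
    n_d = DA.shape[0]
    if not 0 <= u < n_d:
        raise IndexError(f"disease index {u} out of range for {n_d} diseases")
    return diffuse(DA, LA, params, seeds=np.array([u]))[0]


def score_all(DA: np.ndarray, LA: np.ndarray, params: DiffusionParams = DiffusionParams()) -> np.ndarray:
    """Full relevance matrix R: row u holds ``score_disease(u)``."""
    return diffuse(DA, LA, params)


class IDLDA:
    """Similarity-ensemble diffusion model on a disease-lncRNA network.

    Parameters
    ----------
    network : AssociationNetwork
        Binary disease x lncRNA adjacency with labels.
    forest : MeshForest, optional
        Disease -> MeSH tree-number mapping.  Omitting it disables the
        semantic channel; every similarity then reduces to the Gaussian
        interaction-profile kernel.
    delta : float
        Semantic decay factor in [0, 1), default 0.5.
    gamma_d, gamma_l : float
        Nominal kernel bandwidths for the disease and lncRNA kernels.

    ``fit(alpha, beta)`` computes the similarity stack, the ensemble
    associations and the score matrix, returning :class:`IDLDAResults`.
    """

    def __init__(
        self,
        network: AssociationNetwork,
        forest: MeshForest | None = None,
        *,
        delta: float = DEFAULT_DELTA,
        gamma_d: float = 1.0,
        gamma_l: float = 1.0,
    ) -> None:
        self.network = network
        self.forest = forest
        self.delta = delta
        self.gamma_d = gamma_d
        self.gamma_l = gamma_l

    @classmethod
    def from_tables(
        cls,
        associations: str | Path,
        mesh: str | Path | None = None,
        **kwargs,
    ) -> "IDLDA":
        """Build a model straight from an association TSV and a MeSH TSV."""
        net = read_associations(associations)
        forest = read_mesh_forest(mesh) if mesh is not None else None
        return cls(net, forest, **kwargs)

    def similarities(self, A: np.ndarray | None = None, SS: np.ndarray | None = None) -> EnsembleSimilarity:
        return compute_similarities(
            self.network,
            self.forest,
            delta=self.delta,
            gamma_d=self.gamma_d,
            gamma_l=self.gamma_l,
            A=A,
            SS=SS,
        )

    def fit(self, alpha: float = DEFAULT_ALPHA, beta: float = DEFAULT_BETA) -> "IDLDAResults":
        params = DiffusionParams(alpha, beta)
        sims = self.similarities()
        DA, LA = ensemble_associations(self.network.A, sims.DS, sims.LS)
        R = score_all(DA, LA, params)
        return IDLDAResults(self, params, sims, DA, LA, R)


class IDLDAResults:
    """Fitted scores and rankings produced by :meth:`IDLDA.fit`."""

    def __init__(
        self,
        model: IDLDA,
        params: DiffusionParams,
        similarities: EnsembleSimilarity,
        DA: np.ndarray,
        LA: np.ndarray,
        R: np.ndarray,
    ) -> None:
        self.model = model
        self.params = params
        self.similarities = similarities
        self.DA = DA
        self.LA = LA
        self.R = R

    @property
    def scores(self) -> pd.DataFrame:
        net = self.model.network
        return pd.DataFrame(self.R, index=net.disease_names, columns=net.lncrna_names)

    def rank_candidates(self, disease: str, include_known: bool = False) -> pd.DataFrame:
        """Ranked lncRNAs for one disease, best first.

        Ranks are average ranks over the full score row (ties share their
        mean rank); by default only candidate pairs (no known association)
        are listed, in descending score with stable label order on ties.
        """
        net = self.model.network
        u = net.disease_index(disease)
        row = self.R[u]
        ranks = rankdata(-row, method="average")
        known = net.A[u] > 0
        frame = pd.DataFrame(
            {
                "disease": net.disease_names[u],
                "lncrna": net.lncrna_names,
                "score": row,
                "rank": ranks,
                "known": known.astype(int),
            }
        )
        if not include_known:
            frame = frame[~known]
        order = np.lexsort((np.arange(len(frame)), -frame["score"].to_numpy()))
        return frame.iloc[order].reset_index(drop=True)

    def predictions(self, include_known: bool = True) -> pd.DataFrame:
        """Long-form table of every (disease, lncRNA) pair with score and rank."""
        parts = [self.rank_candidates(d, include_known=include_known) for d in self.model.network.disease_names]
        return pd.concat(parts, ignore_index=True)

    def summary(self) -> str:
        net = self.model.network
        dens = net.n_associations / (net.n_diseases * net.n_lncrnas)
        covered = 0
        if self.model.forest is not None:
            covered = sum(1 for d in net.disease_names if d in self.model.forest)
        lines = [
            "IDLDA diffusion results",
            "=======================",
            f"diseases:            {net.n_diseases}",
            f"lncRNAs:             {net.n_lncrnas}",
            f"known associations:  {net.n_associations}",
            f"network density:     {dens:.4f}",
            f"MeSH-covered:        {covered}/{net.n_diseases} diseases",
            f"delta (decay):       {self.model.delta}",
            f"gamma'_d, gamma'_l:  {self.model.gamma_d}, {self.model.gamma_l}",
            f"alpha, beta:         {self.params.alpha}, {self.params.beta}",
            f"score range:         [{self.R.min():.4f}, {self.R.max():.4f}]",
        ]
        return "\n".join(lines)
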