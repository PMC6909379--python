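"""Cross-validation, ROC/AUROC and fold-enrichment analysis.

Three validation schemes are provided:

* ``loocv`` -- global leave-one-association-out: every known pair (u, v) is
  removed in turn, the entire similarity stack is recomputed from the masked
  training adjacency, and the held-out pair is scored against all unknown
  pairs in disease u's row.  Scores are pooled over folds into one ROC.
* ``cv_local`` -- leave rows (new diseases) or columns (new lncRNAs) out in
  K random folds; held-out entities keep no training associations, so their
  predictions rely entirely on semantic/kernel similarity to the training
  side.
* ``grid_search`` -- LOOCV AUROC over the (alpha, beta) grid
  {0, 0.1, ..., 1}^2.  The per-fold similarity matrices do not depend on
  alpha or beta, so each fold is reduced once to four vectors from which the
  score at any grid point is a bilinear combination.

AUROC is the tie-corrected probability that a random positive outscores a
random negative (Wilcoxon/Mann-Whitney form, ties get half credit).

Fold enrichment ranks all N = N_d * N_l pairs by score and reports, per bin
of x consecutive pairs, the density of verified associations relative to the
global density: (m / x) / (M / N).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
from scipy.stats import rankdata

from .io import AssociationNetwork, MeshForest
from .kernels import compute_similarities
from .model import DiffusionParams, ensemble_associations, score_all
from .semantic import DEFAULT_DELTA, semantic_similarity_matrix

__all__ = [
    "CVResult",
    "EnrichmentResult",
    "auroc",
    "roc_points",
    "loocv",
    "cv_local",
    "grid_search",
    "enrichment",
    "plot_roc",
]

GRID_VALUES = tuple(round(0.1 * k, 1) for k in range(11))


def auroc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Tie-corrected AUROC via the rank-sum statistic.

    Equals the fraction of (positive, negative) pairs where the positive
    outscores the negative, counting ties as half.
    """
    labels = np.asarray(labels, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have the same length")
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC needs both a positive and a negative example")
    ranks = rankdata(scores, method="average")
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_points(labels: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """ROC polyline (FPR, TPR), from (0, 0) to (1, 1), one vertex per threshold."""
    labels = np.asarray(labels, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    tp = np.cumsum(y)
    fp = np.cumsum(~y)
    # keep only the last index of each tied score block
    last = np.r_[s[1:] != s[:-1], True]
    tpr = np.r_[0.0, tp[last] / tp[-1]]
    fpr = np.r_[0.0, fp[last] / fp[-1]]
    return np.column_stack([fpr, tpr])


@dataclass
class CVResult:
    """Pooled cross-validation outcome for one scheme and parameter setting."""

    scheme: str
    labels: np.ndarray
    scores: np.ndarray
    params: DiffusionParams
    per_disease_auroc: dict[str, float] = field(default_factory=dict)

    @property
    def auroc(self) -> float:
        return auroc(self.labels, self.scores)

    @property
    def roc(self) -> np.ndarray:
        return roc_points(self.labels, self.scores)


def _fold_components(
    A_train: np.ndarray,
    u: int,
    net: AssociationNetwork,
    SS: np.ndarray,
    gamma_d: float,
    gamma_l: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Reduce one LOOCV fold to the four alpha/beta-independent score vectors.

    With g = alpha*gL + (1-alpha)*gD and the pass-two operators T_L, T_D
    linear in g, the seed row's score at any (alpha, beta) is
    beta*(alpha*a + (1-alpha)*b) + (1-beta)*(alpha*c + (1-alpha)*d).
    """
    sims = compute_similarities(net, None, SS=SS, A=A_train, gamma_d=gamma_d, gamma_l=gamma_l)
    DA, LA = ensemble_associations(A_train, sims.DS, sims.LS)

    def col_shares(M: np.ndarray) -> np.ndarray:
        sums = M.sum(axis=0)
        out = np.zeros_like(M)
        np.divide(M, sums[None, :], out=out, where=sums[None, :] > 0)
        return out

    def row_shares(M: np.ndarray) -> np.ndarray:
        sums = M.sum(axis=1)
        out = np.zeros_like(M)
        np.divide(M, sums[:, None], out=out, where=sums[:, None] > 0)
        return out

    WL_col, WD_col = col_shares(LA), col_shares(DA)
    WL_row, WD_row = row_shares(LA), row_shares(DA)
    gL = WL_col @ LA[u]
    gD = WD_col @ DA[u]
    return (WL_row.T @ gL, WL_row.T @ gD, WD_row.T @ gL, WD_row.T @ gD)


def _combine(comps: tuple[np.ndarray, ...], alpha: float, beta: float) -> np.ndarray:
    a, b, c, d = comps
    return beta * (alpha * a + (1 - alpha) * b) + (1 - beta) * (alpha * c + (1 - alpha) * d)


def _loocv_folds(
    net: AssociationNetwork,
    forest: MeshForest | None,
    delta: float,
    gamma_d: float,
    gamma_l: float,
) -> Iterator[tuple[int, int, np.ndarray, tuple[np.ndarray, ...]]]:
    """Yield (u, v, negative-mask of row u, score components) per known pair."""
    A = net.A
    if forest is None:
        SS = np.zeros((net.n_diseases, net.n_diseases))
    else:
        SS = semantic_similarity_matrix(net.disease_names, forest, delta).to_numpy()
    for u, v in zip(*np.nonzero(A)):
        A_train = A.copy()
        A_train[u, v] = 0.0
        comps = _fold_components(A_train, u, net, SS, gamma_d, gamma_l)
        yield int(u), int(v), A[u] == 0.0, comps


def loocv(
    net: AssociationNetwork,
    forest: MeshForest | None = None,
    params: DiffusionParams = DiffusionParams(),
    *,
    delta: float = DEFAULT_DELTA,
    gamma_d: float = 1.0,
    gamma_l: float = 1.0,
) -> CVResult:
    """Global leave-one-association-out cross-validation, pooled over folds.

    Every similarity matrix is rebuilt from the masked training adjacency in
    each fold.  The fold's positive is the held-out pair's score; negatives
    are the scores of all pairs in the test disease's row that are unknown in
    the original adjacency.
    """
    if net.n_associations < 2:
        raise ValueError("LOOCV needs at least two known associations")
    labels: list[np.ndarray] = []
    scores: list[np.ndarray] = []
    per_disease: dict[str, list[tuple[float, np.ndarray]]] = {}
    for u, v, neg_mask, comps in _loocv_folds(net, forest, delta, gamma_d, gamma_l):
        row = _combine(comps, params.alpha, params.beta)
        pos, negs = row[v], row[neg_mask]
        labels.append(np.r_[1, np.zeros(negs.size)])
        scores.append(np.r_[pos, negs])
        per_disease.setdefault(net.disease_names[u], []).append((pos, negs))
    result = CVResult("loocv", np.concatenate(labels), np.concatenate(scores), params)
    for d, folds in per_disease.items():
        ls = np.concatenate([np.r_[1, np.zeros(n.size)] for _, n in folds])
        sc = np.concatenate([np.r_[p, n] for p, n in folds])
        if ls.any() and not ls.all():
            result.per_disease_auroc[d] = auroc(ls, sc)
    return result


def cv_local(
    net: AssociationNetwork,
    forest: MeshForest | None = None,
    params: DiffusionParams = DiffusionParams(),
    *,
    axis: str = "rows",
    n_folds: int = 5,
    seed: int = 0,
    delta: float = DEFAULT_DELTA,
    gamma_d: float = 1.0,
    gamma_l: float = 1.0,
) -> CVResult:
    """Local cross-validation holding out whole rows (diseases) or columns
    (lncRNAs), pooled over K random folds."""
    if axis not in ("rows", "cols"):
        raise ValueError(f"axis must be 'rows' or 'cols', got {axis!r}")
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    n = net.n_diseases if axis == "rows" else net.n_lncrnas
    if n_folds > n:
        raise ValueError(f"cannot split {n} {axis} into {n_folds} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    if forest is None:
        SS = np.zeros((net.n_diseases, net.n_diseases))
    else:
        SS = semantic_similarity_matrix(net.disease_names, forest, delta).to_numpy()
    labels: list[np.ndarray] = []
    scores: list[np.ndarray] = []
    for fold in np.array_split(order, n_folds):
        A_train = net.A.copy()
        if axis == "rows":
            A_train[fold, :] = 0.0
        else:
            A_train[:, fold] = 0.0
        sims = compute_similarities(net, None, SS=SS, A=A_train, gamma_d=gamma_d, gamma_l=gamma_l)
        DA, LA = ensemble_associations(A_train, sims.DS, sims.LS)
        R = score_all(DA, LA, params)
        if axis == "rows":
            held_scores, held_truth = R[fold, :], net.A[fold, :]
        else:
            held_scores, held_truth = R[:, fold], net.A[:, fold]
        labels.append(held_truth.ravel())
        scores.append(held_scores.ravel())
    all_labels = np.concatenate(labels)
    if not all_labels.any():
        raise ValueError("no fold contains a known association")
    return CVResult(f"cv_{axis}", all_labels, np.concatenate(scores), params)


def grid_search(
    net: AssociationNetwork,
    forest: MeshForest | None = None,
    *,
    alphas: tuple[float, ...] = GRID_VALUES,
    betas: tuple[float, ...] = GRID_VALUES,
    delta: float = DEFAULT_DELTA,
    gamma_d: float = 1.0,
    gamma_l: float = 1.0,
) -> tuple[float, float, float, np.ndarray]:
    """LOOCV AUROC over an (alpha, beta) grid.

    Returns ``(best_alpha, best_beta, best_auroc, table)`` where ``table``
    has shape (len(alphas), len(betas)).  Ties go to the lexicographically
    smallest (alpha, beta).  Fold similarities are computed once and shared
    across all grid points.
    """
    folds = list(_loocv_folds(net, forest, delta, gamma_d, gamma_l))
    if not folds:
        raise ValueError("network has no associations to cross-validate")
    table = np.zeros((len(alphas), len(betas)))
    for ia, alpha in enumerate(alphas):
        for ib, beta in enumerate(betas):
            labels: list[np.ndarray] = []
            scores: list[np.ndarray] = []
            for _, v, neg_mask, comps in folds:
                row = _combine(comps, alpha, beta)
                labels.append(np.r_[1, np.zeros(int(neg_mask.sum()))])
                scores.append(np.r_[row[v], row[neg_mask]])
            table[ia, ib] = auroc(np.concatenate(labels), np.concatenate(scores))
    best_flat = np.argmax(table)  # argmax scans row-major: smallest (alpha, beta) wins ties
    ia, ib = np.unravel_index(best_flat, table.shape)
    return alphas[ia], betas[ib], float(table[ia, ib]), table


@dataclass
class EnrichmentResult:
    """Verified-association enrichment per rank bin of size x."""

    x: int
    fold_scores: list[float]
    counts: list[int]
    bin_sizes: list[int]
    total_positives: int
    total_pairs: int


def enrichment(R: np.ndarray, net: AssociationNetwork, x: int) -> EnrichmentResult:
    """Bin all pairs by descending score and compute (m/size)/(M/N) per bin.

    The last bin may be smaller than x when x does not divide N; it is scored
    with its true size.  Ties in score are broken by stable flat order.
    """
    if x < 1:
        raise ValueError("bin size must be >= 1")
    scores = np.asarray(R, dtype=float).ravel()
    truth = net.A.ravel() > 0
    N = scores.size
    M = int(truth.sum())
    if M == 0:
        raise ValueError("network has no verified associations")
    order = np.argsort(-scores, kind="stable")
    sorted_truth = truth[order]
    fold_scores: list[float] = []
    counts: list[int] = []
    sizes: list[int] = []
    base = M / N
    for start in range(0, N, x):
        chunk = sorted_truth[start : start + x]
        m = int(chunk.sum())
        counts.append(m)
        sizes.append(chunk.size)
        fold_scores.append((m / chunk.size) / base)
    return EnrichmentResult(x, fold_scores, counts, sizes, M, N)


def plot_roc(result: CVResult, path: str) -> None:
    """Render the pooled ROC curve with the chance diagonal."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pts = result.roc
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot(pts[:, 0], pts[:, 1], label=f"{result.scheme} (AUROC={result.auroc:.4f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8, label="chance")
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
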