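"""Disease semantic similarity over MeSH ancestor DAGs.

Each disease located at one or more tree-number coordinates induces a DAG
consisting of those coordinates plus all of their ancestors (prefixes).  The
disease's own nodes contribute 1 to its semantic profile; every ancestor
contributes ``delta ** h`` where ``h`` is the shortest hop distance down to
one of the disease's own nodes -- equivalently, the max-over-children
recursion ``C(t) = max(delta * C(child))`` with decay ``delta`` in [0, 1).

The semantic value of a disease is the sum of its profile, and the semantic
similarity of two diseases is the contribution mass they place on shared DAG
nodes, normalized by their combined semantic values:

    SS(i, j) = sum_{t in V_i & V_j} (C_i(t) + C_j(t)) / (C(i) + C(j))

DAG nodes are identified by full tree-number coordinate; a disease with
several tree numbers has several "self" nodes, all with contribution 1.
Diseases without MeSH coverage have no profile and similarity 0 against
everything, including themselves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MeshForest, normalize_name

__all__ = [
    "MissingDAGError",
    "SemanticProfile",
    "build_profile",
    "semantic_value",
    "semantic_similarity",
    "disease_vs_set",
    "semantic_similarity_matrix",
]

DEFAULT_DELTA = 0.5


class MissingDAGError(KeyError):
    """Raised when a disease has no MeSH tree numbers, hence no DAG."""


def _ancestor_chain(tree_number: str) -> list[str]:
    """All prefixes of a coordinate, from the node itself up to its root."""
    segments = tree_number.split(".")
    return [".".join(segments[: k + 1]) for k in range(len(segments) - 1, -1, -1)]


@dataclass
class SemanticProfile:
    """Per-node semantic contributions for one disease's ancestor DAG."""

    disease: str
    contributions: dict[str, float]

    @property
    def value(self) -> float:
        return float(sum(self.contributions.values()))


def build_profile(disease: str, forest: MeshForest, delta: float = DEFAULT_DELTA) -> SemanticProfile:
    """Contribution profile of ``disease`` over its ancestor DAG.

    Raises :class:`MissingDAGError` if the disease has no tree numbers;
    callers treat its similarity row as all-zero.
    """
    if not 0.0 <= delta < 1.0:
        raise ValueError(f"delta must be in [0, 1), got {delta}")
    name = normalize_name(disease)
    numbers = forest.get(name)
    if not numbers:
        raise MissingDAGError(name)
    contributions: dict[str, float] = {}
    for tn in numbers:
        for hops, node in enumerate(_ancestor_chain(tn)):
            c = delta**hops
            if c > contributions.get(node, 0.0):
                contributions[node] = c
    # delta == 0 leaves only the self nodes with nonzero credit
    contributions = {t: c for t, c in contributions.items() if c > 0.0}
    return SemanticProfile(name, contributions)


def semantic_value(profile: SemanticProfile) -> float:
    """Total semantic score: the sum of all node contributions (>= 1)."""
    if not profile.contributions:
        raise ValueError(f"empty profile for {profile.disease!r}")
    return profile.value


def semantic_similarity(p_i: SemanticProfile, p_j: SemanticProfile) -> float:
    """Shared-node contribution mass over combined semantic values, in [0, 1]."""
    shared = p_i.contributions.keys() & p_j.contributions.keys()
    if not shared:
        return 0.0
    num = sum(p_i.contributions[t] + p_j.contributions[t] for t in shared)
    return num / (p_i.value + p_j.value)


def disease_vs_set(p: SemanticProfile, group: list[SemanticProfile]) -> float:
    """Best semantic similarity of one disease against a group (0 if empty)."""
    if not group:
        return 0.0
    return max(semantic_similarity(p, q) for q in group)


def semantic_similarity_matrix(
    diseases: list[str],
    forest: MeshForest,
    delta: float = DEFAULT_DELTA,
) -> pd.DataFrame:
    """Pairwise SS matrix for an ordered disease list.

    Rows and columns of diseases without MeSH coverage are identically zero
    (including the diagonal), which signals downstream ensembles to fall back
    to the interaction-profile kernel.
    """
    profiles: dict[int, SemanticProfile] = {}
    for idx, d in enumerate(diseases):
        try:
            profiles[idx] = build_profile(d, forest, delta)
        except MissingDAGError:
            continue
    n = len(diseases)
    SS = np.zeros((n, n))
    covered = sorted(profiles)
    # sparse-ish loop: profiles are tiny dicts, n stays in the hundreds
    for a_pos, i in enumerate(covered):
        SS[i, i] = 1.0
        for j in covered[a_pos + 1 :]:
            s = semantic_similarity(profiles[i], profiles[j])
            SS[i, j] = SS[j, i] = s
    labels = [normalize_name(d) for d in diseases]
    return pd.DataFrame(SS, index=labels, columns=labels)
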