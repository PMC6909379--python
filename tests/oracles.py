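"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive -- literal recursions and index loops
with no vectorization or caching -- so that agreement with the package is a
meaningful check rather than a tautology.
"""

from __future__ import annotations

import itertools


def dag_nodes_and_children(tree_numbers: set[str]) -> tuple[set[str], dict[str, set[str]]]:
    """Explicit ancestor DAG of a disease: node set and parent -> children map."""
    nodes: set[str] = set()
    for tn in tree_numbers:
        segs = tn.split(".")
        for k in range(1, len(segs) + 1):
            nodes.add(".".join(segs[:k]))
    children: dict[str, set[str]] = {n: set() for n in nodes}
    for n in nodes:
        if "." in n:
            parent = n.rsplit(".", 1)[0]
            children[parent].add(n)
    return nodes, children


def contribution_oracle(tree_numbers: set[str], delta: float) -> dict[str, float]:
    """Memo-free recursive evaluation of the semantic contribution rule.

    C(t) = 1 if t is one of the disease's own coordinates, else
    max over DAG children c of delta * C(c).
    """
    nodes, children = dag_nodes_and_children(tree_numbers)

    def C(t: str) -> float:
        if t in tree_numbers:
            return 1.0
        return max(delta * C(c) for c in children[t])

    return {t: C(t) for t in nodes if C(t) > 0.0}


def semantic_similarity_oracle(tns_i: set[str], tns_j: set[str], delta: float) -> float:
    ci = contribution_oracle(tns_i, delta)
    cj = contribution_oracle(tns_j, delta)
    shared = set(ci) & set(cj)
    if not shared:
        return 0.0
    num = sum(ci[t] + cj[t] for t in shared)
    return num / (sum(ci.values()) + sum(cj.values()))


def functional_similarity_oracle(A, SS) -> list[list[float]]:
    """Exhaustive-pair evaluation of best-match functional similarity."""
    n_d = len(A)
    n_l = len(A[0])
    disease_sets = [[t for t in range(n_d) if A[t][j]] for j in range(n_l)]

    def best(t: int, group: list[int]) -> float:
        return max((SS[t][d] for d in group), default=0.0)

    FS = [[0.0] * n_l for _ in range(n_l)]
    for i in range(n_l):
        for j in range(n_l):
            Di, Dj = disease_sets[i], disease_sets[j]
            if not Di or not Dj:
                continue
            num = sum(best(t, Dj) for t in Di) + sum(best(t, Di) for t in Dj)
            FS[i][j] = num / (len(Di) + len(Dj))
    return FS


def diffusion_oracle(DA, LA, u: int, alpha: float, beta: float) -> list[float]:
    """Literal index-loop transcription of the two diffusion passes.

    Terms whose normalizing column/row sum is zero contribute nothing.
    """
    n_d = len(DA)
    n_l = len(DA[0])

    def col_sum(M, i):
        return sum(M[jp][i] for jp in range(n_d))

    def row_sum(M, j):
        return sum(M[j][ip] for ip in range(n_l))

    g = []
    for j in range(n_d):
        total = 0.0
        for i in range(n_l):
            cl = col_sum(LA, i)
            if cl > 0:
                total += alpha * (LA[j][i] / cl) * LA[u][i]
            cd = col_sum(DA, i)
            if cd > 0:
                total += (1 - alpha) * (DA[j][i] / cd) * DA[u][i]
        g.append(total)
    scores = []
    for i in range(n_l):
        total = 0.0
        for j in range(n_d):
            rl = row_sum(LA, j)
            if rl > 0:
                total += beta * (LA[j][i] / rl) * g[j]
            rd = row_sum(DA, j)
            if rd > 0:
                total += (1 - beta) * (DA[j][i] / rd) * g[j]
        scores.append(total)
    return scores


def auroc_oracle(labels, scores) -> float:
    """All-pairs comparison with half credit for ties."""
    pos = [s for y, s in zip(labels, scores) if y]
    neg = [s for y, s in zip(labels, scores) if not y]
    total = 0.0
    for p, n in itertools.product(pos, neg):
        if p > n:
            total += 1.0
        elif p == n:
            total += 0.5
    return total / (len(pos) * len(neg))
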