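"""Synthetic association networks and MeSH-style tree forests.

Real inputs are (a) curated disease-lncRNA association tables and (b) the
disease branch of the MeSH thesaurus, where every disease sits at one or
more dot-coordinates of a rooted tree.  The generator emulates both with a
planted block structure: diseases and lncRNAs are split round-robin into
``n_blocks`` communities; associations appear with probability ``p_within``
inside a community and ``p_between`` across; diseases of one community draw
their tree numbers from one synthetic tree (dialect ``C01.234.567``), so
same-block diseases share ancestors (positive semantic similarity) and
cross-block diseases share none.

Defaults plant a clearly detectable two-community signal on a 20 x 20
network (p_within 0.8, p_between 0.02) with 90% MeSH coverage; a fixed seed
makes every artifact byte-identical across runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import AssociationNetwork, MeshForest

__all__ = ["SyntheticSpec", "make_forest", "make_network", "make_database_pair"]

_MAX_REDRAWS = 1000


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic study condition."""

    n_diseases: int = 20
    n_lncrnas: int = 20
    n_blocks: int = 2
    p_within: float = 0.8
    p_between: float = 0.02
    dag_depth: int = 4
    mesh_coverage: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_diseases, self.n_lncrnas, self.n_blocks) < 1:
            raise ValueError("counts must be >= 1")
        if self.dag_depth < 1:
            raise ValueError("dag_depth must be >= 1")
        for name in ("p_within", "p_between", "mesh_coverage"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    def disease_block(self, i: int) -> int:
        return i % self.n_blocks

    def lncrna_block(self, j: int) -> int:
        return j % self.n_blocks

    @property
    def disease_names(self) -> list[str]:
        return [f"disease {i:03d}" for i in range(self.n_diseases)]

    @property
    def lncrna_names(self) -> list[str]:
        return [f"lnc-{j:03d}" for j in range(self.n_lncrnas)]


def make_forest(spec: SyntheticSpec) -> MeshForest:
    """One disjoint synthetic tree per block; covered diseases get 1-2
    coordinates inside their block's tree, so cross-block semantic
    similarity is exactly zero."""
    rng = np.random.default_rng(spec.seed)
    mapping: dict[str, frozenset[str]] = {}
    covered = rng.random(spec.n_diseases) < spec.mesh_coverage
    for i, name in enumerate(spec.disease_names):
        if not covered[i]:
            continue
        root = f"C{spec.disease_block(i) + 1:02d}"
        numbers = set()
        for _ in range(int(rng.integers(1, 3))):
            depth = int(rng.integers(1, spec.dag_depth + 1))
            segs = [root] + [f"{rng.integers(0, 1000):03d}" for _ in range(depth)]
            numbers.add(".".join(segs))
        mapping[name] = frozenset(numbers)
    return MeshForest(mapping)


def make_network(spec: SyntheticSpec) -> AssociationNetwork:
    """Planted-block bipartite adjacency; redrawn until every disease and
    every lncRNA keeps at least one association (the interaction-profile
    kernel bandwidth degenerates on all-zero profile sets)."""
    rng = np.random.default_rng(spec.seed)
    d_blocks = np.array([spec.disease_block(i) for i in range(spec.n_diseases)])
    l_blocks = np.array([spec.lncrna_block(j) for j in range(spec.n_lncrnas)])
    same = d_blocks[:, None] == l_blocks[None, :]
    p = np.where(same, spec.p_within, spec.p_between)
    for _ in range(_MAX_REDRAWS):
        A = (rng.random(p.shape) < p).astype(float)
        if A.sum(axis=1).all() and A.sum(axis=0).all():
            return AssociationNetwork(spec.disease_names, spec.lncrna_names, A)
    raise ValueError(
        "could not draw a network with non-empty rows and columns; "
        "association probabilities are too small"
    )


def _cover_and_fill(
    rng: np.random.Generator,
    pairs: set[tuple[int, int]],
    diseases: range,
    lncrnas: range,
    n_target: int,
    forbidden: set[tuple[int, int]],
) -> set[tuple[int, int]]:
    """Grow ``pairs`` inside diseases x lncrnas until every entity is covered
    and exactly ``n_target`` distinct pairs exist, avoiding ``forbidden``.

    Coverage pairs join an uncovered disease with an uncovered lncRNA
    whenever possible, so the pair budget is spent on at most
    max(#uncovered diseases, #uncovered lncRNAs) coverage cells.
    """
    d_list, l_list = list(diseases), list(lncrnas)
    need_d = [d for d in d_list if d not in {x for x, _ in pairs}]
    need_l = [l for l in l_list if l not in {x for _, x in pairs}]
    rng.shuffle(need_d)
    rng.shuffle(need_l)

    def admissible(cell: tuple[int, int]) -> bool:
        return cell not in forbidden and cell not in pairs

    def random_partner(fixed_d: int | None, fixed_l: int | None) -> tuple[int, int]:
        for _ in range(10000):
            d = fixed_d if fixed_d is not None else int(rng.choice(d_list))
            l = fixed_l if fixed_l is not None else int(rng.choice(l_list))
            if admissible((d, l)):
                return d, l
        raise ValueError("could not find an admissible association cell")

    while need_d or need_l:
        if need_d and need_l and admissible((need_d[-1], need_l[-1])):
            pairs.add((need_d.pop(), need_l.pop()))
        elif need_d:
            pairs.add(random_partner(need_d.pop(), None))
        else:
            pairs.add(random_partner(None, need_l.pop()))
    if len(pairs) > n_target:
        raise ValueError("coverage already exceeds the target association count")
    while len(pairs) < n_target:
        pairs.add(random_partner(None, None))
    return pairs


def make_database_pair(
    seed: int = 0,
    *,
    counts_a: tuple[int, int, int] = (246, 372, 687),
    counts_b: tuple[int, int, int] = (97, 667, 1102),
    counts_union: tuple[int, int, int] = (295, 944, 1669),
) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Synthetic stand-in for two curated association databases with a
    controlled overlap.

    Returns two lists of (disease, lncRNA) name pairs whose per-database
    entity and association counts, and whose union counts, equal the given
    (diseases, lncRNAs, associations) triples exactly.  Defaults mirror the
    sizes of the two public lncRNA-disease databases and their combined
    table.  The content is synthetic; only the counts and the overlap
    structure are meaningful.
    """
    rng = np.random.default_rng(seed)
    (da, la, ea), (db, lb, eb), (du, lu, eu) = counts_a, counts_b, counts_union
    shared_d, shared_l, shared_e = da + db - du, la + lb - lu, ea + eb - eu
    if min(shared_d, shared_l, shared_e) < 0 or shared_e > shared_d * shared_l:
        raise ValueError("inconsistent overlap counts")
    # database A owns entity ids [0, da) x [0, la); B owns the tail ranges;
    # the overlap lives in the intersection of the two id ranges
    d_range_a, l_range_a = range(0, da), range(0, la)
    d_range_b, l_range_b = range(du - db, du), range(lu - lb, lu)
    shared_ds = range(du - db, da)
    shared_ls = range(lu - lb, la)
    assert len(shared_ds) == shared_d and len(shared_ls) == shared_l
    cells = [(d, l) for d in shared_ds for l in shared_ls]
    idx = rng.choice(len(cells), size=shared_e, replace=False)
    shared_pairs = {cells[k] for k in idx}
    pairs_a = _cover_and_fill(rng, set(shared_pairs), d_range_a, l_range_a, ea, forbidden=set())
    forbidden = pairs_a - shared_pairs
    pairs_b = _cover_and_fill(rng, set(shared_pairs), d_range_b, l_range_b, eb, forbidden=forbidden)
    assert len(pairs_a & pairs_b) == shared_e
    d_names = [f"disease {i:03d}" for i in range(du)]
    l_names = [f"lnc-{j:03d}" for j in range(lu)]

    def named(pairs: set[tuple[int, int]]) -> list[tuple[str, str]]:
        return sorted((d_names[d], l_names[l]) for d, l in pairs)

    return named(pairs_a), named(pairs_b)
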