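import numpy as np
import pytest

from idlda import AssociationNetwork, MeshForest, SyntheticSpec, make_forest, make_network


@pytest.fixture
def chain_forest() -> MeshForest:
    """Two chain diseases under a shared root, plus an uncovered disease.

    'deep' sits at R.y.z (three-node chain), 'shallow' at R.x (two-node
    chain); they share only the root R.
    """
    return MeshForest(
        {
            "shallow": frozenset({"R.x"}),
            "deep": frozenset({"R.y.z"}),
            "lone root": frozenset({"Q"}),
        }
    )


@pytest.fixture
def toy_network() -> AssociationNetwork:
    return AssociationNetwork(
        ["shallow", "deep", "uncovered"],
        ["l1", "l2"],
        np.array([[1.0, 1.0], [0.0, 1.0], [1.0, 0.0]]),
    )


@pytest.fixture
def planted() -> tuple:
    """Default two-block planted network with its matching forest."""
    spec = SyntheticSpec(seed=7)
    return make_network(spec), make_forest(spec), spec


def random_instance(rng: np.random.Generator, n_d: int, n_l: int, coverage: float = 1.0):
    """A random small network + forest for property tests.

    Every row and column keeps at least one association; tree numbers are
    random coordinates under two roots so similarity structure is nontrivial.
    """
    while True:
        A = (rng.random((n_d, n_l)) < 0.45).astype(float)
        if A.sum(axis=1).all() and A.sum(axis=0).all():
            break
    d_names = [f"d{i}" for i in range(n_d)]
    l_names = [f"l{j}" for j in range(n_l)]
    mapping = {}
    for i, name in enumerate(d_names):
        if rng.random() >= coverage:
            continue
        tns = set()
        for _ in range(int(rng.integers(1, 3))):
            root = f"C0{int(rng.integers(1, 3))}"
            depth = int(rng.integers(1, 4))
            tns.add(".".join([root] + [str(int(rng.integers(0, 4))) for _ in range(depth)]))
        mapping[name] = frozenset(tns)
    return AssociationNetwork(d_names, l_names, A), MeshForest(mapping)
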