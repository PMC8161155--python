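import numpy as np
import pytest
from hypothesis import settings

import cgmapper as cg
from cgmapper.graph import MolGraph, ensure_unknown, cycle_membership

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

VOCAB = ensure_unknown(("C", "N", "O", "S"))


def make_graph(edges, symbols, bond_channels=None):
    """Construct a MolGraph directly from an edge list (single bonds unless
    bond_channels maps (i, j) -> channel)."""
    n = len(symbols)
    index = {s: k for k, s in enumerate(VOCAB)}
    V = np.zeros((n, len(VOCAB)))
    for a, s in enumerate(symbols):
        V[a, index[s]] = 1.0
    E = np.zeros((n, n, 4))
    for i, j in edges:
        c = (bond_channels or {}).get((i, j), 0)
        E[i, j, c] = E[j, i, c] = 1.0
    g = MolGraph(
        atom_type=V,
        E=E,
        F_d=(E.sum(axis=2) > 0).sum(axis=1).astype(float),
        F_c=np.zeros(n),
        vocabulary=VOCAB,
        symbols=tuple(symbols),
    )
    g.F_c = cycle_membership(g)
    g.validate()
    return g


def permute_graph(g, perm):
    """Relabel atoms of a MolGraph by permutation: new index perm[i] = old i."""
    perm = np.asarray(perm)
    inv = np.argsort(perm)
    return MolGraph(
        atom_type=g.atom_type[inv],
        E=g.E[np.ix_(inv, inv)],
        F_d=g.F_d[inv],
        F_c=g.F_c[inv],
        vocabulary=g.vocabulary,
        symbols=tuple(g.symbols[i] for i in inv),
    )


@pytest.fixture(scope="session")
def path4():
    return make_graph([(0, 1), (1, 2), (2, 3)], "CCCC")


@pytest.fixture(scope="session")
def path3_cco():
    return make_graph([(0, 1), (1, 2)], "CCO")


@pytest.fixture(scope="session")
def star4():
    """Center 0 with three leaves 1..3."""
    return make_graph([(0, 1), (0, 2), (0, 3)], "CNOS")


@pytest.fixture(scope="session")
def two_triangles():
    """Triangles {0,1,2} and {3,4,5} joined by the bridge (2, 3)."""
    return make_graph(
        [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5), (2, 3)], "CCCCCC"
    )


@pytest.fixture(scope="session")
def small_graph_zoo(two_triangles):
    """Assorted graphs with n <= 8 for exhaustive enumeration checks."""
    zoo = [
        make_graph([(0, 1)], "CO"),
        make_graph([(0, 1), (1, 2), (2, 3)], "CCCC"),
        make_graph([(0, 1), (0, 2), (0, 3)], "CNOS"),
        make_graph([(i, (i + 1) % 6) for i in range(6)], "CCCCCC"),
        two_triangles,
        make_graph(
            [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5), (5, 0), (0, 6), (6, 7)],
            "CCCCCCCO",
        ),
    ]
    spec = cg.SynthSpec(atom_range=(5, 8), ring_prob=0.5, seed=11)
    zoo += [cg.random_molgraph(spec, seed=100 + i) for i in range(6)]
    return zoo


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small planted-rule corpus for fast training tests."""
    spec = cg.SynthSpec(n_molecules=24, atom_range=(6, 12), seed=7)
    return cg.make_dataset(spec)


@pytest.fixture(scope="session")
def tiny_model(tiny_dataset):
    """A small trained model (d=16) shared across fast tests."""
    train, _ = tiny_dataset
    model = cg.DSGPM(d=16, T=2, edge_hidden=16, epochs=8, random_state=5)
    model.fit([g for g, _ in train], [ms for _, ms in train])
    return model
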