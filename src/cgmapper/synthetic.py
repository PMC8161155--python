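"""Synthetic molecule-like graphs with planted, rule-based CG mappings.

Random connected graphs are grown as trees with optional ring closures,
respecting element valences (C:4, N:3, O:2, S:2), then annotated by a
declarative cut rule over *model-visible* local features.  The default rule
imitates expert annotation practice -- rings are separated from their
substituents and hetero groups are split off -- by cutting a bond exactly
when its endpoints differ in element or in ring membership, so every planted
bead is a maximal connected fragment of uniform (element, ring-flag).
Because the rule is a function of features the network consumes, a trained
model can in principle recover it exactly, which is what the parameter-
recovery experiments measure.

Datasets round-trip through SMILES: each generated graph is exported with
RDKit and re-parsed, so records validate against the annotation reader.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Callable

import numpy as np

from .graph import MolGraph, Mapping, ensure_unknown, from_smiles, cycle_membership
from .partition import labels_from_cuts

SYNTH_VOCAB = ("C", "N", "O", "S")
_VALENCE = {"C": 4, "N": 3, "O": 2, "S": 2}
_BOND_ORDER = {"single": 1, "double": 2, "triple": 3}


@dataclass
class SynthSpec:
    """Generation conditions for a synthetic corpus.

    Defaults mirror a small-organic-molecule corpus: 6-24 heavy atoms,
    roughly one in three molecules cyclic, carbon-dominated composition.
    """

    n_molecules: int = 250
    atom_range: tuple[int, int] = (6, 24)
    ring_prob: float = 0.35
    atom_weights: dict[str, float] = field(
        default_factory=lambda: {"C": 0.55, "N": 0.15, "O": 0.2, "S": 0.1}
    )
    bond_weights: dict[str, float] = field(
        default_factory=lambda: {"single": 0.8, "double": 0.15, "triple": 0.05}
    )
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.atom_range
        if not 2 <= lo <= hi:
            raise ValueError("atom_range must satisfy 2 <= lo <= hi")
        if not 0 <= self.ring_prob <= 1:
            raise ValueError("ring_prob must be a probability")
        for w in (self.atom_weights, self.bond_weights):
            if any(v < 0 for v in w.values()) or sum(w.values()) <= 0:
                raise ValueError("weights must be nonnegative and not all zero")
        unknown = set(self.bond_weights) - set(_BOND_ORDER)
        if unknown:
            raise ValueError(f"unsupported bond kinds {unknown}")


@dataclass
class PlantedRule:
    """Cut rule over endpoint features.

    A bond is a cut iff any enabled clause fires: ``cut_hetero`` (endpoints
    of different element), ``cut_ring_boundary`` (exactly one endpoint on a
    ring).  ``predicate(g, i, j)`` adds an arbitrary extra clause for test
    scaffolding (e.g. "every edge" -> K = n, none -> K = 1).
    """

    cut_hetero: bool = True
    cut_ring_boundary: bool = True
    predicate: Callable[[MolGraph, int, int], bool] | None = None

    def is_cut(self, g: MolGraph, i: int, j: int) -> bool:
        if self.cut_hetero and g.symbols[i] != g.symbols[j]:
            return True
        if self.cut_ring_boundary and g.F_c[i] != g.F_c[j]:
            return True
        return bool(self.predicate and self.predicate(g, i, j))

    def describe(self) -> dict:
        return {
            "cut_hetero": self.cut_hetero,
            "cut_ring_boundary": self.cut_ring_boundary,
            "custom_predicate": self.predicate is not None,
        }


def _weighted_choice(rng, weights: dict[str, float]) -> str:
    keys = sorted(weights)
    p = np.array([weights[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=p / p.sum())]


def random_molgraph(spec: SynthSpec, seed: int | None = None) -> MolGraph:
    """One random valence-respecting connected graph; deterministic per seed."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = int(rng.integers(spec.atom_range[0], spec.atom_range[1] + 1))
    symbols = [_weighted_choice(rng, spec.atom_weights) for _ in range(n)]
    free = [_VALENCE[s] for s in symbols]
    bonds: dict[tuple[int, int], int] = {}
    # grow a random tree under valence constraints; never saturate the whole
    # frontier before the last atom is placed (single bonds always qualify)
    for v in range(1, n):
        order = _BOND_ORDER[_weighted_choice(rng, spec.bond_weights)]
        frontier = sum(free[:v])

        def hosts_for(o):
            if free[v] < o:
                return []
            if v < n - 1 and (frontier - o) + (free[v] - o) < 1:
                return []
            return [u for u in range(v) if free[u] >= o]

        hosts = hosts_for(order)
        if not hosts:
            order = 1
            hosts = hosts_for(1)
        u = int(rng.choice(hosts))
        bonds[(u, v)] = order - 1  # channel: single=0, double=1, triple=2
        free[u] -= order
        free[v] -= order
    # optional single-bond ring closure (ring size 3..6)
    if rng.random() < spec.ring_prob:
        import networkx as nx

        tree = nx.Graph(list(bonds))
        dist = dict(nx.all_pairs_shortest_path_length(tree, cutoff=5))
        cands = [
            (i, j)
            for i in range(n)
            for j in range(i + 1, n)
            if free[i] >= 1 and free[j] >= 1 and 2 <= dist.get(i, {}).get(j, 99) <= 5
        ]
        if cands:
            i, j = cands[int(rng.integers(len(cands)))]
            bonds[(i, j)] = 0
    vocab = ensure_unknown(SYNTH_VOCAB)
    index = {s: k for k, s in enumerate(vocab)}
    V = np.zeros((n, len(vocab)))
    for a, s in enumerate(symbols):
        V[a, index[s]] = 1.0
    E = np.zeros((n, n, 4))
    for (i, j), c in bonds.items():
        E[i, j, c] = E[j, i, c] = 1.0
    g = MolGraph(
        atom_type=V,
        E=E,
        F_d=(E.sum(axis=2) > 0).sum(axis=1).astype(float),
        F_c=np.zeros(n),
        vocabulary=vocab,
        symbols=tuple(symbols),
    )
    g.F_c = cycle_membership(g)
    g.validate()
    return g


def plant_mapping(g: MolGraph, rule: PlantedRule | None = None) -> Mapping:
    """Ground-truth mapping induced by the rule: delete rule-positive bonds,
    one bead per connected component (always a valid mapping)."""
    rule = rule or PlantedRule()
    cuts = [(i, j) for i, j in g.edges() if rule.is_cut(g, i, j)]
    return labels_from_cuts(g, cuts)


def to_smiles(g: MolGraph) -> str:
    """Export a generated graph as SMILES (simple organics only)."""
    from rdkit import Chem

    mol = Chem.RWMol()
    for s in g.symbols:
        mol.AddAtom(Chem.Atom(s))
    kinds = [Chem.BondType.SINGLE, Chem.BondType.DOUBLE, Chem.BondType.TRIPLE,
             Chem.BondType.AROMATIC]
    for i, j in g.edges():
        c = int(np.argmax(g.E[i, j]))
        mol.AddBond(i, j, kinds[c])
    out = mol.GetMol()
    Chem.SanitizeMol(out)
    return Chem.MolToSmiles(out)


def make_dataset(spec: SynthSpec, rule: PlantedRule | None = None,
                 out_dir=None, train_fraction: float = 0.8):
    """Annotated synthetic corpus with a molecule-level train/test split.

    Each record's graph round-trips through SMILES (so files validate with
    the annotation reader) and the planted rule is applied to the re-parsed
    graph, keeping annotation indices consistent with the SMILES atom
    order.  Duplicate molecules are regenerated.  With ``out_dir`` set,
    writes train.json / test.json / manifest.json; byte-identical per seed.
    """
    rule = rule or PlantedRule()
    entries: list[tuple[MolGraph, list[Mapping]]] = []
    seen: set[str] = set()
    attempt = 0
    while len(entries) < spec.n_molecules:
        if attempt > 50 * spec.n_molecules:
            raise RuntimeError("generation stalled; spec infeasible?")
        g0 = random_molgraph(spec, seed=(spec.seed * 1_000_003 + attempt) % 2**31)
        attempt += 1
        try:
            smiles = to_smiles(g0)
        except Exception:  # rare sanitization rejection
            continue
        if smiles in seen:
            continue
        seen.add(smiles)
        g = from_smiles(smiles, ensure_unknown(SYNTH_VOCAB))
        entries.append((g, [plant_mapping(g, rule)]))
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(len(entries))
    n_train = int(round(train_fraction * len(entries)))
    train = [entries[i] for i in perm[:n_train]]
    test = [entries[i] for i in perm[n_train:]]
    if out_dir is not None:
        from pathlib import Path
        from .graph import write_mappings

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_mappings(train, out / "train.json")
        write_mappings(test, out / "test.json")
        manifest = {
            "spec": asdict(spec),
            "rule": rule.describe(),
            "train_fraction": train_fraction,
            "n_train": len(train),
            "n_test": len(test),
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
            fh.write("\n")
    return train, test
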