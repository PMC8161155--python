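"""Molecular graphs and coarse-grained (CG) mappings.

A molecule is represented over its heavy atoms only: ``MolGraph`` holds a
one-hot atom-type matrix ``V`` over a dataset-level vocabulary, a symmetric
``n x n x 4`` bond tensor ``E`` (one-hot bond type per bonded pair), the
per-atom degree ``F_d`` and a per-atom cycle indicator ``F_c``.  A CG mapping
(``Mapping``) assigns every atom to one of ``K`` beads; the *cuts* of a
mapping are the bonds whose endpoints land in different beads.

Annotated datasets are JSON files of records
``{"smiles": ..., "cgnodes": [[atom idx of bead 0], [bead 1], ...]}``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

#: fixed channel order of the bond-type one-hot
BOND_CHANNELS = ("single", "double", "triple", "aromatic")

#: reserved vocabulary entry for atom types unseen at training time
UNKNOWN_ATOM = "*"


class AnnotationError(ValueError):
    """An annotation record violates the Mapping invariants."""


@dataclass
class MolGraph:
    """Heavy-atom molecular graph with model input features.

    Attributes
    ----------
    atom_type : (n, |Q|) float array, one-hot rows over ``vocabulary``
    E : (n, n, 4) float array, symmetric bond tensor, zero diagonal
    F_d : (n,) float array, heavy-atom degree
    F_c : (n,) {0,1} array, 1 iff the atom lies on a cycle
    vocabulary : atom-type vocabulary Q the one-hot refers to
    smiles : source SMILES if the graph came from one
    """

    atom_type: np.ndarray
    E: np.ndarray
    F_d: np.ndarray
    F_c: np.ndarray
    vocabulary: tuple[str, ...]
    smiles: str | None = None
    symbols: tuple[str, ...] = field(default=())

    @property
    def n(self) -> int:
        return self.atom_type.shape[0]

    @property
    def adjacency(self) -> np.ndarray:
        """Binary (n, n) adjacency collapsed over bond-type channels."""
        return (self.E.sum(axis=2) > 0).astype(float)

    def edges(self) -> list[tuple[int, int]]:
        """Sorted list of bonded pairs (i, j) with i < j."""
        a = self.adjacency
        return [(i, j) for i in range(self.n) for j in range(i + 1, self.n) if a[i, j]]

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n))
        g.add_edges_from(self.edges())
        return g

    def validate(self) -> None:
        n = self.n
        if self.E.shape != (n, n, 4):
            raise ValueError(f"bond tensor shape {self.E.shape} != {(n, n, 4)}")
        if not np.array_equal(self.E, self.E.transpose(1, 0, 2)):
            raise ValueError("bond tensor not symmetric")
        if np.any(self.E[np.arange(n), np.arange(n)] != 0):
            raise ValueError("self bonds present")
        per_pair = self.E.sum(axis=2)
        if not np.all(np.isin(per_pair, (0.0, 1.0))):
            raise ValueError("each bonded pair must have exactly one bond-type channel set")
        if not np.array_equal(self.F_d, (per_pair > 0).sum(axis=1).astype(float)):
            raise ValueError("F_d inconsistent with bond tensor")
        if n > 1 and not nx.is_connected(self.to_networkx()):
            raise ValueError("molecular graph must be connected")


@dataclass(frozen=True)
class Mapping:
    """Per-atom bead assignment ``B`` with bead count ``K``."""

    B: tuple[int, ...]
    K: int

    @staticmethod
    def from_labels(labels) -> "Mapping":
        labels = [int(x) for x in labels]
        return Mapping(B=tuple(labels), K=(max(labels) + 1 if labels else 0))

    def beads(self) -> list[list[int]]:
        out: list[list[int]] = [[] for _ in range(self.K)]
        for i, b in enumerate(self.B):
            out[b].append(i)
        return out

    def validate(self, g: MolGraph) -> None:
        if len(self.B) != g.n:
            raise AnnotationError(f"mapping length {len(self.B)} != atom count {g.n}")
        used = set(self.B)
        if used != set(range(self.K)):
            raise AnnotationError(f"bead indices {sorted(used)} are not dense 0..{self.K - 1}")
        gx = g.to_networkx()
        for k, atoms in enumerate(self.beads()):
            sub = gx.subgraph(atoms)
            if len(atoms) > 1 and not nx.is_connected(sub):
                raise AnnotationError(f"bead {k} induces a disconnected subgraph")


def derive_cuts(g: MolGraph, m: Mapping) -> frozenset[tuple[int, int]]:
    """Bonds whose endpoints carry different bead labels.

    Invariant under any permutation of bead indices.
    """
    if len(m.B) != g.n:
        raise ValueError(f"mapping length {len(m.B)} != atom count {g.n}")
    return frozenset((i, j) for i, j in g.edges() if m.B[i] != m.B[j])


def cycle_membership(g: MolGraph | nx.Graph) -> np.ndarray:
    """Per-atom cycle indicator from a cycle basis of the graph.

    An atom is flagged 1 iff it appears in at least one basis cycle; on a
    connected graph this is exactly the set of atoms lying on any cycle.
    """
    gx = g if isinstance(g, nx.Graph) else g.to_networkx()
    flag = np.zeros(gx.number_of_nodes())
    for cyc in nx.cycle_basis(gx):
        flag[list(cyc)] = 1.0
    return flag


def _bond_channel(bond) -> int:
    from rdkit import Chem

    order = {
        Chem.BondType.SINGLE: 0,
        Chem.BondType.DOUBLE: 1,
        Chem.BondType.TRIPLE: 2,
        Chem.BondType.AROMATIC: 3,
    }
    try:
        return order[bond.GetBondType()]
    except KeyError:
        logger.warning("bond type %s mapped to 'single' channel", bond.GetBondType())
        return 0


def from_smiles(smiles: str, vocabulary) -> MolGraph:
    """Parse a SMILES string into a heavy-atom :class:`MolGraph`.

    Hydrogens are stripped; atom indices follow the parser's atom order for
    the given SMILES (which is what annotation files refer to).  Atom types
    missing from ``vocabulary`` map to the reserved unknown slot and are
    logged.  Multi-fragment SMILES are rejected.
    """
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    if len(Chem.GetMolFrags(mol)) != 1:
        raise ValueError(f"multi-fragment SMILES rejected: {smiles!r}")
    mol = Chem.RemoveHs(mol)
    vocabulary = ensure_unknown(vocabulary)
    index = {s: i for i, s in enumerate(vocabulary)}
    n = mol.GetNumAtoms()
    V = np.zeros((n, len(vocabulary)))
    symbols = []
    for a in mol.GetAtoms():
        sym = a.GetSymbol()
        symbols.append(sym)
        if sym not in index:
            logger.warning("atom type %s not in vocabulary; using unknown slot", sym)
        V[a.GetIdx(), index.get(sym, index[UNKNOWN_ATOM])] = 1.0
    E = np.zeros((n, n, 4))
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        c = _bond_channel(b)
        E[i, j, c] = E[j, i, c] = 1.0
    F_d = (E.sum(axis=2) > 0).sum(axis=1).astype(float)
    g = MolGraph(
        atom_type=V,
        E=E,
        F_d=F_d,
        F_c=np.zeros(n),
        vocabulary=tuple(vocabulary),
        smiles=smiles,
        symbols=tuple(symbols),
    )
    g.F_c = cycle_membership(g)
    g.validate()
    return g


def ensure_unknown(vocabulary) -> tuple[str, ...]:
    """Vocabulary with the reserved unknown slot appended if absent."""
    vocab = tuple(vocabulary)
    return vocab if UNKNOWN_ATOM in vocab else vocab + (UNKNOWN_ATOM,)


def build_vocabulary(smiles_list) -> tuple[str, ...]:
    """Sorted atom-type vocabulary of a corpus, plus the unknown slot."""
    from rdkit import Chem

    seen: set[str] = set()
    for s in smiles_list:
        mol = Chem.MolFromSmiles(s)
        if mol is None:
            continue
        seen.update(a.GetSymbol() for a in mol.GetAtoms())
    return ensure_unknown(sorted(seen))


# ---------------------------------------------------------------------------
# annotated-dataset I/O (the HAM-release JSON dialect)

DEFAULT_KEYS = {"smiles": "smiles", "beads": "cgnodes"}


def _mapping_from_beads(g: MolGraph, beads) -> Mapping:
    B = [-1] * g.n
    for k, atoms in enumerate(beads):
        for a in atoms:
            a = int(a)
            if not 0 <= a < g.n:
                raise AnnotationError(f"atom index {a} out of range for {g.n} atoms")
            if B[a] != -1:
                raise AnnotationError(f"atom {a} assigned to two beads")
            B[a] = k
    if -1 in B:
        raise AnnotationError(f"atom {B.index(-1)} not assigned to any bead")
    m = Mapping(B=tuple(B), K=len(beads))
    m.validate(g)
    return m


def load_annotations(path, vocabulary=None, keys=DEFAULT_KEYS):
    """Read an annotated-mapping JSON file.

    Returns a list of ``(MolGraph, [Mapping, ...])`` with one entry per
    distinct SMILES; invalid records are skipped with a logged warning.  If
    ``vocabulary`` is None it is built from the file's molecules.
    """
    with open(path) as fh:
        records = json.load(fh)
    if not isinstance(records, list):
        raise ValueError("annotation file must contain a list of records")
    if vocabulary is None:
        vocabulary = build_vocabulary(r[keys["smiles"]] for r in records)
    out: dict[str, tuple[MolGraph, list[Mapping]]] = {}
    for idx, rec in enumerate(records):
        smiles = rec[keys["smiles"]]
        try:
            if smiles in out:
                g = out[smiles][0]
            else:
                g = from_smiles(smiles, vocabulary)
            m = _mapping_from_beads(g, rec[keys["beads"]])
        except (ValueError, KeyError) as exc:
            logger.warning("skipping record %d (%s): %s", idx, smiles, exc)
            continue
        out.setdefault(smiles, (g, []))[1].append(m)
    return list(out.values())


def write_mappings(entries, path, keys=DEFAULT_KEYS) -> None:
    """Write ``(MolGraph, [Mapping, ...])`` entries as annotation JSON.

    Round-trips bit-exactly with :func:`load_annotations`.
    """
    records = []
    for g, mappings in entries:
        if g.smiles is None:
            raise ValueError("cannot serialize a graph without a SMILES source")
        for m in mappings:
            records.append({keys["smiles"]: g.smiles, keys["beads"]: m.beads()})
    with open(path, "w") as fh:
        json.dump(records, fh, indent=1)
        fh.write("\n")


def write_mapping(g: MolGraph, m: Mapping, path) -> None:
    """Write a single graph/mapping pair as a one-record annotation file."""
    write_mappings([(g, [m])], path)
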