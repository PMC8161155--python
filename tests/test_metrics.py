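"""AMI and cut metrics against independent references; CV protocol."""

import itertools
from functools import lru_cache
from math import lgamma, log, exp

import numpy as np
import pytest
from hypothesis import given, strategies as st

import cgmapper as cg
from cgmapper.graph import Mapping

from conftest import make_graph


# --- independent AMI reference: contingency table + hypergeometric EMI -----

def _contingency(a, b):
    ka, kb = max(a) + 1, max(b) + 1
    t = np.zeros((ka, kb), dtype=int)
    for x, y in zip(a, b):
        t[x, y] += 1
    return t


def _entropy(counts, n):
    return -sum(c / n * log(c / n) for c in counts if c > 0)


@lru_cache(maxsize=None)
def _ref_ami_cached(table_bytes, shape):
    t = np.frombuffer(table_bytes, dtype=int).reshape(shape)
    n = int(t.sum())
    a, b = t.sum(axis=1), t.sum(axis=0)
    mi = 0.0
    for i in range(t.shape[0]):
        for j in range(t.shape[1]):
            nij = t[i, j]
            if nij > 0:
                mi += nij / n * log(n * nij / (a[i] * b[j]))
    # expected MI under the permutation (hypergeometric) null
    emi = 0.0
    lg = lgamma
    for i in range(t.shape[0]):
        for j in range(t.shape[1]):
            lo = max(1, a[i] + b[j] - n)
            for nij in range(lo, min(a[i], b[j]) + 1):
                lp = (
                    lg(a[i] + 1) + lg(b[j] + 1) + lg(n - a[i] + 1) + lg(n - b[j] + 1)
                    - lg(n + 1) - lg(nij + 1) - lg(a[i] - nij + 1)
                    - lg(b[j] - nij + 1) - lg(n - a[i] - b[j] + nij + 1)
                )
                emi += exp(lp) * (nij / n) * log(n * nij / (a[i] * b[j]))
    hu, hv = _entropy(a, n), _entropy(b, n)
    if hu == 0.0 and hv == 0.0:
        return 1.0
    denom = max(hu, hv) - emi
    if denom == 0.0:
        return 0.0
    return (mi - emi) / denom


def ref_ami(a, b):
    t = _contingency(tuple(a), tuple(b))
    return _ref_ami_cached(t.tobytes(), t.shape)


def all_partitions(n):
    """All set partitions of range(n) as dense label tuples (RGS)."""
    out = []

    def rec(i, labels, k):
        if i == n:
            out.append(tuple(labels))
            return
        for lab in range(k + 1):
            labels.append(lab)
            rec(i + 1, labels, k + (1 if lab == k else 0))
            labels.pop()

    rec(0, [], 0)
    return out


class TestAMI:
    def test_identical_labelings(self):
        assert cg.ami([0, 0, 1, 1], [0, 0, 1, 1]) == pytest.approx(1.0)

    def test_renamed_labels(self):
        assert cg.ami([0, 0, 1, 2], [2, 2, 0, 1]) == pytest.approx(1.0)

    def test_constant_vs_two_clusters_is_zero(self):
        assert cg.ami([0, 0, 0, 0], [0, 0, 1, 1]) == pytest.approx(0.0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            cg.ami([0, 1], [0, 1, 2])

    @pytest.mark.parametrize("n", [2, 3, 4, 5, 6])
    def test_exhaustive_against_reference(self, n):
        """Every pair of set partitions of n points matches the independent
        contingency-table / hypergeometric-EMI computation.

        AMI depends on the pair only through its contingency table, up to
        row/column permutation, so each canonical table is checked once.
        """
        parts = all_partitions(n)
        checked = {}
        for a in parts:
            for b in parts:
                t = _contingency(a, b)
                canon = tuple(sorted(map(tuple, t[np.lexsort(t.T[::-1])].T)))
                if canon in checked:
                    continue
                checked[canon] = (a, b)
                assert cg.ami(a, b) == pytest.approx(ref_ami(a, b), abs=1e-8), (a, b)


class TestCutPRF:
    def test_perfect(self):
        s = frozenset({(0, 1), (2, 3)})
        assert cg.cut_prf(s, s) == (1.0, 1.0, 1.0)

    def test_disjoint(self):
        assert cg.cut_prf({(0, 1)}, {(2, 3)}) == (0.0, 0.0, 0.0)

    def test_arithmetic(self):
        pred = {(0, 1), (1, 2), (2, 3), (3, 4)}
        truth = {(0, 1), (1, 2), (2, 3), (5, 6), (7, 8)}
        p, r, f1 = cg.cut_prf(pred, truth)
        assert (p, r) == (0.75, 0.6)
        assert f1 == pytest.approx(2 / 3)

    def test_empty_conventions(self):
        assert cg.cut_prf(set(), set()) == (1.0, 1.0, 1.0)
        assert cg.cut_prf(set(), {(0, 1)})[:2] == (0.0, 0.0)
        assert cg.cut_prf({(0, 1)}, set())[1] == 0.0

    def test_matches_set_arithmetic_exhaustively(self):
        """All predicted/true cut subsets of a 4-edge path (n <= 6 regime)."""
        edges = [(0, 1), (1, 2), (2, 3), (3, 4)]
        for pr in range(16):
            for tr in range(16):
                pred = frozenset(e for k, e in enumerate(edges) if pr >> k & 1)
                truth = frozenset(e for k, e in enumerate(edges) if tr >> k & 1)
                p, r, f1 = cg.cut_prf(pred, truth)
                tp = len(pred & truth)
                if pred:
                    assert p == tp / len(pred)
                if truth:
                    assert r == tp / len(truth)
                if p + r:
                    assert f1 == pytest.approx(2 * p * r / (p + r))


class TestScoreMolecule:
    def test_single_annotation_plain(self, path4):
        pred = Mapping((0, 0, 1, 1), 2)
        row = cg.score_molecule(path4, pred, [pred])
        assert row.ami == pytest.approx(1.0) and row.cut_f1 == 1.0

    def test_best_of_two_annotations(self, path4):
        pred = Mapping((0, 0, 1, 1), 2)
        other = Mapping((0, 1, 1, 1), 2)
        row = cg.score_molecule(path4, pred, [other, pred])
        assert row.ami == pytest.approx(1.0)
        assert row.cut_f1 == 1.0

    def test_best_of_dominates_each_single(self):
        g = make_graph([(i, i + 1) for i in range(5)], "CCCCCC")
        pred = Mapping((0, 0, 0, 1, 1, 1), 2)
        anns = [
            Mapping((0, 0, 1, 1, 2, 2), 3),
            Mapping((0, 0, 0, 0, 1, 1), 2),
            Mapping((0, 1, 2, 3, 4, 5), 6),
        ]
        best = cg.score_molecule(g, pred, anns)
        for m in anns:
            single = cg.score_molecule(g, pred, [m])
            assert best.ami >= single.ami - 1e-12
            assert best.cut_f1 >= single.cut_f1 - 1e-12


class TestKFold:
    def test_even_sizes(self):
        folds = cg.kfold_split(10, k=5, seed=0)
        assert [len(f) for f in folds] == [2] * 5

    @given(st.integers(5, 40), st.integers(2, 5), st.integers(0, 1000))
    def test_partition_property(self, n, k, seed):
        folds = cg.kfold_split(n, k=k, seed=seed)
        flat = np.concatenate(folds)
        assert sorted(flat.tolist()) == list(range(n))
        assert max(len(f) for f in folds) - min(len(f) for f in folds) <= 1

    def test_seeded_reproducible(self):
        a = cg.kfold_split(17, k=4, seed=3)
        b = cg.kfold_split(17, k=4, seed=3)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))

    def test_k_too_large(self):
        with pytest.raises(ValueError):
            cg.kfold_split(3, k=5, seed=0)


class _OracleModel:
    """Predicts the first annotation exactly (a perfect predictor)."""

    def __init__(self):
        self.memory = {}

    def fit(self, graphs, anns):
        return self

    def predict(self, graphs, K=None):
        return [cg.plant_mapping(g) for g in graphs]


class TestEvaluateDataset:
    def test_perfect_predictor_scores_one(self, tiny_dataset):
        train, test = tiny_dataset
        data = (train + test)[:10]
        rep = cg.evaluate_dataset(_OracleModel, data, k=2, seed=0)
        agg = rep.aggregate()
        assert agg["ami"] == pytest.approx(1.0)
        assert agg["cut_f1"] == pytest.approx(1.0)
        assert agg["n_molecules"] == 10
        assert cg.fold_means(rep)["ami"] == pytest.approx(1.0)

    def test_one_row_per_molecule_with_fold_ids(self, tiny_dataset):
        train, test = tiny_dataset
        data = (train + test)[:8]
        rep = cg.evaluate_dataset(_OracleModel, data, k=4, seed=1)
        assert len(rep.rows) == 8
        assert sorted({r.fold for r in rep.rows}) == [0, 1, 2, 3]

    def test_fold_means_of_constant_rows(self):
        rep = cg.MetricsReport(
            rows=[
                cg.MoleculeScore(ami=0.5, cut_precision=0.5, cut_recall=0.5,
                                 cut_f1=0.5, fold=f)
                for f in (0, 0, 1)
            ]
        )
        assert cg.fold_means(rep)["ami"] == pytest.approx(0.5)


class TestHumanAgreement:
    def test_identical_annotations_agree_perfectly(self, path4):
        m = Mapping((0, 0, 1, 1), 2)
        rep = cg.human_agreement([(path4, [m, m])])
        assert rep.rows[0].ami == pytest.approx(1.0)
        assert rep.rows[0].cut_f1 == pytest.approx(1.0)

    def test_different_K_pairs_skipped(self, path4):
        rep = cg.human_agreement(
            [(path4, [Mapping((0, 0, 1, 1), 2), Mapping((0, 1, 2, 2), 3)])]
        )
        assert rep.rows == []
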