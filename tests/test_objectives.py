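"""Triplet/pair enumeration against brute force; loss identities."""

import itertools

import numpy as np
import pytest

import cgmapper as cg
from cgmapper.graph import Mapping, derive_cuts
from cgmapper.objectives import (
    bce_with_logits,
    edge_cut_logits,
    init_cut_head,
    predict_topk_cuts,
)
from cgmapper._autodiff import Tensor

from conftest import make_graph


def brute_triplets(g, m):
    cuts = derive_cuts(g, m)
    edges = set(g.edges())

    def is_edge(i, j):
        return (min(i, j), max(i, j)) in edges

    def is_cut(i, j):
        return (min(i, j), max(i, j)) in cuts

    n = g.n
    return sorted(
        (a, p, x)
        for a, p, x in itertools.product(range(n), repeat=3)
        if is_edge(a, p) and not is_cut(a, p) and is_edge(a, x) and is_cut(a, x)
    )


def brute_pairs(g, m):
    cuts = derive_cuts(g, m)
    return sorted(e for e in g.edges() if e not in cuts)


def random_mapping(g, rng):
    labels = rng.integers(0, 3, size=g.n)
    dense = {}
    return Mapping.from_labels([dense.setdefault(int(x), len(dense)) for x in labels])


class TestEnumeration:
    def test_path_hand_example(self):
        g = make_graph([(0, 1), (1, 2)], "CCO")
        m = Mapping((0, 0, 1), 2)
        assert cg.enumerate_triplets(g, m) == [(1, 0, 2)]
        assert cg.enumerate_pairs(g, m) == [(0, 1)]

    def test_single_bead_empty_triplets_all_pairs(self, two_triangles):
        m = Mapping((0,) * 6, 1)
        assert cg.enumerate_triplets(two_triangles, m) == []
        assert cg.enumerate_pairs(two_triangles, m) == sorted(two_triangles.edges())

    def test_star_hand_example(self):
        # center 0, leaves 1-3; leaves in 3 beads, center with leaf 1
        g = make_graph([(0, 1), (0, 2), (0, 3)], "CCCC")
        m = Mapping((0, 0, 1, 2), 3)
        assert cg.enumerate_triplets(g, m) == [(0, 1, 2), (0, 1, 3)]

    def test_all_singletons_empty_pairs(self, star4):
        m = Mapping((0, 1, 2, 3), 4)
        assert cg.enumerate_pairs(star4, m) == []

    def test_matches_brute_force_on_zoo(self, small_graph_zoo):
        rng = np.random.default_rng(42)
        for g in small_graph_zoo:
            if g.n > 8:
                continue
            for _ in range(5):
                m = random_mapping(g, rng)
                assert cg.enumerate_triplets(g, m) == brute_triplets(g, m)
                assert cg.enumerate_pairs(g, m) == brute_pairs(g, m)


class TestLossIdentities:
    def test_identical_embeddings_triplet_equals_margin(self):
        X = np.ones((4, 3)) / np.sqrt(3)
        trips = [(0, 1, 2), (1, 2, 3)]
        assert cg.triplet_loss(X, trips, alpha=0.7) == pytest.approx(0.7)
        assert cg.pair_loss(X, [(0, 1), (2, 3)]) == pytest.approx(0.0)

    def test_hinge_boundary_is_zero(self):
        alpha = 0.5
        X = np.array([[1.0, 0.0], [1.0, 0.0], [1.0, alpha]])  # d(a,p)=0, d(a,n)=alpha
        assert cg.triplet_loss(X, [(0, 1, 2)], alpha=alpha) == pytest.approx(0.0, abs=1e-5)

    def test_orthogonal_negative_example(self):
        X = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        # max(0, 0 - sqrt(2) + 0.5) = 0
        assert cg.triplet_loss(X, [(0, 1, 2)], alpha=0.5) == 0.0
        # single pair distance^2 = 2; mean over {2, 0} = 1
        assert cg.pair_loss(X, [(0, 2)]) == pytest.approx(2.0)
        assert cg.pair_loss(X, [(0, 2), (0, 1)]) == pytest.approx(1.0)

    def test_total_loss_arithmetic(self):
        X = np.eye(3)
        # with stub sets empty, components contribute 0
        assert cg.total_loss(X, [], [], alpha=1.0, lam=0.1) == 0.0
        # 0.3 + 0.1 * 1.0 computed from constructed embeddings
        Xp = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        lt = cg.triplet_loss(Xp, [(0, 1, 2)], alpha=np.sqrt(2) + 0.3)  # hinge = 0.3
        lp = cg.pair_loss(Xp, [(0, 2), (0, 1)])  # 1.0
        assert lt == pytest.approx(0.3, abs=1e-5)
        total = cg.total_loss(Xp, [(0, 1, 2)], [(0, 2), (0, 1)],
                              alpha=np.sqrt(2) + 0.3, lam=0.1)
        assert total == pytest.approx(0.4, abs=1e-5)

    def test_lambda_zero_reduces_to_triplet(self):
        X = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 0.0]])
        trips, pairs = [(0, 2, 1)], [(0, 2)]
        assert cg.total_loss(X, trips, pairs, alpha=1.0, lam=0.0) == pytest.approx(
            cg.triplet_loss(X, trips, alpha=1.0)
        )
        assert cg.total_loss(X, trips, pairs, alpha=1.0, lam=0.5,
                             use_triplet=False) == pytest.approx(
            0.5 * cg.pair_loss(X, pairs)
        )

    def test_rotation_invariance(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(6, 4))
        X /= np.linalg.norm(X, axis=1, keepdims=True)
        q, _ = np.linalg.qr(rng.normal(size=(4, 4)))
        trips = [(0, 1, 2), (3, 4, 5)]
        pairs = [(0, 3), (1, 4)]
        assert cg.triplet_loss(X @ q, trips, 1.0) == pytest.approx(
            cg.triplet_loss(X, trips, 1.0)
        )
        assert cg.pair_loss(X @ q, pairs) == pytest.approx(cg.pair_loss(X, pairs))


class TestCutClassifierHead:
    def test_logits_symmetric_in_endpoints(self, two_triangles):
        head = init_cut_head(width=5, hidden=7, seed=0)
        rng = np.random.default_rng(0)
        X = rng.normal(size=(6, 5))
        logits, edges = edge_cut_logits(X, two_triangles, head)
        # recompute with every edge reversed: scores must be identical
        flipped = [(j, i) for i, j in edges]
        i, j = (np.array(c) for c in zip(*flipped))
        from cgmapper._autodiff import concat_cols

        Xt = Tensor(X)

        def score(a, b):
            f = concat_cols([Xt.rows(a), Xt.rows(b)])
            return (f @ head["W_c1"] + head["b_c1"]).relu() @ head["W_c2"] + head["b_c2"]

        assert np.allclose(logits, (score(i, j) + score(j, i)).data)

    def test_bce_matches_reference(self):
        rng = np.random.default_rng(2)
        logits = Tensor(rng.normal(size=(5, 1)))
        y = rng.integers(0, 2, size=(5, 1)).astype(float)
        p = 1 / (1 + np.exp(-logits.data))
        ref = -np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))
        assert float(bce_with_logits(logits, y).data) == pytest.approx(ref)

    def test_topk_selection(self):
        edges = [(0, 1), (1, 2), (2, 3), (3, 4)]
        probs = [0.1, 0.9, 0.4, 0.9]
        assert predict_topk_cuts(probs, edges, 1) == {(1, 2)}
        assert predict_topk_cuts(probs, edges, 2) == {(1, 2), (3, 4)}
        assert predict_topk_cuts(probs, edges, 4) == set(edges)
        with pytest.raises(ValueError):
            predict_topk_cuts(probs, edges, 5)

    def test_perfect_probabilities_recover_truth(self, two_triangles):
        m = Mapping((0, 0, 0, 1, 1, 1), 2)
        truth = derive_cuts(two_triangles, m)
        edges = two_triangles.edges()
        probs = [1.0 if e in truth else 0.0 for e in edges]
        pred = predict_topk_cuts(probs, edges, len(truth))
        assert pred == truth
        assert cg.cut_prf(pred, truth) == (1.0, 1.0, 1.0)
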