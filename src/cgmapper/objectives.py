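"""Training objectives over annotated molecular graphs.

The metric-learning objective enumerates, exhaustively, (anchor, positive,
negative) atom triplets -- a non-cut bond <a, p> and a cut bond <a, n>
sharing the anchor -- and non-cut bond pairs, then penalizes triplets whose
embedding distances violate a margin and pulls non-cut pairs together:

    L = mean_P max(0, ||x_a - x_p|| - ||x_a - x_n|| + alpha)
        + lambda * mean_S ||x_a - x_a'||^2

The alternative edge-classification head scores each bond's probability of
being a cut from its endpoint embeddings (symmetrized over both endpoint
orders) and is trained with binary cross-entropy.
"""

from __future__ import annotations

import numpy as np

from ._autodiff import Tensor, concat_cols, mean_all
from .graph import MolGraph, Mapping, derive_cuts

_EPS = 1e-12


def enumerate_triplets(g: MolGraph, m: Mapping) -> list[tuple[int, int, int]]:
    """All (a, p, n) with <a,p> a non-cut bond and <a,n> a cut bond.

    Exhaustive and sorted; empty when the mapping has no cuts (K = 1).
    """
    cuts = derive_cuts(g, m)
    pos: dict[int, list[int]] = {}
    neg: dict[int, list[int]] = {}
    for i, j in g.edges():
        kind = neg if (i, j) in cuts else pos
        kind.setdefault(i, []).append(j)
        kind.setdefault(j, []).append(i)
    out = [
        (a, p, n)
        for a in sorted(set(pos) & set(neg))
        for p in sorted(pos[a])
        for n in sorted(neg[a])
    ]
    return sorted(out)


def enumerate_pairs(g: MolGraph, m: Mapping) -> list[tuple[int, int]]:
    """All non-cut bonds (i, j), i < j, sorted."""
    cuts = derive_cuts(g, m)
    return sorted(e for e in g.edges() if e not in cuts)


def _row_dists(X: Tensor, idx_a, idx_b) -> Tensor:
    diff = X.rows(idx_a) - X.rows(idx_b)
    return (diff.sumsq_rows() + _EPS).sqrt()


def triplet_loss(X, triplets, alpha: float):
    """Mean hinge over the triplet set; 0 for an empty set.

    Zero exactly when ||x_a - x_p|| + alpha <= ||x_a - x_n|| for every
    triplet.  Returns a Tensor if given one (for backprop), else a float.
    """
    as_tensor = isinstance(X, Tensor)
    if len(triplets) == 0:
        return Tensor(0.0) if as_tensor else 0.0
    Xt = X if as_tensor else Tensor(np.asarray(X))
    a, p, n = (np.array(col) for col in zip(*triplets))
    hinge = (_row_dists(Xt, a, p) - _row_dists(Xt, a, n) + alpha).relu()
    loss = mean_all(hinge)
    return loss if as_tensor else float(loss.data)


def pair_loss(X, pairs):
    """Mean squared embedding distance over non-cut bonds; 0 if empty."""
    as_tensor = isinstance(X, Tensor)
    if len(pairs) == 0:
        return Tensor(0.0) if as_tensor else 0.0
    Xt = X if as_tensor else Tensor(np.asarray(X))
    a, b = (np.array(col) for col in zip(*pairs))
    loss = mean_all((Xt.rows(a) - Xt.rows(b)).sumsq_rows())
    return loss if as_tensor else float(loss.data)


def total_loss(X, triplets, pairs, alpha: float, lam: float,
               use_triplet: bool = True, use_pair: bool = True):
    """L = L_triplet + lambda * L_pair, with ablation switches."""
    lt = triplet_loss(X, triplets, alpha) if use_triplet else 0.0
    lp = pair_loss(X, pairs) if use_pair else 0.0
    return lt + lam * lp


# ---------------------------------------------------------------------------
# edge-classification ("Cut Cls.") head

def init_cut_head(width: int, hidden: int, seed: int) -> dict[str, Tensor]:
    """Small MLP 2*width -> hidden -> 1 scoring an ordered endpoint pair."""
    rng = np.random.default_rng(seed)

    def u(fan_in, shape):
        b = 1.0 / np.sqrt(fan_in)
        return Tensor(rng.uniform(-b, b, size=shape))

    return {
        "W_c1": u(2 * width, (2 * width, hidden)),
        "b_c1": u(2 * width, (hidden,)),
        "W_c2": u(hidden, (hidden, 1)),
        "b_c2": u(hidden, (1,)),
    }


def edge_cut_logits(X, g: MolGraph, head) -> tuple[object, list[tuple[int, int]]]:
    """Per-bond cut logit, symmetrized by summing both endpoint orders.

    Returns (logits (m, 1), edges) with edges in sorted order.
    """
    edges = g.edges()
    Xt = X if isinstance(X, Tensor) else Tensor(np.asarray(X))
    i, j = (np.array(col) for col in zip(*edges))

    def score(a, b):
        feats = concat_cols([Xt.rows(a), Xt.rows(b)])
        return (feats @ head["W_c1"] + head["b_c1"]).relu() @ head["W_c2"] + head["b_c2"]

    logits = score(i, j) + score(j, i)
    return (logits if isinstance(X, Tensor) else logits.data), edges


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Numerically stable mean binary cross-entropy on raw logits."""
    y = np.asarray(targets, dtype=float).reshape(logits.shape)
    ell = logits.data
    val = np.maximum(ell, 0) - ell * y + np.log1p(np.exp(-np.abs(ell)))
    out = Tensor(val.mean(), (logits,))
    sig = 1.0 / (1.0 + np.exp(-ell))
    out.backward_fn = lambda g: (g * (sig - y) / y.size,)
    return out


def predict_topk_cuts(probabilities, edges, k: int) -> frozenset[tuple[int, int]]:
    """Top-k bonds by cut probability; ties broken by sorted edge index."""
    probs = np.asarray(probabilities, dtype=float).ravel()
    if k > len(edges):
        raise ValueError(f"k={k} exceeds number of edges {len(edges)}")
    order = sorted(range(len(edges)), key=lambda e: (-probs[e], edges[e]))
    return frozenset(edges[e] for e in order[:k])
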