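"""Evaluation: AMI, cut precision/recall/F1, cross-validation protocol.

Partition quality is scored with Adjusted Mutual Information between
predicted and annotated bead labels (adjusted for chance under the
permutation model, max normalizer), and with precision/recall/F1 on the
predicted cut-bond set against the annotated one.  Molecules with several
annotations are scored best-of-annotations, separately for AMI and for the
cut metrics.  Dataset evaluation is k-fold cross-validation with
molecule-level folds (all annotations of a molecule travel together).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import adjusted_mutual_info_score

from .graph import MolGraph, Mapping, derive_cuts


def ami(labels_a, labels_b) -> float:
    """Adjusted Mutual Information, max-normalized; 1 iff labelings agree
    up to renaming, ~0 for chance-level agreement."""
    if len(labels_a) != len(labels_b):
        raise ValueError("labelings must have equal length")
    return float(adjusted_mutual_info_score(labels_a, labels_b, average_method="max"))


def cut_prf(pred, truth) -> tuple[float, float, float]:
    """Precision, recall, F1 with cut bonds as the positive class.

    Degenerate-set conventions: empty prediction has precision 0 (flagged
    in the report); an empty truth (K = 1 molecule) gives recall 1 when the
    prediction is also empty, else 0.
    """
    pred, truth = frozenset(pred), frozenset(truth)
    tp = len(pred & truth)
    p = tp / len(pred) if pred else 0.0
    if truth:
        r = tp / len(truth)
    else:
        r = 1.0 if not pred else 0.0
    if not pred and not truth:
        p = 1.0  # nothing to predict, nothing predicted
    f1 = 2 * p * r / (p + r) if p + r > 0 else 0.0
    return p, r, f1


@dataclass
class MoleculeScore:
    """Best-of-annotations scores for one molecule."""

    ami: float
    cut_precision: float
    cut_recall: float
    cut_f1: float
    n_annotations: int = 1
    molecule_id: str | None = None
    fold: int | None = None
    empty_prediction: bool = False


@dataclass
class MetricsReport:
    """Per-molecule rows plus arithmetic-mean aggregates."""

    rows: list[MoleculeScore] = field(default_factory=list)

    def aggregate(self) -> dict[str, float]:
        if not self.rows:
            raise ValueError("empty report")
        return {
            "ami": float(np.mean([r.ami for r in self.rows])),
            "cut_precision": float(np.mean([r.cut_precision for r in self.rows])),
            "cut_recall": float(np.mean([r.cut_recall for r in self.rows])),
            "cut_f1": float(np.mean([r.cut_f1 for r in self.rows])),
            "n_molecules": len(self.rows),
        }


def score_molecule(g: MolGraph, prediction: Mapping, annotations) -> MoleculeScore:
    """Score one prediction against every annotation; keep the best.

    The best AMI and the best cut triple may come from different
    annotations.
    """
    if not annotations:
        raise ValueError("at least one annotation required")
    pred_cuts = derive_cuts(g, prediction)
    best_ami = max(ami(prediction.B, m.B) for m in annotations)
    best_prf = max(
        (cut_prf(pred_cuts, derive_cuts(g, m)) for m in annotations),
        key=lambda t: (t[2], t[0], t[1]),
    )
    return MoleculeScore(
        ami=best_ami,
        cut_precision=best_prf[0],
        cut_recall=best_prf[1],
        cut_f1=best_prf[2],
        n_annotations=len(annotations),
        molecule_id=g.smiles,
        empty_prediction=not pred_cuts,
    )


def kfold_split(n_molecules: int, k: int = 5, seed: int = 0) -> list[np.ndarray]:
    """Disjoint, seeded, near-equal molecule-level folds covering 0..n-1."""
    if not 1 <= k <= n_molecules:
        raise ValueError(f"k={k} must be in [1, {n_molecules}]")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_molecules)
    return [np.sort(perm[i::k]) for i in range(k)]


def evaluate_dataset(make_model, dataset, k: int = 5, seed: int = 0,
                     select_on_test: bool = False) -> MetricsReport:
    """k-fold cross-validation of a mapping predictor.

    ``make_model()`` must return an unfitted estimator with
    ``fit(graphs, annotations)`` and ``predict(graphs, K=...)``;
    ``dataset`` is a list of (MolGraph, [Mapping, ...]).  Each molecule is
    predicted with the bead count of its first annotation and scored
    best-of-annotations; aggregates are means over molecules within a fold,
    then over folds (equivalently reported per-row here with fold ids).

    ``select_on_test=True`` feeds the test fold to ``fit`` as validation
    data for best-epoch selection (a leaky protocol kept only for
    comparison with reports that use it; the default is clean).
    """
    import inspect

    folds = kfold_split(len(dataset), k=k, seed=seed)
    report = MetricsReport()
    for fold_id, test_idx in enumerate(folds):
        test_set = set(test_idx.tolist())
        train = [dataset[i] for i in range(len(dataset)) if i not in test_set]
        test = [dataset[i] for i in test_idx]
        model = make_model()
        fit_kwargs = {}
        if select_on_test and "validation_data" in inspect.signature(model.fit).parameters:
            fit_kwargs["validation_data"] = (
                [g for g, _ in test], [ms for _, ms in test]
            )
        model.fit([g for g, _ in train], [ms for _, ms in train], **fit_kwargs)
        preds = model.predict([g for g, _ in test], K=[ms[0].K for _, ms in test])
        for (g, ms), pred in zip(test, preds):
            row = score_molecule(g, pred, ms)
            row.fold = fold_id
            report.rows.append(row)
    return report


def fold_means(report: MetricsReport) -> dict[str, float]:
    """Average per-molecule scores within each fold, then across folds."""
    folds = sorted({r.fold for r in report.rows})
    per_fold = []
    for f in folds:
        rows = [r for r in report.rows if r.fold == f]
        per_fold.append(MetricsReport(rows=rows).aggregate())
    return {
        key: float(np.mean([pf[key] for pf in per_fold]))
        for key in ("ami", "cut_precision", "cut_recall", "cut_f1")
    }


def human_agreement(dataset) -> MetricsReport:
    """Inter-annotator agreement over same-K annotation pairs.

    For every molecule and every unordered pair of annotations with equal
    bead counts, one annotation is treated as the prediction and the other
    as truth; cut metrics are averaged over both orders (AMI is symmetric).
    """
    report = MetricsReport()
    for g, ms in dataset:
        for i in range(len(ms)):
            for j in range(i + 1, len(ms)):
                if ms[i].K != ms[j].K:
                    continue
                ci, cj = derive_cuts(g, ms[i]), derive_cuts(g, ms[j])
                pij, rij, fij = cut_prf(ci, cj)
                pji, rji, fji = cut_prf(cj, ci)
                report.rows.append(
                    MoleculeScore(
                        ami=ami(ms[i].B, ms[j].B),
                        cut_precision=(pij + pji) / 2,
                        cut_recall=(rij + rji) / 2,
                        cut_f1=(fij + fji) / 2,
                        n_annotations=len(ms),
                        molecule_id=g.smiles,
                    )
                )
    return report
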