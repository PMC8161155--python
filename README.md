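# cgmapper

Supervised prediction of coarse-grained (CG) mappings for small organic
molecules.  A CG mapping assigns every heavy atom of a molecule to one of
`K` beads — the interaction sites of a lower-resolution molecular dynamics
model — with each bead inducing a connected subgraph.  Practitioners
usually pick these mappings by intuition; `cgmapper` learns to reproduce
annotated mappings by treating the task as supervised graph partitioning.

## Method

A message-passing neural network embeds each atom of the molecular graph
(one-hot atom types `V`, bond-typed adjacency `E`, degree `F_d`, cycle
indicator `F_c`) as a unit vector `x̃_u`:

- edge-conditioned messages `H_u = W·X_u + Σ_{v∈N(u)} φᵉ(E_uv)·X_v`
  followed by a GRU update, repeated `T` times;
- readout `x̃_u = normalize( [MLP(X_u^T) | V_u | F_d(u) | F_c(u)] )`.

Training is metric learning on the annotated partition `B`: for every
triplet (anchor, positive, negative) where ⟨a,p⟩ is a within-bead bond and
⟨a,n⟩ a cut bond,

    L = mean max(0, ‖x̃_a−x̃_p‖ − ‖x̃_a−x̃_n‖ + α) + λ · mean ‖x̃_a−x̃_a′‖²

(α = 1, λ = 0.1).  At inference a Gaussian kernel on the bond support,
`A_ij = exp(−‖x̃_i−x̃_j‖²/2σ²)` with σ = 1, feeds spectral clustering into
`K` clusters, and each connected component of each cluster becomes a bead.
The package also ships the adjacency-only spectral baseline, an
edge-classification alternative (per-bond cut probability, top-k cuts),
AMI / cut-precision/recall/F1 evaluation with best-of-annotations scoring,
molecule-level k-fold cross-validation, inter-annotator agreement, and a
synthetic-data generator with planted, rule-based mappings so everything is
trainable and testable without external downloads.  The network and its
training loop run on a small numpy reverse-mode autodiff engine included in
the package; no deep-learning framework is required.

## Worked example

```python
import numpy as np
import cgmapper as cg

spec = cg.SynthSpec(n_molecules=60, seed=42)          # planted-rule corpus
train, test = cg.make_dataset(spec)                   # 48 train / 12 test
model = cg.DSGPM(d=32, T=3, edge_hidden=32, epochs=10, random_state=0)
model.fit([g for g, _ in train], [ms for _, ms in train])

graphs = [g for g, _ in test]
annotations = [ms for _, ms in test]
preds = model.predict(graphs, K=[ms[0].K for ms in annotations])
rows = [cg.score_molecule(g, p, ms) for g, p, ms in zip(graphs, preds, annotations)]
print(f"held-out AMI    {np.mean([r.ami for r in rows]):.3f}")
print(f"held-out cut F1 {np.mean([r.cut_f1 for r in rows]):.3f}")

g = cg.from_smiles("CCOc1ccccc1", model.vocabulary_)  # ethoxybenzene
(pred,) = model.predict([g], K=3)
print("ethoxybenzene beads:", pred.beads())
```

prints

```
held-out AMI    0.752
held-out cut F1 0.903
ethoxybenzene beads: [[0, 1], [2], [3, 4, 5, 6, 7, 8]]
```

The mapping groups the ethyl carbons, isolates the ether oxygen and keeps
the phenyl ring whole — the structure the planted rule encodes (cut bonds
whose endpoints differ in element or ring membership).  AMI scores the
predicted bead labels against the annotation adjusted for chance; cut F1
scores the predicted cut-bond set.  On the same molecules the
adjacency-only spectral baseline (which sees no atom or bond types) reaches
0.355 AMI / 0.608 cut F1, so the learned affinity is what carries the
performance.

The same pipeline is available from the shell:

```
cgmapper generate --n-molecules 250 --seed 1 --out-dir data/
cgmapper train --data data/train.json --checkpoint model.npz
cgmapper predict --checkpoint model.npz --smiles mols.smi --out pred.json
cgmapper evaluate --data data/train.json --method dsgpm --report report.json
```

Annotated datasets are JSON records
`{"smiles": ..., "cgnodes": [[atoms of bead 0], [bead 1], ...]}`; the same
reader ingests externally annotated corpora in that dialect.

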