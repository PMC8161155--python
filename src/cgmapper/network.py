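"""Message-passing network producing unit-norm atom embeddings.

Architecture: a fully-connected layer projects the one-hot atom type into a
(d-2)-dimensional space; degree and cycle indicator are appended to give the
initial state ``X^0`` (n x d).  T rounds of edge-conditioned convolution
(an NNConv-style message ``H_u = W X_u + sum_v phi_e(E_uv) X_v``, where
``phi_e`` is a small MLP mapping the bond-type one-hot to a d x d matrix)
each followed by a GRU cell (message as input, atom state as hidden) yield
``X^T``.  The readout passes ``X^T`` through an MLP, concatenates the raw
inputs ``V, F_d, F_c`` back on, and L2-normalizes each row, so all pairwise
embedding distances lie in [0, 2].
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from ._autodiff import Tensor, concat_cols, normalize_rows
from .graph import MolGraph

CHECKPOINT_VERSION = 1


@dataclass
class ModelConfig:
    """Hyperparameters of the embedding network.

    d is the hidden width (two slots are consumed by the degree and cycle
    features, so d >= 3); T the number of message-passing rounds; q the
    output MLP width (None -> d); edge_hidden the hidden width of the
    bond-type MLP; alpha the triplet margin; lam the pair-loss coefficient;
    sigma the Gaussian-kernel bandwidth.
    """

    d: int = 128
    T: int = 3
    q: int | None = None
    edge_hidden: int = 128
    alpha: float = 1.0
    lam: float = 0.1
    sigma: float = 1.0
    seed: int = 0
    use_degree: bool = True
    use_cycle: bool = True

    def __post_init__(self):
        if self.d < 3:
            raise ValueError("hidden width d must be >= 3")
        if self.T < 1 or (self.q is not None and self.q < 1):
            raise ValueError("T and q must be positive")
        if self.sigma <= 0 or self.alpha < 0:
            raise ValueError("sigma must be positive and alpha nonnegative")

    @property
    def q_out(self) -> int:
        return self.q if self.q is not None else self.d

    def embedding_width(self, n_types: int) -> int:
        """Width q' = q + |Q| + 2 of the final embedding rows."""
        return self.q_out + n_types + 2


def _uniform(rng, fan_in, shape):
    bound = 1.0 / np.sqrt(max(fan_in, 1))
    return Tensor(rng.uniform(-bound, bound, size=shape))


def init_params(cfg: ModelConfig, n_types: int) -> dict[str, Tensor]:
    """Fan-in uniform initialization, reproducible from ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    d, h, q = cfg.d, cfg.edge_hidden, cfg.q_out
    p: dict[str, Tensor] = {}
    p["W_emb"] = _uniform(rng, n_types, (n_types, d - 2))
    p["b_emb"] = _uniform(rng, n_types, (d - 2,))
    # bond-type MLP: {0,1}^4 -> h -> d*d
    p["W_e1"] = _uniform(rng, 4, (4, h))
    p["b_e1"] = _uniform(rng, 4, (h,))
    p["W_e2"] = _uniform(rng, h, (h, d * d))
    p["b_e2"] = _uniform(rng, h, (d * d,))
    # root weight of the edge-conditioned convolution
    p["W_root"] = _uniform(rng, d, (d, d))
    p["b_root"] = _uniform(rng, d, (d,))
    # GRU (input = message H, hidden = atom state X)
    for gate in ("r", "z", "n"):
        p[f"W_i{gate}"] = _uniform(rng, d, (d, d))
        p[f"W_h{gate}"] = _uniform(rng, d, (d, d))
        p[f"b_i{gate}"] = _uniform(rng, d, (d,))
        p[f"b_h{gate}"] = _uniform(rng, d, (d,))
    # output MLP d -> d -> q
    p["W_m1"] = _uniform(rng, d, (d, d))
    p["b_m1"] = _uniform(rng, d, (d,))
    p["W_m2"] = _uniform(rng, d, (d, q))
    p["b_m2"] = _uniform(rng, d, (q,))
    return p


def _input_columns(g: MolGraph, cfg: ModelConfig):
    """Constant per-atom feature columns (ablations zero, not drop, them)."""
    fd = g.F_d[:, None] if cfg.use_degree else np.zeros((g.n, 1))
    fc = g.F_c[:, None] if cfg.use_cycle else np.zeros((g.n, 1))
    return Tensor(g.atom_type), Tensor(fd), Tensor(fc)


def initial_features(g: MolGraph, params, cfg: ModelConfig) -> Tensor:
    """X^0: projected atom type with degree and cycle columns appended."""
    V, fd, fc = _input_columns(g, cfg)
    if g.atom_type.shape[1] != params["W_emb"].shape[0]:
        raise ValueError(
            f"graph vocabulary size {g.atom_type.shape[1]} does not match "
            f"model ({params['W_emb'].shape[0]})"
        )
    return concat_cols([V @ params["W_emb"] + params["b_emb"], fd, fc])


def _edge_matrices(params, cfg: ModelConfig) -> list[Tensor]:
    """phi_e evaluated at the 4 canonical bond one-hots -> four d x d maps."""
    eye = Tensor(np.eye(4))
    hidden = (eye @ params["W_e1"] + params["b_e1"]).relu()
    theta = hidden @ params["W_e2"] + params["b_e2"]
    d = cfg.d
    return [theta.rows([b]).reshape(d, d) for b in range(4)]


def message_pass(X: Tensor, g: MolGraph, params, cfg: ModelConfig, edge_mats=None) -> Tensor:
    """One synchronous message-passing round (NNConv message + GRU update)."""
    if X.shape != (g.n, cfg.d):
        raise ValueError(f"state shape {X.shape} != {(g.n, cfg.d)}")
    if edge_mats is None:
        edge_mats = _edge_matrices(params, cfg)
    H = X @ params["W_root"] + params["b_root"]
    for b in range(4):
        A_b = g.E[:, :, b]
        if A_b.any():
            H = H + Tensor(A_b) @ (X @ edge_mats[b])
    r = (H @ params["W_ir"] + params["b_ir"] + X @ params["W_hr"] + params["b_hr"]).sigmoid()
    z = (H @ params["W_iz"] + params["b_iz"] + X @ params["W_hz"] + params["b_hz"]).sigmoid()
    n = (H @ params["W_in"] + params["b_in"] + r * (X @ params["W_hn"] + params["b_hn"])).tanh()
    return (1.0 - z) * n + z * X


def readout(X: Tensor, g: MolGraph, params, cfg: ModelConfig) -> Tensor:
    """MLP(X^T) ++ V ++ F_d ++ F_c, then row-wise L2 normalization."""
    V, fd, fc = _input_columns(g, cfg)
    hidden = (X @ params["W_m1"] + params["b_m1"]).relu()
    out = hidden @ params["W_m2"] + params["b_m2"]
    return normalize_rows(concat_cols([out, V, fd, fc]))


def forward(g: MolGraph, params, cfg: ModelConfig) -> Tensor:
    """Full embedding pass; deterministic given parameters and the graph."""
    X = initial_features(g, params, cfg)
    edge_mats = _edge_matrices(params, cfg)
    for _ in range(cfg.T):
        X = message_pass(X, g, params, cfg, edge_mats)
    return readout(X, g, params, cfg)


def embed(g: MolGraph, params, cfg: ModelConfig) -> np.ndarray:
    """Forward pass returning a plain (n, q') numpy array of unit rows."""
    return forward(g, params, cfg).data


# ---------------------------------------------------------------------------
# checkpoints

def save_checkpoint(path, params, cfg: ModelConfig, vocabulary, extra=None) -> None:
    meta = {
        "version": CHECKPOINT_VERSION,
        "config": asdict(cfg),
        "vocabulary": list(vocabulary),
        "extra": extra or {},
    }
    arrays = {k: p.data for k, p in params.items()}
    np.savez(path, __meta__=np.array(json.dumps(meta)), **arrays)


def load_checkpoint(path):
    """Returns (params, config, vocabulary, extra); bit-exact round-trip."""
    with np.load(path, allow_pickle=False) as npz:
        meta = json.loads(str(npz["__meta__"]))
        if meta["version"] != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta['version']}")
        params = {k: Tensor(npz[k]) for k in npz.files if k != "__meta__"}
    cfg = ModelConfig(**meta["config"])
    return params, cfg, tuple(meta["vocabulary"]), meta["extra"]
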