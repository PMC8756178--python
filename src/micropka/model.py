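"""Graph-attention message-passing network with a per-atom pKa head.

Six attention layers (in the Attentive FP family) refine per-atom states:
each layer scores every directed edge with a leaky-ReLU attention logit,
normalizes the scores over each atom's in-neighborhood with a softmax,
aggregates the attended neighbor messages, and feeds the context into a
gated recurrent (GRU) update of the atom state.  There is deliberately no
molecule-level readout: the final atom states go straight into a small
fully connected head that emits one raw pKa per atom.  Masking and pooling
into macro-pKa live in :mod:`micropka.pooling` / :mod:`micropka.mil`.

The network, its initialization and its training run entirely on NumPy via
the reverse-mode engine in :mod:`micropka.autodiff`; deterministic mode
(dropout off, fixed seed) is bitwise reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from .autodiff import Tensor, constant
from .chemgraph import FeatureConfig, MoleculeGraph

__all__ = [
    "ModelConfig",
    "ModelState",
    "AtomEmbeddingMatrix",
    "BatchedGraphs",
    "init_model",
    "atom_embeddings",
    "atom_pka_head",
    "predict_micro",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and reproducibility knobs.

    ``n_layers`` defaults to the six stacked attention layers of the
    reference architecture; ``mode`` selects which macro label the model is
    trained against and which mask sign applies downstream.
    """

    n_layers: int = 6
    hidden_dim: int = 200
    dropout_rate: float = 0.1
    head_hidden_dims: tuple = (128,)
    mode: str = "acidic"
    seed: int = 0

    def __post_init__(self):
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.hidden_dim < 1 or any(d < 1 for d in self.head_hidden_dims):
            raise ValueError("hidden dimensions must be positive")
        if self.mode not in ("acidic", "basic"):
            raise ValueError("mode must be 'acidic' or 'basic'")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["head_hidden_dims"] = list(self.head_hidden_dims)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["head_hidden_dims"] = tuple(d["head_hidden_dims"])
        return cls(**d)


@dataclass
class ModelState:
    """Parameters plus the configs they were built for."""

    params: dict
    config: ModelConfig
    feature_config: FeatureConfig
    training_meta: dict = field(default_factory=dict)

    def parameter_list(self) -> list[Tensor]:
        return list(self.params.values())

    def fingerprint(self) -> str:
        """Hash of architecture + parameters, for stale-index detection."""
        h = hashlib.sha256()
        h.update(json.dumps(self.config.to_dict(), sort_keys=True).encode())
        h.update(json.dumps(self.feature_config.to_dict(), sort_keys=True).encode())
        for name in sorted(self.params):
            h.update(name.encode())
            h.update(np.ascontiguousarray(self.params[name].data).tobytes())
        return h.hexdigest()


@dataclass
class AtomEmbeddingMatrix:
    """Per-atom vectors aligned to graph atom order.

    ``last_hidden`` marks these as final-layer states, the representation
    used by the similarity search and the PCA export.
    """

    vectors: np.ndarray
    last_hidden: bool = True


# ---------------------------------------------------------------------------
# batching


class BatchedGraphs:
    """A disjoint union of molecule graphs flattened to edge lists.

    Atoms of molecule k occupy the contiguous index range
    ``[offsets[k], offsets[k+1])``; every undirected bond contributes two
    directed edges so each atom attends over its full neighborhood.
    """

    def __init__(self, graphs: Sequence[MoleculeGraph]):
        xs, srcs, dsts, efeats, mol_ids = [], [], [], [], []
        offsets = [0]
        for k, g in enumerate(graphs):
            off = offsets[-1]
            xs.append(g.atom_features)
            mol_ids.append(np.full(g.n_atoms, k, dtype=np.int64))
            for (a, b), bf in zip(g.bonds, g.bond_features):
                srcs += [off + a, off + b]
                dsts += [off + b, off + a]
                efeats += [bf, bf]
            offsets.append(off + g.n_atoms)
        self.n_mols = len(graphs)
        self.offsets = np.asarray(offsets, dtype=np.int64)
        self.atom_mol = np.concatenate(mol_ids) if mol_ids else np.zeros(0, np.int64)
        self.X = np.concatenate(xs, axis=0) if xs else np.zeros((0, 0))
        self.edge_src = np.asarray(srcs, dtype=np.int64)
        self.edge_dst = np.asarray(dsts, dtype=np.int64)
        bond_dim = graphs[0].bond_features.shape[1] if graphs else 0
        self.edge_feat = (
            np.vstack(efeats) if efeats else np.zeros((0, bond_dim))
        )

    @property
    def n_atoms(self) -> int:
        return int(self.offsets[-1])


# ---------------------------------------------------------------------------
# initialization


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> Tensor:
    s = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-s, s, size=(fan_in, fan_out)), requires_grad=True)


def _zeros(*shape) -> Tensor:
    return Tensor(np.zeros(shape), requires_grad=True)


def init_model(config: ModelConfig, feature_config: FeatureConfig | None = None) -> ModelState:
    """Initialize all parameters from ``config.seed`` (Glorot uniform)."""
    fc = feature_config or FeatureConfig()
    rng = np.random.default_rng(config.seed)
    H, fa, fb = config.hidden_dim, fc.atom_dim, fc.bond_dim
    p: dict[str, Tensor] = {
        "W_in": _glorot(rng, fa, H),
        "b_in": _zeros(1, H),
    }
    for l in range(config.n_layers):
        p[f"L{l}.W_msg"] = _glorot(rng, H, H)
        p[f"L{l}.W_bond"] = _glorot(rng, fb, H)
        p[f"L{l}.A_dst"] = _glorot(rng, H, H)
        p[f"L{l}.A_src"] = _glorot(rng, H, H)
        p[f"L{l}.b_att"] = _zeros(1, H)
        p[f"L{l}.u_att"] = _glorot(rng, H, 1)
        for gate in ("z", "r", "n"):
            p[f"L{l}.W{gate}"] = _glorot(rng, H, H)
            p[f"L{l}.U{gate}"] = _glorot(rng, H, H)
            p[f"L{l}.b{gate}"] = _zeros(1, H)
    dims = [H] + list(config.head_hidden_dims) + [1]
    for i, (a, b) in enumerate(zip(dims[:-1], dims[1:])):
        p[f"head.W{i}"] = _glorot(rng, a, b)
        p[f"head.b{i}"] = _zeros(1, b)
    return ModelState(params=p, config=config, feature_config=fc)


# ---------------------------------------------------------------------------
# forward pass


def _gru(p: dict, l: int, ctx: Tensor, h: Tensor) -> Tensor:
    z = (ctx @ p[f"L{l}.Wz"] + h @ p[f"L{l}.Uz"] + p[f"L{l}.bz"]).sigmoid()
    r = (ctx @ p[f"L{l}.Wr"] + h @ p[f"L{l}.Ur"] + p[f"L{l}.br"]).sigmoid()
    n = (ctx @ p[f"L{l}.Wn"] + (r * (h @ p[f"L{l}.Un"])) + p[f"L{l}.bn"]).tanh()
    one_minus_z = z.scale(-1.0).shift(1.0)
    return one_minus_z * n + z * h


def forward_batch(
    state: ModelState,
    batch: BatchedGraphs,
    dropout_active: bool = False,
    rng: Optional[np.random.Generator] = None,
    collect_attention: bool = False,
):
    """Run the network on a batched graph.

    Returns ``(embeddings, raw_pka, attention)`` where ``embeddings`` is the
    (n_atoms, hidden) final-layer state tensor, ``raw_pka`` the (n_atoms, 1)
    unmasked per-atom prediction, and ``attention`` a per-layer list of
    per-edge weights (only when ``collect_attention``).
    """
    p = state.params
    cfg = state.config
    if batch.X.shape[1] != state.feature_config.atom_dim:
        raise ValueError(
            f"feature length {batch.X.shape[1]} does not match schema "
            f"({state.feature_config.atom_dim})"
        )
    if dropout_active and rng is None:
        rng = np.random.default_rng(cfg.seed)
    rate = cfg.dropout_rate if dropout_active else 0.0

    h = (constant(batch.X) @ p["W_in"] + p["b_in"]).leaky_relu()
    src, dst = batch.edge_src, batch.edge_dst
    efeat = constant(batch.edge_feat)
    has_edges = src.size > 0
    attention = []
    for l in range(cfg.n_layers):
        if has_edges:
            hs = h.gather(src)
            hd = h.gather(dst)
            msg = hs @ p[f"L{l}.W_msg"] + efeat @ p[f"L{l}.W_bond"]
            t = (hd @ p[f"L{l}.A_dst"] + hs @ p[f"L{l}.A_src"] + p[f"L{l}.b_att"]).leaky_relu()
            score = t @ p[f"L{l}.u_att"]
            alpha = score.segment_softmax(dst, batch.n_atoms)
            if collect_attention:
                attention.append(alpha.data.copy())
            ctx = (alpha * msg).segment_sum(dst, batch.n_atoms).elu()
        else:
            ctx = constant(np.zeros_like(h.data))
        h = _gru(p, l, ctx, h)
        if rate > 0.0:
            h = h.dropout(rate, rng)

    y = h
    n_head = len(cfg.head_hidden_dims) + 1
    for i in range(n_head):
        y = y @ p[f"head.W{i}"] + p[f"head.b{i}"]
        if i < n_head - 1:
            y = y.leaky_relu()
            if rate > 0.0:
                y = y.dropout(rate, rng)
    return h, y, attention


def atom_embeddings(
    state: ModelState,
    graph: MoleculeGraph,
    dropout_active: bool = False,
    rng: Optional[np.random.Generator] = None,
) -> AtomEmbeddingMatrix:
    """Final-layer per-atom embeddings for a single molecule."""
    batch = BatchedGraphs([graph])
    h, _, _ = forward_batch(state, batch, dropout_active=dropout_active, rng=rng)
    return AtomEmbeddingMatrix(vectors=h.data.copy(), last_hidden=True)


def atom_pka_head(state: ModelState, embeddings: AtomEmbeddingMatrix) -> np.ndarray:
    """Map per-atom embeddings through the fully connected head.

    Returns the raw (unmasked) per-atom pKa vector of length N.
    """
    y = constant(embeddings.vectors)
    p = state.params
    n_head = len(state.config.head_hidden_dims) + 1
    for i in range(n_head):
        y = y @ p[f"head.W{i}"] + p[f"head.b{i}"]
        if i < n_head - 1:
            y = y.leaky_relu()
    return y.data[:, 0].copy()


def predict_micro(
    state: ModelState,
    graph: MoleculeGraph,
    dropout_active: bool = False,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Raw per-atom pKa predictions (no masking) for one molecule."""
    batch = BatchedGraphs([graph])
    _, y, _ = forward_batch(state, batch, dropout_active=dropout_active, rng=rng)
    return y.data[:, 0].copy()


# ---------------------------------------------------------------------------
# checkpoint I/O


def save_checkpoint(state: ModelState, path: str) -> None:
    """Bundle parameters + ModelConfig + FeatureConfig into one file."""
    meta = json.dumps(
        {
            "model_config": state.config.to_dict(),
            "feature_config": state.feature_config.to_dict(),
            "training_meta": state.training_meta,
            "format_version": 1,
        }
    )
    arrays = {f"param/{k}": v.data for k, v in state.params.items()}
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str, feature_config: FeatureConfig | None = None) -> ModelState:
    """Load a checkpoint; a mismatched FeatureConfig is an error."""
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        params = {
            k[len("param/"):]: Tensor(z[k], requires_grad=True)
            for k in z.files
            if k.startswith("param/")
        }
    cfg = ModelConfig.from_dict(meta["model_config"])
    fc = FeatureConfig.from_dict(meta["feature_config"])
    if feature_config is not None and feature_config.to_dict() != fc.to_dict():
        raise ValueError("checkpoint feature schema does not match the requested one")
    return ModelState(params=params, config=cfg, feature_config=fc, training_meta=meta["training_meta"])
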