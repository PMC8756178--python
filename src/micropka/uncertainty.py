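"""Prediction uncertainty, embedding similarity search, and PCA export.

Uncertainty comes from Monte-Carlo dropout: the trained network is run with
dropout left active, and the empirical 2.5/97.5 percentiles of the pooled
macro-pKa across samples form a 95% interval.  The similarity search
compares molecules by the final-layer embedding of their dominant ionizable
atom: reference molecules whose embedding lies within a small Euclidean
distance of the query's are returned (nearest first, at most four) together
with their experimental pKa.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .chemgraph import MoleculeGraph, MoleculeRecord, build_graph, sites_for_mode
from .model import BatchedGraphs, ModelState, forward_batch
from .pooling import pool_values
from .training import NoSiteError, dominant_sites

__all__ = [
    "UncertainPrediction",
    "EmbeddingIndex",
    "mc_dropout_predict",
    "build_embedding_index",
    "similar_molecules",
    "project_embeddings",
    "DISTANCE_THRESHOLD",
    "MAX_NEIGHBORS",
]

log = logging.getLogger(__name__)

#: Euclidean distance below which two dominant-atom embeddings count as similar.
DISTANCE_THRESHOLD = 0.05
#: Maximum number of similar molecules returned per query.
MAX_NEIGHBORS = 4


@dataclass
class UncertainPrediction:
    """Macro-pKa with an empirical 95% interval from MC-dropout samples."""

    macro_mean: float
    ci_low: float
    ci_high: float
    n_samples: int
    samples: Optional[np.ndarray] = None


def mc_dropout_predict(
    state: ModelState,
    graph: MoleculeGraph,
    mode: Optional[str] = None,
    n_samples: int = 100,
    seed: int = 0,
    keep_samples: bool = False,
) -> UncertainPrediction:
    """``n_samples`` stochastic forward passes with dropout active.

    Returns the sample mean and percentile 95% interval of the pooled macro
    value; reproducible for a fixed seed.  With ``dropout_rate == 0`` every
    pass is identical and the interval degenerates to a point (warned).
    """
    mode = mode or state.config.mode
    sites = sorted(sites_for_mode(graph, mode))
    if not sites:
        raise NoSiteError(f"molecule {graph.smiles!r} has no {mode} site")
    if state.config.dropout_rate == 0.0:
        warnings.warn("dropout_rate is 0; MC-dropout interval is degenerate")
    rng = np.random.default_rng(seed)
    batch = BatchedGraphs([graph])
    vals = np.empty(n_samples)
    for k in range(n_samples):
        _, y, _ = forward_batch(state, batch, dropout_active=state.config.dropout_rate > 0, rng=rng)
        vals[k] = pool_values(y.data[sites, 0], mode)
    if np.all(vals == vals[0]):  # no stochasticity: exactly degenerate
        mean = lo = hi = float(vals[0])
    else:
        mean = float(vals.mean())
        lo = float(np.percentile(vals, 2.5))
        hi = float(np.percentile(vals, 97.5))
        # empirical percentiles can exclude the mean for tiny/skewed samples
        lo, hi = min(lo, mean), max(hi, mean)
    return UncertainPrediction(
        macro_mean=mean, ci_low=lo, ci_high=hi, n_samples=n_samples,
        samples=vals if keep_samples else None,
    )


# ---------------------------------------------------------------------------
# embedding index


@dataclass
class EmbeddingIndex:
    """Reference set of dominant-atom embeddings with experimental pKa.

    One entry per (record, mode), keyed to the first dominant site in atom
    index order; ``model_fingerprint`` ties the index to the exact model
    that produced it.
    """

    record_ids: list
    atom_indices: np.ndarray
    embeddings: np.ndarray
    experimental_pka: np.ndarray
    mode: str
    model_fingerprint: str

    def __len__(self) -> int:
        return len(self.record_ids)

    def save(self, path: str) -> None:
        meta = json.dumps({
            "record_ids": self.record_ids,
            "mode": self.mode,
            "model_fingerprint": self.model_fingerprint,
        })
        np.savez(
            path,
            __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
            atom_indices=self.atom_indices,
            embeddings=self.embeddings,
            experimental_pka=self.experimental_pka,
        )

    @classmethod
    def load(cls, path: str) -> "EmbeddingIndex":
        with np.load(path) as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            return cls(
                record_ids=meta["record_ids"],
                atom_indices=z["atom_indices"],
                embeddings=z["embeddings"],
                experimental_pka=z["experimental_pka"],
                mode=meta["mode"],
                model_fingerprint=meta["model_fingerprint"],
            )


def _dominant_embedding(state: ModelState, graph: MoleculeGraph, mode: str) -> tuple[int, np.ndarray]:
    assign = dominant_sites(state, graph, mode)
    atom = min(assign.G)  # first dominant site in atom-index order
    h, _, _ = forward_batch(state, BatchedGraphs([graph]))
    return atom, h.data[atom].copy()


def build_embedding_index(
    state: ModelState,
    records: Sequence[MoleculeRecord],
    mode: Optional[str] = None,
) -> EmbeddingIndex:
    """Predict each record's dominant site and store its embedding.

    Records with no site of the mode are skipped with a warning.
    """
    mode = mode or state.config.mode
    ids, atoms, vecs, pkas = [], [], [], []
    for rec in records:
        graph = build_graph(rec.standardized_smiles, state.feature_config)
        try:
            atom, vec = _dominant_embedding(state, graph, mode)
        except NoSiteError:
            log.warning("record %s has no %s site; not indexed", rec.record_id, mode)
            continue
        ids.append(rec.record_id)
        atoms.append(atom)
        vecs.append(vec)
        label = rec.label(mode)
        pkas.append(np.nan if label is None else float(label))
    return EmbeddingIndex(
        record_ids=ids,
        atom_indices=np.asarray(atoms, dtype=np.int64),
        embeddings=np.vstack(vecs) if vecs else np.zeros((0, state.config.hidden_dim)),
        experimental_pka=np.asarray(pkas),
        mode=mode,
        model_fingerprint=state.fingerprint(),
    )


def similar_molecules(
    index: EmbeddingIndex,
    state: ModelState,
    query: MoleculeGraph,
    mode: Optional[str] = None,
    threshold: float = DISTANCE_THRESHOLD,
    max_neighbors: int = MAX_NEIGHBORS,
) -> list[dict]:
    """Index entries whose dominant-atom embedding is within ``threshold``.

    Euclidean distance, nearest first, truncated to ``max_neighbors``.
    An empty result is a valid outcome, not an error; querying with a model
    other than the one that built the index is a stale-index error.
    """
    mode = mode or state.config.mode
    if index.model_fingerprint != state.fingerprint():
        raise ValueError("stale index: built by a different model/configuration")
    if index.mode != mode:
        raise ValueError(f"index mode {index.mode!r} does not match query mode {mode!r}")
    _, qvec = _dominant_embedding(state, query, mode)
    if len(index) == 0:
        return []
    d = np.linalg.norm(index.embeddings - qvec[None, :], axis=1)
    hits = np.where(d < threshold)[0]
    hits = hits[np.argsort(d[hits], kind="stable")][:max_neighbors]
    return [
        {
            "record_id": index.record_ids[i],
            "distance": float(d[i]),
            "experimental_pka": float(index.experimental_pka[i]),
            "atom_index": int(index.atom_indices[i]),
        }
        for i in hits
    ]


# ---------------------------------------------------------------------------
# PCA export


def project_embeddings(embeddings: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Top-2 principal components of mean-centered embeddings.

    Returns (coordinates (n, 2), explained-variance fractions (2,)).
    Component signs are fixed by making each component's largest-magnitude
    loading positive, so the projection is fully deterministic.  Constant
    (rank-0) input is an error.
    """
    X = np.asarray(embeddings, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 embedding vectors")
    Xc = X - X.mean(axis=0)
    total_var = float((Xc ** 2).sum())
    if total_var == 0.0:
        raise ValueError("rank-0 input: all embeddings identical")
    # economical SVD; components are rows of Vt
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = min(2, S.size)
    comps = Vt[:k]
    for j in range(k):
        i = int(np.argmax(np.abs(comps[j])))
        if comps[j, i] < 0:
            comps[j] = -comps[j]
    coords = Xc @ comps.T
    frac = (S[:k] ** 2) / total_var
    if k < 2:  # single feature dimension: pad a zero second axis
        coords = np.hstack([coords, np.zeros((X.shape[0], 1))])
        frac = np.append(frac, 0.0)
    return coords, frac
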