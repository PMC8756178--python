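"""Training against macro labels and the evaluation suite.

The model never sees a per-atom label: the loss is the mean squared error
between the *pooled* macro prediction and the molecule's macro label, so
all per-atom learning signal is routed through the pooling gradient (the
softmin/softmax weight of each site).  Evaluation covers standard
regression metrics, applicability-domain analysis by maximum Tanimoto
similarity to the training set, and the dominant-site consistency metrics
used to compare the model's site assignments with an expert's.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator
from sklearn.metrics import mean_absolute_error, mean_squared_error, r2_score

from .autodiff import Tensor
from .chemgraph import FeatureConfig, MoleculeGraph, MoleculeRecord, build_graph, sites_for_mode
from .model import BatchedGraphs, ModelState, forward_batch
from .pooling import pool_values

__all__ = [
    "DatasetSplit",
    "TrainRunConfig",
    "EvalReport",
    "DominantSiteAssignment",
    "ConsistencyReport",
    "split_dataset",
    "train",
    "predict_macro",
    "compute_regression_metrics",
    "max_similarity_bins",
    "dominant_sites",
    "consistency_rate",
    "difference_value",
    "aggregate_runs",
]

log = logging.getLogger(__name__)

_LN10 = np.log(10.0)


# ---------------------------------------------------------------------------
# splitting


@dataclass
class DatasetSplit:
    train: list
    validation: list
    test: list
    ratios: tuple
    seed: int


def split_dataset(
    records: Sequence[MoleculeRecord],
    ratios: tuple = (0.70, 0.15, 0.15),
    seed: int = 0,
) -> DatasetSplit:
    """Uniform random 70:15:15 partition, deterministic per seed.

    Subset sizes follow the largest-remainder rule: floor each quota, then
    hand the leftover records to the subsets with the largest fractional
    remainders (ties go to the earlier subset).
    """
    if len(records) < 3:
        raise ValueError("need at least 3 records to split")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"ratios must sum to 1, got {ratios}")
    n = len(records)
    quotas = [r * n for r in ratios]
    sizes = [int(np.floor(q)) for q in quotas]
    remainders = [q - s for q, s in zip(quotas, sizes)]
    for _ in range(n - sum(sizes)):
        i = int(np.argmax(remainders))
        sizes[i] += 1
        remainders[i] = -1.0
    perm = np.random.default_rng(seed).permutation(n)
    shuffled = [records[i] for i in perm]
    a, b = sizes[0], sizes[0] + sizes[1]
    return DatasetSplit(
        train=shuffled[:a],
        validation=shuffled[a:b],
        test=shuffled[b:],
        ratios=tuple(ratios),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# training


@dataclass
class TrainRunConfig:
    """Optimizer and schedule knobs for one training run."""

    learning_rate: float = 3e-3
    batch_size: int = 128
    max_epochs: int = 500
    patience: int = 30
    seed: int = 0
    grad_clip: float = 5.0
    lr_decay: float = 0.5          # multiplier applied when validation stalls
    lr_decay_patience: int = 10
    min_learning_rate: float = 1e-4


class _Adam:
    def __init__(self, params: list[Tensor], lr: float):
        self.params = params
        self.lr = lr
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self, clip: float) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        gnorm = np.sqrt(sum(float((p.grad ** 2).sum()) for p in self.params if p.grad is not None))
        scale = min(1.0, clip / (gnorm + 1e-12)) if clip > 0 else 1.0
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad * scale
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mh = self.m[i] / (1 - b1 ** self.t)
            vh = self.v[i] / (1 - b2 ** self.t)
            p.data -= self.lr * mh / (np.sqrt(vh) + eps)
            p.zero_grad()


@dataclass
class _PreparedSet:
    graphs: list
    site_lists: list      # sorted site indices per molecule
    labels: np.ndarray
    records: list


def _prepare(records: Sequence[MoleculeRecord], mode: str, config: FeatureConfig) -> _PreparedSet:
    graphs, sites, labels, kept = [], [], [], []
    for rec in records:
        y = rec.label(mode)
        if y is None or not np.isfinite(y):
            log.warning("record %s has no finite %s label; excluded", rec.record_id, mode)
            continue
        g = build_graph(rec.standardized_smiles, config)
        s = sorted(sites_for_mode(g, mode))
        if not s:
            log.warning("record %s has no %s site; excluded from training", rec.record_id, mode)
            continue
        graphs.append(g)
        sites.append(s)
        labels.append(float(y))
        kept.append(rec)
    return _PreparedSet(graphs, sites, np.asarray(labels), kept)


def _macro_tensor(state: ModelState, prep: _PreparedSet, idx: np.ndarray,
                  dropout_active: bool = False, rng=None) -> Tensor:
    """Pooled macro predictions for molecules ``idx`` as one tensor."""
    graphs = [prep.graphs[i] for i in idx]
    batch = BatchedGraphs(graphs)
    _, y, _ = forward_batch(state, batch, dropout_active=dropout_active, rng=rng)
    site_global, site_mol = [], []
    for k, i in enumerate(idx):
        off = batch.offsets[k]
        for s in prep.site_lists[i]:
            site_global.append(off + s)
            site_mol.append(k)
    site_global = np.asarray(site_global, dtype=np.int64)
    site_mol = np.asarray(site_mol, dtype=np.int64)
    micro = y.gather(site_global)
    mode = state.config.mode
    if mode == "acidic":
        lse = micro.scale(-_LN10).segment_logsumexp(site_mol, len(idx))
        return lse.scale(-1.0 / _LN10)
    lse = micro.scale(_LN10).segment_logsumexp(site_mol, len(idx))
    return lse.scale(1.0 / _LN10)


def train(
    state: ModelState,
    split: DatasetSplit,
    run_config: Optional[TrainRunConfig] = None,
) -> tuple[ModelState, dict]:
    """Minimize MSE between pooled macro predictions and macro labels.

    Early-stops on validation MAE with the configured patience and returns
    the best-validation parameters.  Records without a finite label or
    without any site of the model's mode are excluded with a warning.
    Reproducible: the run seed drives shuffling and dropout.
    """
    rc = run_config or TrainRunConfig()
    mode = state.config.mode
    prep_tr = _prepare(split.train, mode, state.feature_config)
    prep_va = _prepare(split.validation, mode, state.feature_config)
    if not prep_tr.graphs:
        raise ValueError("empty training set after exclusions")
    rng = np.random.default_rng(rc.seed)
    params = state.parameter_list()
    opt = _Adam(params, rc.learning_rate)
    n = len(prep_tr.graphs)
    va_idx = np.arange(len(prep_va.graphs))

    history = {"train_loss": [], "val_mae": []}
    best = {"val": np.inf, "epoch": -1, "params": None}
    stall = 0
    for epoch in range(rc.max_epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, rc.batch_size):
            idx = order[start:start + rc.batch_size]
            macro = _macro_tensor(state, prep_tr, idx, dropout_active=state.config.dropout_rate > 0, rng=rng)
            target = Tensor(prep_tr.labels[idx][:, None])
            loss = (macro - target).square().mean()
            loss.backward()
            losses.append(float(loss.data))
            if rc.learning_rate > 0:
                opt.step(rc.grad_clip)
            else:
                for p in params:
                    p.zero_grad()
        train_loss = float(np.mean(losses))
        if len(va_idx):
            va_pred = _macro_tensor(state, prep_va, va_idx).data[:, 0]
            val_mae = float(np.mean(np.abs(va_pred - prep_va.labels)))
        else:
            val_mae = train_loss
        history["train_loss"].append(train_loss)
        history["val_mae"].append(val_mae)
        log.info("epoch %d train_loss %.4f val_mae %.4f", epoch, train_loss, val_mae)

        if val_mae < best["val"] - 1e-6:
            best.update(val=val_mae, epoch=epoch,
                        params={k: v.data.copy() for k, v in state.params.items()})
            stall = 0
        else:
            stall += 1
            if stall % rc.lr_decay_patience == 0 and opt.lr > rc.min_learning_rate:
                opt.lr = max(opt.lr * rc.lr_decay, rc.min_learning_rate)
            if stall >= rc.patience:
                break

    if best["params"] is not None:
        for k, v in best["params"].items():
            state.params[k].data = v
    state.training_meta = {"epochs": len(history["train_loss"]),
                           "best_epoch": best["epoch"],
                           "best_val_mae": best["val"] if np.isfinite(best["val"]) else None}
    return state, history


def predict_macro(state: ModelState, graphs: Sequence[MoleculeGraph]) -> list:
    """Pooled macro prediction per molecule; None where the mode has no site."""
    mode = state.config.mode
    out = []
    for g in graphs:
        sites = sorted(sites_for_mode(g, mode))
        if not sites:
            out.append(None)
            continue
        batch = BatchedGraphs([g])
        _, y, _ = forward_batch(state, batch)
        out.append(pool_values(y.data[sites, 0], mode))
    return out


# ---------------------------------------------------------------------------
# metrics


@dataclass
class EvalReport:
    mae: float
    rmse: float
    r2: Optional[float]
    n: int
    r2_undefined: bool = False
    per_bin_mae: Optional[list] = None
    runs: Optional[dict] = None


def compute_regression_metrics(predictions: Sequence[float], truths: Sequence[float]) -> EvalReport:
    """MAE, RMSE and coefficient of determination R^2 = 1 - SS_res/SS_tot.

    R^2 is flagged undefined when fewer than two samples are given or the
    truths are constant (SS_tot = 0).
    """
    p = np.asarray(predictions, dtype=float)
    t = np.asarray(truths, dtype=float)
    if p.shape != t.shape:
        raise ValueError("predictions and truths must have equal length")
    mae = float(mean_absolute_error(t, p))
    rmse = float(np.sqrt(mean_squared_error(t, p)))
    ss_tot = float(((t - t.mean()) ** 2).sum())
    if len(t) < 2 or ss_tot == 0.0:
        return EvalReport(mae=mae, rmse=rmse, r2=None, n=len(t), r2_undefined=True)
    return EvalReport(mae=mae, rmse=rmse, r2=float(r2_score(t, p)), n=len(t))


def aggregate_runs(reports: Sequence[EvalReport]) -> dict:
    """Mean and sample standard deviation over independent runs."""
    out = {}
    for name in ("mae", "rmse", "r2"):
        vals = [getattr(r, name) for r in reports if getattr(r, name) is not None]
        if vals:
            out[name] = {"mean": float(np.mean(vals)),
                         "std": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0}
    out["runs"] = [{"mae": r.mae, "rmse": r.rmse, "r2": r.r2} for r in reports]
    return out


# ---------------------------------------------------------------------------
# applicability domain: max-similarity binning


_MORGAN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=1024)

DEFAULT_BIN_EDGES = (0.0, 0.3, 0.4, 0.5, 0.6, 1.0)


def _fingerprint(smiles: str):
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"cannot fingerprint {smiles!r}")
    return _MORGAN.GetFingerprint(mol)


def max_similarity_bins(
    test_records: Sequence[MoleculeRecord],
    train_records: Sequence[MoleculeRecord],
    bin_edges: Sequence[float] = DEFAULT_BIN_EDGES,
    predictions: Optional[Sequence[float]] = None,
    truths: Optional[Sequence[float]] = None,
) -> tuple[np.ndarray, list]:
    """Assign each test molecule its max Tanimoto similarity to the train set.

    Similarity uses 1024-bit radius-2 circular (Morgan) fingerprints.  Bins
    are right-open except the last, which is closed at 1.0.  When aligned
    predictions/truths are supplied, a per-bin MAE table is computed.

    Returns ``(max_sims, table)`` where ``table`` rows are dicts with the
    bin interval, n, and (if available) the bin MAE.
    """
    if not train_records:
        raise ValueError("empty training set")
    train_fps = [_fingerprint(r.standardized_smiles) for r in train_records]
    sims = np.empty(len(test_records))
    for i, rec in enumerate(test_records):
        fp = _fingerprint(rec.standardized_smiles)
        sims[i] = max(DataStructs.BulkTanimotoSimilarity(fp, train_fps))

    edges = list(bin_edges)
    table = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        last = hi == edges[-1]
        in_bin = (sims >= lo) & ((sims <= hi) if last else (sims < hi))
        row = {"bin": (lo, hi), "n": int(in_bin.sum()), "mae": None}
        if predictions is not None and truths is not None and in_bin.any():
            p = np.asarray(predictions, dtype=float)[in_bin]
            t = np.asarray(truths, dtype=float)[in_bin]
            row["mae"] = float(np.mean(np.abs(p - t)))
        table.append(row)
    return sims, table


# ---------------------------------------------------------------------------
# dominant-site consistency


@dataclass
class DominantSiteAssignment:
    """Predicted dominant ionization site set G of one molecule.

    G collects every site whose predicted micro-pKa is within ``epsilon``
    of the extreme (minimum for acidic, maximum for basic), so near-ties
    yield a multi-element set.
    """

    molecule_id: str
    mode: str
    G: frozenset
    epsilon: float
    extreme_value: float
    site_micro: dict = field(default_factory=dict)


class NoSiteError(ValueError):
    pass


def dominant_sites(
    state: ModelState,
    graph: MoleculeGraph,
    mode: Optional[str] = None,
    epsilon: float = 0.1,
    molecule_id: str = "",
) -> DominantSiteAssignment:
    """Sites within epsilon of the extremal predicted micro-pKa."""
    mode = mode or state.config.mode
    sites = sorted(sites_for_mode(graph, mode))
    if not sites:
        raise NoSiteError(f"molecule {molecule_id or graph.smiles!r} has no {mode} site")
    batch = BatchedGraphs([graph])
    _, y, _ = forward_batch(state, batch)
    micro = {s: float(y.data[s, 0]) for s in sites}
    extreme = min(micro.values()) if mode == "acidic" else max(micro.values())
    G = frozenset(s for s, v in micro.items() if abs(v - extreme) <= epsilon)
    return DominantSiteAssignment(
        molecule_id=molecule_id, mode=mode, G=G, epsilon=epsilon,
        extreme_value=extreme, site_micro=micro,
    )


@dataclass
class ConsistencyReport:
    """Agreement between predicted dominant sites and expert assignments.

    ``c`` holds the per-molecule indicator (1 when the expert site lies in
    the predicted set G); the consistency rate is their mean.  Difference
    values quantify each disagreement as the worst-case absolute gap
    between the model's micro-pKa at its chosen sites and at the expert's.
    """

    c: list
    consistency_rate: float
    n: int
    difference_values: list


def consistency_rate(
    assignments: Sequence[DominantSiteAssignment],
    expert_sites: Sequence[int],
) -> ConsistencyReport:
    if len(assignments) != len(expert_sites):
        raise ValueError("assignments and expert site lists differ in length")
    c, diffs = [], []
    for a, h in zip(assignments, expert_sites):
        hit = 1 if h in a.G else 0
        c.append(hit)
        if not hit:
            if h not in a.site_micro:
                raise ValueError(f"expert site {h} is not a {a.mode} site of {a.molecule_id}")
            fh = a.site_micro[h]
            diffs.append(max(abs(a.site_micro[g] - fh) for g in a.G))
    n = len(c)
    return ConsistencyReport(
        c=c,
        consistency_rate=float(np.mean(c)) if n else float("nan"),
        n=n,
        difference_values=diffs,
    )


def difference_value(state: ModelState, graph: MoleculeGraph, g: int, h: int,
                     mode: Optional[str] = None) -> float:
    """|f(g) - f(h)|: gap between predicted micro-pKa at two sites."""
    mode = mode or state.config.mode
    sites = sites_for_mode(graph, mode)
    for s in (g, h):
        if s not in sites:
            raise ValueError(f"atom {s} is not a {mode} site")
    batch = BatchedGraphs([graph])
    _, y, _ = forward_batch(state, batch)
    return float(abs(y.data[g, 0] - y.data[h, 0]))
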