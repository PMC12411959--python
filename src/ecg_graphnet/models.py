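"""Graph-convolutional beat classifiers.

Three nested architectures predict a class in {N, S, V} for every beat of
a segment graph, in a many-to-many fashion and for any number of beats:

* **PQRST-Net** — GC blocks on the segment graph, QRS-centered pooling to
  one row per beat, then a fully connected prediction block.
* **PQRST-QRS-Net** — additionally routes the pooled beat features through
  GC blocks on the beat graph (path topology, RR-derived edge weights).
* **ECG-GraphNet** — additionally concatenates a skip path (the pooled
  segment-graph output) with the beat-graph output before prediction.

Each GC block is ``ReLU(BN(Â H W + b))`` with the symmetrically
degree-normalized weighted adjacency ``Â = D^{-1/2} A D^{-1/2}``; each FC
block is ``ReLU(BN(X W + b))``. Batch normalization uses batch moments in
training (over all nodes/beats of the graph batch) and running averages at
inference, so a single graph can be classified alone.

Training batches stack graphs block-diagonally (sparse adjacency and
pooling operators), so one parameter set serves graphs of any size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.sparse as sp

from . import nn
from .graphs import ECGGraph, build_qrs_graph, pooling_matrix
from .synthetic import CLASSES

ARCHITECTURES = ("pqrst", "pqrst_qrs", "ecg_graphnet")
SKIP_MODES = ("concat", "add", "none")


@dataclass(frozen=True)
class ArchitectureConfig:
    arch: str = "ecg_graphnet"
    in_dim: int = 22
    pqrst_channels: tuple[int, ...] = (32, 32)
    qrs_channels: tuple[int, ...] = (32,)
    fc_hidden: int = 16
    n_classes: int = 3
    pool_c: float = 0.1
    pool_inclusive: bool = True
    skip_mode: str = "concat"
    qrs_identity: bool = False  # testing hook: beat-graph block passes through

    def __post_init__(self) -> None:
        if self.arch not in ARCHITECTURES:
            raise ValueError(f"arch must be one of {ARCHITECTURES}")
        if self.skip_mode not in SKIP_MODES:
            raise ValueError(f"skip_mode must be one of {SKIP_MODES}")
        if any(c <= 0 for c in self.pqrst_channels + self.qrs_channels) \
                or self.fc_hidden <= 0:
            raise ValueError("channel sizes must be positive")

    @property
    def uses_qrs_block(self) -> bool:
        return self.arch in ("pqrst_qrs", "ecg_graphnet")

    @property
    def uses_skip(self) -> bool:
        return self.arch == "ecg_graphnet" and self.skip_mode != "none"


def gc_forward(H: np.ndarray, A: np.ndarray, W: np.ndarray,
               b: np.ndarray | None = None, bn: nn.BatchNorm | None = None,
               activation=nn.relu, train: bool = False) -> np.ndarray:
    """One graph convolution ``act(BN(Â H W + b))`` on a raw adjacency ``A``.

    ``A`` must be square, symmetric, and carry self-loops (positive
    degrees). Row count of the output equals that of ``H``.
    """
    A = np.asarray(A, dtype=float)
    if A.shape[0] != A.shape[1] or A.shape[0] != np.asarray(H).shape[0]:
        raise ValueError("adjacency and feature dimensions do not match")
    if not np.allclose(A, A.T):
        raise ValueError("adjacency must be symmetric")
    a_hat = nn.normalize_adjacency(A)
    z = a_hat @ (np.asarray(H, dtype=float) @ W)
    if b is not None:
        z = z + b
    if bn is not None:
        z = bn.forward(z, train=train)
    return activation(z) if activation is not None else z


@dataclass
class GraphBatch:
    """Block-diagonal stack of segment graphs ready for the network."""

    X: np.ndarray
    a_pqrst: sp.csr_matrix
    pool: sp.csr_matrix
    a_qrs: sp.csr_matrix
    labels: np.ndarray | None
    beats_per_graph: tuple[int, ...]
    patient_ids: tuple[str, ...]


def make_batch(graphs: Sequence[ECGGraph], pool_c: float = 0.1,
               pool_inclusive: bool = True) -> GraphBatch:
    """Stack graphs into one block-diagonal batch (features, Â, pooling, Â_qrs)."""
    xs, a_list, p_list, q_list, labels, nb = [], [], [], [], [], []
    for g in graphs:
        xs.append(g.X)
        a_list.append(nn.normalize_adjacency(g.A))
        p_list.append(pooling_matrix(g.node_meta, pool_c, pool_inclusive))
        qg = build_qrs_graph(g)
        q_list.append(nn.normalize_adjacency(qg.A))
        labels.extend(CLASSES.index(lab) for lab in g.beat_labels)
        nb.append(g.n_beats)
    return GraphBatch(
        np.vstack(xs),
        sp.block_diag(a_list, format="csr"),
        sp.block_diag(p_list, format="csr"),
        sp.block_diag(q_list, format="csr"),
        np.asarray(labels, dtype=int),
        tuple(nb),
        tuple(g.patient_id for g in graphs),
    )


class _GCBlock:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        self.gc = nn.GraphConv(n_in, n_out, rng)
        self.bn = nn.BatchNorm(n_out)

    @property
    def layers(self):
        return [self.gc, self.bn]

    def forward(self, h, a_hat, train):
        z = self.gc.forward(h, a_hat, train)
        z = self.bn.forward(z, train)
        self._mask = z > 0
        return nn.relu(z)

    def backward(self, g):
        g = g * self._mask
        g = self.bn.backward(g)
        return self.gc.backward(g)


class _FCBlock:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        self.fc = nn.Dense(n_in, n_out, rng)
        self.bn = nn.BatchNorm(n_out)

    @property
    def layers(self):
        return [self.fc, self.bn]

    def forward(self, x, train):
        z = self.bn.forward(self.fc.forward(x, train), train)
        self._mask = z > 0
        return nn.relu(z)

    def backward(self, g):
        g = g * self._mask
        g = self.bn.backward(g)
        return self.fc.backward(g)


class BeatClassifier:
    """Parameterized network for one of the three architectures.

    Parameter init draws from per-block child seeds, so e.g. the prediction
    block of two configs sharing a seed is identical even if one config
    lacks the beat-graph block.
    """

    def __init__(self, cfg: ArchitectureConfig, seed: int = 0) -> None:
        self.cfg = cfg
        ss = np.random.SeedSequence(seed)
        rng_p, rng_q, rng_f = (np.random.default_rng(s) for s in ss.spawn(3))
        self.pqrst_blocks = []
        n_in = cfg.in_dim
        for n_out in cfg.pqrst_channels:
            self.pqrst_blocks.append(_GCBlock(n_in, n_out, rng_p))
            n_in = n_out
        pooled_dim = n_in
        self.qrs_blocks = []
        if cfg.uses_qrs_block and not cfg.qrs_identity:
            for n_out in cfg.qrs_channels:
                self.qrs_blocks.append(_GCBlock(n_in, n_out, rng_q))
                n_in = n_out
        pred_in = n_in
        if cfg.uses_skip:
            if cfg.skip_mode == "concat":
                pred_in = pooled_dim + n_in
            elif pooled_dim != n_in:
                raise ValueError("additive skip needs matching channel sizes")
        self._pooled_dim = pooled_dim
        self.fc_block = _FCBlock(pred_in, cfg.fc_hidden, rng_f)
        self.out = nn.Dense(cfg.fc_hidden, cfg.n_classes, rng_f)

    # -- plumbing ---------------------------------------------------------
    @property
    def layers(self):
        out = []
        for blk in self.pqrst_blocks + self.qrs_blocks:
            out.extend(blk.layers)
        out.extend(self.fc_block.layers)
        out.append(self.out)
        return out

    @property
    def n_params(self) -> int:
        return nn.collect_params(self.layers)

    def get_state(self):
        return nn.get_state(self.layers)

    def set_state(self, state) -> None:
        nn.set_state(self.layers, state)

    # -- forward/backward -------------------------------------------------
    def forward(self, batch: GraphBatch, train: bool = False) -> np.ndarray:
        """Per-beat class probabilities, rows = total beats in the batch."""
        h = batch.X
        for blk in self.pqrst_blocks:
            h = blk.forward(h, batch.a_pqrst, train)
        pooled = batch.pool @ h
        self._batch = batch
        if self.cfg.uses_qrs_block:
            q = pooled
            for blk in self.qrs_blocks:
                q = blk.forward(q, batch.a_qrs, train)
            if self.cfg.uses_skip:
                z = np.hstack([pooled, q]) if self.cfg.skip_mode == "concat" \
                    else pooled + q
            else:
                z = q
        else:
            z = pooled
        hfc = self.fc_block.forward(z, train)
        logits = self.out.forward(hfc, train)
        self._probs = nn.softmax(logits)
        return self._probs

    def backward(self, labels: np.ndarray) -> None:
        """Cross-entropy gradient through the whole stack (call after forward)."""
        nb = len(labels)
        g = self._probs.copy()
        g[np.arange(nb), labels] -= 1.0
        g /= nb
        g = self.out.backward(g)
        g = self.fc_block.backward(g)
        pd = self._pooled_dim
        if self.cfg.uses_qrs_block:
            if self.cfg.uses_skip and self.cfg.skip_mode == "concat":
                g_skip, g_q = g[:, :pd], g[:, pd:]
            elif self.cfg.uses_skip:  # add
                g_skip, g_q = g, g
            else:
                g_skip, g_q = np.zeros((g.shape[0], pd)), g
            for blk in reversed(self.qrs_blocks):
                g_q = blk.backward(g_q)
            g_pooled = g_skip + g_q
        else:
            g_pooled = g
        g_nodes = self._batch.pool.T @ g_pooled
        for blk in reversed(self.pqrst_blocks):
            g_nodes = blk.backward(g_nodes)

    # -- inference --------------------------------------------------------
    def predict_proba(self, graph: ECGGraph) -> "BeatPrediction":
        if graph.n_beats == 0 or len(graph.qrs_positions) == 0:
            raise ValueError("graph has no QRS nodes to classify")
        batch = make_batch([graph], self.cfg.pool_c, self.cfg.pool_inclusive)
        return BeatPrediction(self.forward(batch, train=False))


@dataclass
class BeatPrediction:
    """Per-beat probability rows over (N, S, V); argmax ties favor N < S < V."""

    probs: np.ndarray

    @property
    def labels(self) -> np.ndarray:
        return self.probs.argmax(axis=1)

    @property
    def label_names(self) -> tuple[str, ...]:
        return tuple(CLASSES[i] for i in self.labels)

    def __len__(self) -> int:
        return self.probs.shape[0]


__all__ = [
    "ARCHITECTURES",
    "ArchitectureConfig",
    "BeatClassifier",
    "BeatPrediction",
    "GraphBatch",
    "gc_forward",
    "make_batch",
]
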