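"""ECG graph construction and QRS-centered weighted average pooling.

Two graphs are built from one annotated record:

* **segment graph** (``G_PQRST``): one node per annotated P/QRS/T segment in
  chronological order. Node features (d = 22 by default) are
  ``[one-hot type (3) | width s (1) | AE embedding (16) | gap to previous
  node, gap to next node in s (2)]``. Edges: unit self-loops, chronologically
  adjacent pairs, and QRS-QRS pairs inside a 5-node window (each QRS connects
  to up to 2 preceding and 2 following QRS nodes). Non-self edges are
  weighted by a logistic function of the time gap, so closer segments get
  weights nearer 1.
* **beat graph** (``G_QRS``): one node per QRS complex on a path topology,
  consecutive edges weighted from the RR interval.

The pooling operator aggregates node features beat-by-beat:
``pool(f_n) = 1/(1+k+j) * sum_{i=-k..j} (1 - c|i|) f_{n+i}``, where k and j
are the node-position offsets to the nearest preceding and following QRS
nodes (truncated at the graph boundary) and c is a decay constant. Weights
are floored at 0 if ``1 - c|i|`` goes negative; the ``1/(1+k+j)``
normalizer is kept as printed regardless.

All times are in seconds, so features are invariant to the sampling rate
and to translating the whole record in time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import scipy.sparse as sp

from .embedding import AEModel, embed
from .synthetic import AnnotatedECGRecord, SEGMENT_TYPES

EDGE_SCHEMES = ("qrs", "pp", "both", "none")


@dataclass(frozen=True)
class GraphConfig:
    """Edge-construction parameters of the segment graph."""

    edges: str = "qrs"        # same-type edge scheme: qrs | pp | both | none
    window: int = 5           # same-type window: node plus (window-1)/2 each side
    alpha: float = 10.0       # logistic steepness, 1/s
    delta0: float = 0.3       # logistic midpoint, s (inter-segment gap scale)
    rr_alpha: float = 6.0     # beat-graph logistic steepness, 1/s
    rr_delta0: float = 0.7    # beat-graph midpoint, s (typical resting RR)
    raw_rr_weights: bool = False  # beat-graph edges: raw RR instead of logistic

    def __post_init__(self) -> None:
        if self.edges not in EDGE_SCHEMES:
            raise ValueError(f"edges must be one of {EDGE_SCHEMES}")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive (edge weights must decrease "
                             "with the time gap)")


@dataclass(frozen=True)
class NodeMeta:
    segment_type: str
    beat_index: int
    onset: float   # seconds
    offset: float  # seconds


@dataclass
class ECGGraph:
    """Segment graph of one record: features X (M×d), weighted adjacency A."""

    X: np.ndarray
    A: np.ndarray
    node_meta: tuple[NodeMeta, ...]
    beat_labels: tuple[str, ...]
    patient_id: str = ""
    record_id: str = ""
    cfg: GraphConfig = field(default_factory=GraphConfig)

    @property
    def n_nodes(self) -> int:
        return self.X.shape[0]

    @property
    def n_beats(self) -> int:
        return len(self.beat_labels)

    @property
    def qrs_positions(self) -> np.ndarray:
        return np.array([i for i, m in enumerate(self.node_meta)
                         if m.segment_type == "QRS"], dtype=int)


@dataclass
class QRSGraph:
    """Beat graph: one node per QRS, consecutive-beat edges from RR intervals."""

    features: np.ndarray | None
    A: np.ndarray
    rr: np.ndarray  # RR intervals between consecutive beats, seconds


@dataclass
class PooledBeatMatrix:
    """Per-beat pooled feature rows plus the pooling bookkeeping (k, j, c)."""

    values: np.ndarray
    ks: np.ndarray
    js: np.ndarray
    c: float


def edge_weight(delta_t, alpha: float = 10.0, delta0: float = 0.3):
    """Logistic edge weight ``1 / (1 + exp(alpha (Δt − δ0)))`` in (0, 1).

    Strictly decreasing in the time gap ``delta_t`` (seconds); equals 0.5 at
    ``delta_t == delta0``.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    delta_t = np.asarray(delta_t, dtype=float)
    if np.any(delta_t < 0):
        raise ValueError("time gaps must be non-negative")
    w = 1.0 / (1.0 + np.exp(alpha * (delta_t - delta0)))
    return float(w) if w.ndim == 0 else w


def _build_adjacency(meta: Sequence[NodeMeta], cfg: GraphConfig) -> np.ndarray:
    """Weighted symmetric adjacency from node metadata alone.

    Shared by record-level construction and subgraph extraction so both
    apply identical rules. Same-type (QRS-QRS, P-P) gaps are measured
    onset-to-onset; chronologically adjacent gaps offset-to-next-onset.
    If two rules produce the same edge, the larger weight wins.
    """
    m = len(meta)
    a = np.eye(m)
    for i in range(m - 1):
        gap = max(0.0, meta[i + 1].onset - meta[i].offset)
        w = edge_weight(gap, cfg.alpha, cfg.delta0)
        a[i, i + 1] = a[i + 1, i] = max(a[i, i + 1], w)
    half = (cfg.window - 1) // 2
    schemes = {"qrs": ("QRS",), "pp": ("P",), "both": ("QRS", "P"), "none": ()}
    for stype in schemes[cfg.edges]:
        pos = [i for i, nm in enumerate(meta) if nm.segment_type == stype]
        for a_i in range(len(pos)):
            for b_i in range(a_i + 1, min(a_i + half + 1, len(pos))):
                u, v = pos[a_i], pos[b_i]
                gap = meta[v].onset - meta[u].onset
                w = edge_weight(max(0.0, gap), cfg.alpha, cfg.delta0)
                a[u, v] = a[v, u] = max(a[u, v], w)
    return a


def build_graph(record: AnnotatedECGRecord, aes: dict[str, AEModel],
                cfg: GraphConfig = GraphConfig()) -> ECGGraph:
    """Build the segment graph of one annotated record.

    ``aes`` maps segment type to a trained autoencoder. Raises on a record
    without beats or with out-of-order segments.
    """
    if not record.beats:
        raise ValueError("record has no beats; cannot build a graph")
    nodes: list[NodeMeta] = []
    segments: list[np.ndarray] = []
    for bi, beat in enumerate(record.beats):
        if "QRS" not in beat.segments:
            raise ValueError(f"beat {bi} lacks a QRS segment")
        for stype in SEGMENT_TYPES:
            if stype not in beat.segments:
                continue
            on, off = beat.segments[stype]
            nodes.append(NodeMeta(stype, bi, on / record.fs, off / record.fs))
            segments.append(record.samples[on:off])
    onsets = [nm.onset for nm in nodes]
    if any(b < a for a, b in zip(onsets, onsets[1:])):
        raise ValueError("segments are out of chronological order")

    latent = aes[nodes[0].segment_type].cfg.latent_dim
    d = 3 + 1 + latent + 2
    m = len(nodes)
    x = np.zeros((m, d))
    for i, (nm, seg) in enumerate(zip(nodes, segments)):
        x[i, SEGMENT_TYPES.index(nm.segment_type)] = 1.0
        x[i, 3] = nm.offset - nm.onset
        x[i, 4:4 + latent] = embed(aes[nm.segment_type], seg)
        if i > 0:
            x[i, 4 + latent] = max(0.0, nm.onset - nodes[i - 1].offset)
        if i < m - 1:
            x[i, 5 + latent] = max(0.0, nodes[i + 1].onset - nm.offset)
    a = _build_adjacency(nodes, cfg)
    return ECGGraph(x, a, tuple(nodes), record.labels,
                    record.patient_id, record.record_id, cfg)


def pooling_weights(node_meta: Sequence[NodeMeta], c: float, inclusive: bool = True):
    """Per-beat pooling index ranges and weight vectors.

    Returns ``(rows, ks, js)`` where ``rows[b]`` is a list of
    ``(node_index, weight)`` pairs for beat ``b``. The summation limits
    ``-k..j`` include the neighboring QRS nodes themselves; pass
    ``inclusive=False`` to stop one node short of them on each side
    (pooling then only reaches the adjacent P and T nodes).
    """
    if c < 0:
        raise ValueError("decay constant c must be non-negative")
    qrs = [i for i, nm in enumerate(node_meta) if nm.segment_type == "QRS"]
    if not qrs:
        raise ValueError("graph has no QRS nodes")
    m = len(node_meta)
    rows, ks, js = [], [], []
    for b, n in enumerate(qrs):
        k = n - qrs[b - 1] if b > 0 else n
        j = qrs[b + 1] - n if b < len(qrs) - 1 else m - 1 - n
        if not inclusive:
            k = max(0, k - 1) if b > 0 else k
            j = max(0, j - 1) if b < len(qrs) - 1 else j
        norm = 1.0 / (1 + k + j)
        rows.append([(n + i, norm * max(0.0, 1.0 - c * abs(i)))
                     for i in range(-k, j + 1)])
        ks.append(k)
        js.append(j)
    return rows, np.array(ks), np.array(js)


def pooling_matrix(node_meta: Sequence[NodeMeta], c: float,
                   inclusive: bool = True) -> sp.csr_matrix:
    """Sparse B×M operator P with ``P @ H`` = QRS-centered pooled features."""
    rows, _, _ = pooling_weights(node_meta, c, inclusive)
    m = len(node_meta)
    data, ri, ci = [], [], []
    for b, row in enumerate(rows):
        for idx, w in row:
            ri.append(b)
            ci.append(idx)
            data.append(w)
    return sp.csr_matrix((data, (ri, ci)), shape=(len(rows), m))


def qrs_centered_pool(H: np.ndarray, node_meta: Sequence[NodeMeta],
                      c: float = 0.1, inclusive: bool = True) -> PooledBeatMatrix:
    """QRS-centered weighted average pooling of node features ``H``."""
    rows, ks, js = pooling_weights(node_meta, c, inclusive)
    p = pooling_matrix(node_meta, c, inclusive)
    return PooledBeatMatrix(p @ np.asarray(H, dtype=float), ks, js, c)


def build_qrs_graph(graph: ECGGraph, beat_features: PooledBeatMatrix | None = None,
                    cfg: GraphConfig | None = None) -> QRSGraph:
    """Path graph over beats with RR-interval-derived consecutive edge weights."""
    cfg = cfg or graph.cfg
    qrs = graph.qrs_positions
    if beat_features is not None and beat_features.values.shape[0] != len(qrs):
        raise ValueError("beat feature rows do not align with QRS nodes")
    onsets = np.array([graph.node_meta[i].onset for i in qrs])
    rr = np.diff(onsets)
    b = len(qrs)
    a = np.eye(b)
    for i, interval in enumerate(rr):
        w = float(interval) if cfg.raw_rr_weights else edge_weight(
            max(0.0, float(interval)), cfg.rr_alpha, cfg.rr_delta0)
        a[i, i + 1] = a[i + 1, i] = w
    feats = None if beat_features is None else beat_features.values
    return QRSGraph(feats, a, rr)


def extract_beat_subgraph(graph: ECGGraph, beat_lo: int, beat_hi: int,
                          keep_boundary_distances: bool = False) -> ECGGraph:
    """New graph from beats ``beat_lo..beat_hi`` (inclusive) of ``graph``.

    Node features are copied and the adjacency is rebuilt with the same
    rules, so the result satisfies every segment-graph invariant on its
    own. By default the new boundary nodes get a zero gap on their missing
    side, matching record-level construction; with
    ``keep_boundary_distances`` they retain the source record's gaps —
    timing context (e.g. a premature beat's short preceding interval) that
    would otherwise be lost with the removed neighbor.
    """
    keep = [i for i, nm in enumerate(graph.node_meta)
            if beat_lo <= nm.beat_index <= beat_hi]
    if not keep:
        raise ValueError("empty beat range")
    meta = tuple(
        replace(graph.node_meta[i], beat_index=graph.node_meta[i].beat_index - beat_lo)
        for i in keep
    )
    x = graph.X[keep].copy()
    if not keep_boundary_distances:
        x[0, -2] = 0.0
        x[-1, -1] = 0.0
    a = _build_adjacency(meta, graph.cfg)
    labels = graph.beat_labels[beat_lo:beat_hi + 1]
    return ECGGraph(x, a, meta, labels, graph.patient_id,
                    f"{graph.record_id}.sub{beat_lo}-{beat_hi}", graph.cfg)
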