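"""Graph-level minority-class rebalancing for training sets.

The study mixture is heavily skewed toward normal beats (about
75/15/10 % for N/S/V), which starves a per-beat classifier of ectopic
examples. Rebalancing operates on graphs, never on raw signal samples:

1. **Run extraction** — subgraphs are cut out around minority (S or V)
   beats. A window is a run of consecutive beats of one ectopic class,
   capped at ``window`` beats; it keeps all the run's segment nodes and
   rebuilds the adjacency with the standard construction rules. Because
   windows contain no N beats, the N beat count is provably unchanged.
2. **Feature jitter** — each extracted subgraph gets multiplicative
   Gaussian jitter (sd ``jitter_sd``) on its width and inter-segment
   distance features only; one-hot and embedding coordinates encode
   segment identity and morphology class and are left untouched.

A greedy loop repeatedly picks the ectopic class with the largest deficit
relative to the target proportions and appends one jittered run-subgraph,
stopping when every class proportion is within ``tol`` of its target or a
growth cap is reached. Original graphs are never mutated.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np

from .graphs import ECGGraph, extract_beat_subgraph
from .synthetic import CLASSES

_JITTER_COLS_FROM_END = 2  # the two distance features sit in the last columns
_WIDTH_COL = 3


@dataclass(frozen=True)
class AugmentationPlan:
    """Target mixture and jitter settings for training-set rebalancing."""

    targets: tuple[float, float, float] = (0.40, 0.30, 0.30)  # N, S, V
    jitter_sd: float = 0.05
    window: int = 8
    tol: float = 0.02
    max_factor: float = 20.0  # cap: new graphs <= max_factor * len(originals)

    def __post_init__(self) -> None:
        if not np.isclose(sum(self.targets), 1.0, atol=1e-6):
            raise ValueError("target proportions must sum to 1")
        if any(t < 0 for t in self.targets):
            raise ValueError("target proportions must be non-negative")


@dataclass
class AugmentationReport:
    counts_before: dict[str, int]
    counts_after: dict[str, int]
    n_new_graphs: int
    capped: bool = False

    @property
    def proportions_after(self) -> dict[str, float]:
        total = sum(self.counts_after.values())
        return {c: self.counts_after[c] / total for c in CLASSES}


def _minority_runs(graph: ECGGraph, window: int) -> list[tuple[str, int, int]]:
    """Maximal same-class ectopic beat runs as (label, first, last), capped."""
    runs = []
    labels = graph.beat_labels
    i = 0
    while i < len(labels):
        if labels[i] in ("S", "V"):
            j = i
            while j + 1 < len(labels) and labels[j + 1] == labels[i]:
                j += 1
            lo = i
            while lo <= j:
                hi = min(j, lo + window - 1)
                runs.append((labels[i], lo, hi))
                lo = hi + 1
            i = j + 1
        else:
            i += 1
    return runs


def _jitter(graph: ECGGraph, sd: float, rng: np.random.Generator) -> ECGGraph:
    x = graph.X.copy()
    cols = [_WIDTH_COL, x.shape[1] - 2, x.shape[1] - 1]
    for col in cols:
        x[:, col] *= 1.0 + rng.normal(0.0, sd, size=x.shape[0])
    return ECGGraph(x, graph.A.copy(), graph.node_meta, graph.beat_labels,
                    graph.patient_id, graph.record_id, graph.cfg)


def augment(graphs: list[ECGGraph], plan: AugmentationPlan,
            rng: np.random.Generator) -> tuple[list[ECGGraph], AugmentationReport]:
    """Return originals + minority-run subgraphs approaching ``plan.targets``.

    Raises if a class with a positive target has no beats in the input.
    If the growth cap is hit first, a warning reports the achieved
    proportions.
    """
    counts = Counter({c: 0 for c in CLASSES})
    for g in graphs:
        counts.update(g.beat_labels)
    before = dict(counts)
    targets = dict(zip(CLASSES, plan.targets))
    for cls in ("S", "V"):
        if targets[cls] > 0 and counts[cls] == 0:
            raise ValueError(f"target {targets[cls]:.2f} for class {cls} "
                             "but no such beats exist in the input")

    candidates: dict[str, list[tuple[ECGGraph, int, int]]] = {"S": [], "V": []}
    for g in graphs:
        for cls, lo, hi in _minority_runs(g, plan.window):
            candidates[cls].append((g, lo, hi))

    out = list(graphs)
    cap = int(plan.max_factor * len(graphs))
    capped = False
    while True:
        total = sum(counts.values())
        props = {c: counts[c] / total for c in CLASSES}
        if all(abs(props[c] - targets[c]) <= plan.tol for c in CLASSES):
            break
        deficits = {c: targets[c] - props[c] for c in ("S", "V")}
        cls = max(deficits, key=lambda c: (deficits[c], c))
        if deficits[cls] <= 0:
            break  # beats can only be added; nothing left to improve
        if len(out) - len(graphs) >= cap:
            capped = True
            warnings.warn(
                "augmentation cap reached; achieved proportions "
                + ", ".join(f"{c}={props[c]:.3f}" for c in CLASSES)
            )
            break
        src, lo, hi = candidates[cls][rng.integers(len(candidates[cls]))]
        sub = extract_beat_subgraph(src, lo, hi, keep_boundary_distances=True)
        out.append(_jitter(sub, plan.jitter_sd, rng))
        counts.update(sub.beat_labels)
    report = AugmentationReport(before, dict(counts), len(out) - len(graphs), capped)
    return out, report
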