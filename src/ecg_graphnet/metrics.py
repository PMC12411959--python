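"""Per-class beat metrics, exact-match accuracy, and CV aggregation.

All metrics derive from the 3×3 confusion matrix over (N, S, V):
Sn = TP/(TP+FN), PPV = TP/(TP+FP), F1 = their harmonic mean, Acc =
correct/total, Macro F1 = unweighted mean of the class F1 scores. A class
absent from the labels has undefined Sn/F1; by default it is reported as
NaN and excluded from the Macro F1 denominator (switchable to counting it
as 0). With ``exclude_ends`` the first and last beat of every graph are
dropped before counting — segment boundaries at graph ends are poorly
connected, and the study protocol scores interior beats separately.

Cross-validation summaries report per-fold values, their mean, and the
error range (max − min)/2, with the standard deviation alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .models import BeatPrediction
from .synthetic import CLASSES


def _as_label_array(x) -> np.ndarray:
    if isinstance(x, BeatPrediction):
        return x.labels
    arr = np.asarray(x)
    if arr.dtype.kind in "US":
        return np.array([CLASSES.index(v) for v in arr], dtype=int)
    return arr.astype(int)


def _trim(arr: np.ndarray, exclude_ends: bool) -> np.ndarray:
    return arr[1:-1] if exclude_ends else arr


@dataclass
class EvalReport:
    """Per-class Sn/PPV/F1 plus overall Acc and Macro F1 for one evaluation."""

    confusion: np.ndarray
    exclude_ends: bool = False
    nan_excluded_from_macro: bool = True

    @property
    def per_class(self) -> dict[str, dict[str, float]]:
        cm = self.confusion
        out = {}
        for i, cls in enumerate(CLASSES):
            tp = cm[i, i]
            fn = cm[i, :].sum() - tp
            fp = cm[:, i].sum() - tp
            sn = tp / (tp + fn) if tp + fn > 0 else float("nan")
            ppv = tp / (tp + fp) if tp + fp > 0 else float("nan")
            if np.isnan(sn) or np.isnan(ppv) or sn + ppv == 0:
                f1 = float("nan") if np.isnan(sn) else 0.0
            else:
                f1 = 2 * sn * ppv / (sn + ppv)
            out[cls] = {"sn": sn, "ppv": ppv, "f1": f1}
        return out

    @property
    def acc(self) -> float:
        total = self.confusion.sum()
        return float(np.trace(self.confusion) / total) if total else float("nan")

    @property
    def macro_f1(self) -> float:
        f1s = np.array([v["f1"] for v in self.per_class.values()])
        if self.nan_excluded_from_macro:
            f1s = f1s[~np.isnan(f1s)]
        else:
            f1s = np.nan_to_num(f1s)
        return float(f1s.mean()) if f1s.size else float("nan")


def confusion_matrix(preds: Sequence, labels: Sequence,
                     exclude_ends: bool = False) -> np.ndarray:
    """3×3 confusion matrix over per-graph prediction/label sequences."""
    cm = np.zeros((3, 3), dtype=int)
    if len(preds) != len(labels):
        raise ValueError("preds and labels must align per graph")
    for p, y in zip(preds, labels):
        p = _trim(_as_label_array(p), exclude_ends)
        y = _trim(_as_label_array(y), exclude_ends)
        if len(p) != len(y):
            raise ValueError("prediction/label length mismatch within a graph")
        for pi, yi in zip(p, y):
            cm[yi, pi] += 1
    return cm


def evaluate(preds: Sequence, labels: Sequence, exclude_ends: bool = False,
             nan_excluded_from_macro: bool = True) -> EvalReport:
    """Score aligned per-graph predictions against labels."""
    cm = confusion_matrix(preds, labels, exclude_ends)
    return EvalReport(cm, exclude_ends, nan_excluded_from_macro)


def exact_match(preds: Sequence, labels: Sequence,
                exclude_ends: bool = False) -> float:
    """Fraction of graphs whose (optionally end-excluded) beats all match."""
    if len(preds) != len(labels):
        raise ValueError("preds and labels must align per graph")
    hits = 0
    for p, y in zip(preds, labels):
        p = _trim(_as_label_array(p), exclude_ends)
        y = _trim(_as_label_array(y), exclude_ends)
        if len(p) != len(y):
            raise ValueError("prediction/label length mismatch within a graph")
        hits += int(np.array_equal(p, y))
    return hits / len(preds) if len(preds) else float("nan")


@dataclass
class CVSummary:
    """Fold-level reports with mean and (max − min)/2 error range."""

    fold_reports: list[EvalReport] = field(default_factory=list)
    fold_exact_match: list[float] = field(default_factory=list)

    def _series(self, getter) -> np.ndarray:
        return np.array([getter(r) for r in self.fold_reports], dtype=float)

    def summary(self, getter) -> dict[str, float]:
        vals = self._series(getter)
        return {
            "mean": float(np.nanmean(vals)),
            "error_range": float((np.nanmax(vals) - np.nanmin(vals)) / 2),
            "sd": float(np.nanstd(vals)),
        }

    @property
    def macro_f1(self) -> dict[str, float]:
        return self.summary(lambda r: r.macro_f1)

    @property
    def acc(self) -> dict[str, float]:
        return self.summary(lambda r: r.acc)

    def class_f1(self, cls: str) -> dict[str, float]:
        return self.summary(lambda r: r.per_class[cls]["f1"])

    @property
    def exact_match(self) -> dict[str, float]:
        vals = np.array(self.fold_exact_match, dtype=float)
        if vals.size == 0:
            return {"mean": float("nan"), "error_range": float("nan"), "sd": float("nan")}
        return {
            "mean": float(np.nanmean(vals)),
            "error_range": float((np.nanmax(vals) - np.nanmin(vals)) / 2),
            "sd": float(np.nanstd(vals)),
        }
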