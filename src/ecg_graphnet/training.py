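"""Interpatient cross-validation, training loop, grid search, ensembling,
and the pattern/size generalization (scalability) protocol.

The unit of leakage control is the patient: folds partition patients, the
per-fold segment autoencoders are fit only on training-fold records, and
augmentation touches training folds only. Every training call asserts
train/validation patient disjointness.

Training minimizes per-beat cross-entropy with Adam on the full graph
batch and stops early when the validation loss has not improved for
``patience`` consecutive epochs, restoring the best-validation parameters.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from . import nn
from .augmentation import AugmentationPlan, augment
from .embedding import AEConfig, AEModel, fit_segment_autoencoders
from .graphs import ECGGraph, GraphConfig, build_graph
from .metrics import CVSummary, EvalReport, evaluate, exact_match
from .models import ArchitectureConfig, BeatClassifier, BeatPrediction, make_batch
from .synthetic import AnnotatedECGRecord, has_ectopic_run

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 5e-3
    max_epochs: int = 400
    patience: int = 40
    min_delta: float = 1e-9


@dataclass(frozen=True)
class FoldSplit:
    """Partition of patients into k folds; every patient in exactly one."""

    k: int
    assignment: dict[str, int]

    def fold_patients(self, fold: int) -> set[str]:
        return {p for p, f in self.assignment.items() if f == fold}


def interpatient_folds(patient_ids: Sequence[str], k: int,
                       seed: int = 0) -> FoldSplit:
    """Deterministic near-equal partition of patients into k folds."""
    unique = sorted(set(patient_ids))
    if len(unique) < k:
        raise ValueError(f"{len(unique)} patients cannot fill {k} folds")
    rng = np.random.default_rng(seed)
    order = list(unique)
    rng.shuffle(order)
    return FoldSplit(k, {p: i % k for i, p in enumerate(order)})


def _assert_disjoint(train_graphs: Sequence[ECGGraph],
                     val_graphs: Sequence[ECGGraph]) -> None:
    tr = {g.patient_id for g in train_graphs}
    va = {g.patient_id for g in val_graphs}
    overlap = tr & va
    if overlap:
        raise ValueError(f"patient leakage between train and val: {sorted(overlap)}")


@dataclass
class TrainedModel:
    model: BeatClassifier
    aes: dict[str, AEModel]
    history: list[dict] = field(default_factory=list)

    def predict_record(self, record: AnnotatedECGRecord,
                       graph_cfg: GraphConfig) -> BeatPrediction:
        return self.model.predict_proba(build_graph(record, self.aes, graph_cfg))


def train_model(cfg: ArchitectureConfig, train_graphs: Sequence[ECGGraph],
                val_graphs: Sequence[ECGGraph], seed: int = 0,
                train_cfg: TrainConfig = TrainConfig()) -> tuple[BeatClassifier, list[dict]]:
    """Train one classifier with early stopping on validation loss.

    Returns the model restored to its best-validation-loss parameters,
    plus the per-epoch loss history. Fully deterministic under ``seed``.
    """
    if not train_graphs:
        raise ValueError("empty training set")
    _assert_disjoint(train_graphs, val_graphs)
    model = BeatClassifier(cfg, seed=seed)
    opt = nn.Adam(model.layers, lr=train_cfg.lr)
    train_batch = make_batch(train_graphs, cfg.pool_c, cfg.pool_inclusive)
    val_batch = make_batch(val_graphs, cfg.pool_c, cfg.pool_inclusive)

    best_loss, best_state, bad_epochs = np.inf, None, 0
    history: list[dict] = []
    for epoch in range(train_cfg.max_epochs):
        probs = model.forward(train_batch, train=True)
        train_loss = nn.cross_entropy(probs, train_batch.labels)
        opt.zero_grad()
        model.backward(train_batch.labels)
        opt.step()

        val_probs = model.forward(val_batch, train=False)
        val_loss = nn.cross_entropy(val_probs, val_batch.labels)
        history.append({"epoch": epoch, "train_loss": train_loss,
                        "val_loss": val_loss})
        if val_loss < best_loss - train_cfg.min_delta:
            best_loss, best_state, bad_epochs = val_loss, model.get_state(), 0
        else:
            bad_epochs += 1
            if bad_epochs >= train_cfg.patience:
                break
    if best_state is not None:
        model.set_state(best_state)
    return model, history


@dataclass
class FoldData:
    train_graphs: list[ECGGraph]
    val_graphs: list[ECGGraph]
    aes: dict[str, AEModel]


def prepare_fold(train_records: Sequence[AnnotatedECGRecord],
                 val_records: Sequence[AnnotatedECGRecord],
                 graph_cfg: GraphConfig, seed: int,
                 ae_cfg: AEConfig = AEConfig(),
                 augment_plan: AugmentationPlan | None = None) -> FoldData:
    """Fit fold autoencoders on training records, build graphs, augment train."""
    aes = fit_segment_autoencoders(train_records, ae_cfg, seed=seed)
    train_graphs = [build_graph(r, aes, graph_cfg) for r in train_records]
    val_graphs = [build_graph(r, aes, graph_cfg) for r in val_records]
    if augment_plan is not None:
        rng = np.random.default_rng(seed + 1)
        train_graphs, _ = augment(train_graphs, augment_plan, rng)
    return FoldData(train_graphs, val_graphs, aes)


@dataclass
class CVResult:
    summary: CVSummary
    fold_models: list[TrainedModel]
    cfg: ArchitectureConfig


def run_cv(records: Sequence[AnnotatedECGRecord], cfg: ArchitectureConfig,
           k: int = 5, seed: int = 0, graph_cfg: GraphConfig = GraphConfig(),
           train_cfg: TrainConfig = TrainConfig(),
           ae_cfg: AEConfig = AEConfig(),
           augment_plan: AugmentationPlan | None = None,
           exclude_ends: bool = False,
           prepared_folds: Sequence[FoldData] | None = None) -> CVResult:
    """k-fold interpatient cross-validation of one architecture.

    ``prepared_folds`` lets several architectures share identical fold
    data (autoencoders + graphs), as the study's architecture comparison
    requires.
    """
    split = interpatient_folds([r.patient_id for r in records], k, seed)
    summary = CVSummary()
    fold_models: list[TrainedModel] = []
    for fold in range(k):
        if prepared_folds is not None:
            data = prepared_folds[fold]
        else:
            val_p = split.fold_patients(fold)
            data = prepare_fold(
                [r for r in records if r.patient_id not in val_p],
                [r for r in records if r.patient_id in val_p],
                graph_cfg, seed + fold, ae_cfg, augment_plan,
            )
        model, history = train_model(cfg, data.train_graphs, data.val_graphs,
                                     seed=seed + fold, train_cfg=train_cfg)
        preds = [model.predict_proba(g) for g in data.val_graphs]
        labels = [g.beat_labels for g in data.val_graphs]
        summary.fold_reports.append(evaluate(preds, labels, exclude_ends))
        summary.fold_exact_match.append(exact_match(preds, labels, exclude_ends))
        fold_models.append(TrainedModel(model, data.aes, history))
        log.info("fold %d: macro F1 %.4f", fold, summary.fold_reports[-1].macro_f1)
    return CVResult(summary, fold_models, cfg)


def prepare_cv_folds(records: Sequence[AnnotatedECGRecord], k: int, seed: int,
                     graph_cfg: GraphConfig = GraphConfig(),
                     ae_cfg: AEConfig = AEConfig(),
                     augment_plan: AugmentationPlan | None = None) -> list[FoldData]:
    """Precompute fold data shared across architecture comparisons."""
    split = interpatient_folds([r.patient_id for r in records], k, seed)
    folds = []
    for fold in range(k):
        val_p = split.fold_patients(fold)
        folds.append(prepare_fold(
            [r for r in records if r.patient_id not in val_p],
            [r for r in records if r.patient_id in val_p],
            graph_cfg, seed + fold, ae_cfg, augment_plan,
        ))
    return folds


# -- grid search ----------------------------------------------------------

def grid_search(grid: Mapping[str, Sequence], records, k: int = 5, seed: int = 0,
                base_cfg: ArchitectureConfig = ArchitectureConfig(),
                **cv_kwargs) -> tuple[ArchitectureConfig, list[dict]]:
    """Exhaustive search over ``ArchitectureConfig`` field values.

    ``grid`` maps config field names to candidate values. The winner
    maximizes mean Macro F1; ties break toward fewer parameters, then
    lexicographic config order. Failing cells are recorded and skipped.
    """
    if not grid:
        raise ValueError("grid must be non-empty")
    keys = sorted(grid)
    cells: list[dict] = []
    for combo in itertools.product(*(grid[key] for key in keys)):
        overrides = dict(zip(keys, combo))
        try:
            cfg = replace(base_cfg, **overrides)
            result = run_cv(records, cfg, k=k, seed=seed, **cv_kwargs)
            cells.append({
                "overrides": overrides,
                "macro_f1": result.summary.macro_f1["mean"],
                "n_params": result.fold_models[0].model.n_params,
                "summary": result.summary,
                "failed": False,
            })
        except Exception as exc:  # noqa: BLE001 - robustness across the lattice
            cells.append({"overrides": overrides, "failed": True,
                          "error": str(exc)})
            log.warning("grid cell %s failed: %s", overrides, exc)
    ok = [c for c in cells if not c["failed"]]
    if not ok:
        raise RuntimeError("every grid cell failed")
    winner = min(ok, key=lambda c: (-c["macro_f1"], c["n_params"],
                                    sorted(c["overrides"].items()).__repr__()))
    best_cfg = replace(base_cfg, **winner["overrides"])
    return best_cfg, cells


# -- ensembling -----------------------------------------------------------

def ensemble_predict(models: Sequence[BeatClassifier], graph: ECGGraph) -> BeatPrediction:
    """Soft voting: mean of member per-beat probabilities, argmax label."""
    if not models:
        raise ValueError("need at least one model")
    probs = [m.predict_proba(graph).probs for m in models]
    shapes = {p.shape for p in probs}
    if len(shapes) > 1:
        raise ValueError("members disagree on beat count")
    return BeatPrediction(np.mean(probs, axis=0))


def ensemble_predict_record(models: Sequence[TrainedModel],
                            record: AnnotatedECGRecord,
                            graph_cfg: GraphConfig) -> BeatPrediction:
    """Soft voting where each member embeds with its own fold autoencoders."""
    if not models:
        raise ValueError("need at least one model")
    probs = [m.predict_record(record, graph_cfg).probs for m in models]
    return BeatPrediction(np.mean(probs, axis=0))


# -- scalability protocol -------------------------------------------------

@dataclass
class ScalabilitySplits:
    """Training and test record sets for the pattern/size protocol."""

    train_records: list[AnnotatedECGRecord]
    pattern: list[AnnotatedECGRecord]
    size: list[AnnotatedECGRecord]
    control: list[AnnotatedECGRecord]
    test_patients: set[str]

    @property
    def train_patients(self) -> set[str]:
        return {r.patient_id for r in self.train_records}


def _qualifies(record: AnnotatedECGRecord) -> bool:
    labels = record.labels
    return (len(labels) == 8 and "N" in labels and has_ectopic_run(labels))


def scalability_splits(records: Sequence[AnnotatedECGRecord]) -> ScalabilitySplits:
    """Split records by the pattern rule, keeping patients disjoint.

    Test patients own at least one 8-beat record with >= 1 N beat and a run
    of >= 4 consecutive same-class ectopic beats; everyone else trains.
    The training side keeps only its 8-beat records. Test records are
    routed to Pattern (qualifying), Size (>= 9 beats), or Control
    (other 8-beat) sets.
    """
    test_patients = {r.patient_id for r in records if _qualifies(r)}
    if not test_patients:
        raise ValueError(
            "no patient owns a qualifying pattern record; generate data with "
            "ectopic-run patterns (see synthetic.generate_scalability_dataset)"
        )
    train_records, pattern, size, control = [], [], [], []
    for r in records:
        if r.patient_id in test_patients:
            if _qualifies(r):
                pattern.append(r)
            elif len(r.beats) >= 9:
                size.append(r)
            elif len(r.beats) == 8:
                control.append(r)
        elif len(r.beats) == 8:
            train_records.append(r)
    splits = ScalabilitySplits(train_records, pattern, size, control, test_patients)
    assert not splits.train_patients & test_patients
    return splits


@dataclass
class ScalabilityResult:
    cv: CVResult
    test_reports: dict[str, EvalReport]
    test_exact_match: dict[str, float]


def scalability_run(records: Sequence[AnnotatedECGRecord],
                    cfg: ArchitectureConfig, seed: int = 0, k: int = 5,
                    graph_cfg: GraphConfig = GraphConfig(),
                    train_cfg: TrainConfig = TrainConfig(),
                    ae_cfg: AEConfig = AEConfig(),
                    augment_plan: AugmentationPlan | None = None,
                    exclude_ends: bool = False) -> ScalabilityResult:
    """Train on 8-beat graphs only; soft-vote the k fold models on the
    Pattern, Size, and Control test sets without reconfiguration."""
    splits = scalability_splits(records)
    cv = run_cv(splits.train_records, cfg, k=k, seed=seed, graph_cfg=graph_cfg,
                train_cfg=train_cfg, ae_cfg=ae_cfg, augment_plan=augment_plan,
                exclude_ends=exclude_ends)
    reports, em = {}, {}
    for name, recs in (("pattern", splits.pattern), ("size", splits.size),
                       ("control", splits.control)):
        preds = [ensemble_predict_record(cv.fold_models, r, graph_cfg)
                 for r in recs]
        labels = [r.labels for r in recs]
        reports[name] = evaluate(preds, labels, exclude_ends)
        em[name] = exact_match(preds, labels, exclude_ends)
    return ScalabilityResult(cv, reports, em)
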