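"""Metrics oracles, fold hygiene, early stopping, ensembling, grid search,
and the scalability split rules."""

import numpy as np
import pytest
from sklearn.metrics import precision_recall_fscore_support

from ecg_graphnet import (ArchitectureConfig, BeatPrediction, evaluate,
                          exact_match, ensemble_predict, interpatient_folds,
                          train_model)
from ecg_graphnet.models import BeatClassifier
from ecg_graphnet.synthetic import AnnotatedECGRecord, Beat
from ecg_graphnet.training import (TrainConfig, grid_search,
                                   scalability_splits)

from oracle_helpers import brute_force_metrics


class TestMetrics:
    def test_hand_built_confusion_case(self):
        rep = evaluate([["N", "S", "S", "V"]], [["N", "N", "S", "V"]])
        assert rep.acc == pytest.approx(0.75)
        assert rep.per_class["N"]["f1"] == pytest.approx(2 / 3)
        assert rep.per_class["S"]["f1"] == pytest.approx(2 / 3)
        assert rep.per_class["V"]["f1"] == pytest.approx(1.0)
        assert rep.macro_f1 == pytest.approx(7 / 9)

    def test_perfect_predictions_score_one(self):
        labels = [["N", "S", "V", "N"], ["V", "N"]]
        rep = evaluate(labels, labels)
        assert rep.acc == 1.0 and rep.macro_f1 == 1.0
        assert exact_match(labels, labels) == 1.0

    def test_agrees_with_brute_force_and_sklearn(self, rng):
        for _ in range(200):
            n = int(rng.integers(3, 40))
            y = rng.integers(0, 3, n)
            p = rng.integers(0, 3, n)
            if len(set(y)) < 3:
                continue  # keep every class defined to share conventions
            rep = evaluate([p], [y])
            pc, acc, macro = brute_force_metrics(p, y)
            assert rep.acc == pytest.approx(acc)
            assert rep.macro_f1 == pytest.approx(macro)
            prec, rec, f1, _ = precision_recall_fscore_support(
                y, p, labels=[0, 1, 2], zero_division=0.0)
            for i, cls in enumerate(("N", "S", "V")):
                assert rep.per_class[cls]["sn"] == pytest.approx(rec[i])
                got_f1 = rep.per_class[cls]["f1"]
                assert (0.0 if np.isnan(got_f1) else got_f1) == pytest.approx(f1[i])

    def test_exact_match_agrees_with_direct_count(self, rng):
        graphs_p, graphs_y, want = [], [], 0
        for _ in range(300):
            n = int(rng.integers(2, 10))
            y = rng.integers(0, 3, n)
            p = y.copy()
            if rng.random() < 0.5:
                p[rng.integers(n)] = (p[rng.integers(n)] + 1) % 3
            graphs_p.append(p)
            graphs_y.append(y)
            want += int(np.array_equal(p, y))
        assert exact_match(graphs_p, graphs_y) == pytest.approx(want / 300)

    def test_exact_match_interior_error_counts_half(self):
        labels = [["N", "N", "N"], ["N", "S", "N"]]
        preds = [["N", "N", "N"], ["N", "V", "N"]]
        assert exact_match(preds, labels) == 0.5

    def test_absent_class_excluded_from_macro(self):
        rep = evaluate([["N", "N", "S"]], [["N", "N", "S"]])
        assert np.isnan(rep.per_class["V"]["f1"])
        assert rep.macro_f1 == pytest.approx(1.0)
        rep0 = evaluate([["N", "N", "S"]], [["N", "N", "S"]],
                        nan_excluded_from_macro=False)
        assert rep0.macro_f1 == pytest.approx(2 / 3)


class TestExcludeEnds:
    def test_only_middle_beat_counts_in_three_beat_graph(self):
        rep = evaluate([["V", "N", "V"]], [["N", "N", "N"]], exclude_ends=True)
        assert rep.acc == 1.0
        assert rep.confusion.sum() == 1

    def test_end_corruption_leaves_report_unchanged(self, rng):
        labels, clean, dirty = [], [], []
        for _ in range(50):
            n = int(rng.integers(3, 9))
            y = rng.integers(0, 3, n)
            p = y.copy()
            p[rng.integers(1, n - 1)] = rng.integers(0, 3)
            d = p.copy()
            d[0] = (d[0] + 1) % 3
            d[-1] = (d[-1] + 2) % 3
            labels.append(y)
            clean.append(p)
            dirty.append(d)
        a = evaluate(clean, labels, exclude_ends=True)
        b = evaluate(dirty, labels, exclude_ends=True)
        np.testing.assert_array_equal(a.confusion, b.confusion)
        assert exact_match(clean, labels, exclude_ends=True) == \
            exact_match(dirty, labels, exclude_ends=True)

    def test_end_only_error_counts_as_matched(self):
        assert exact_match([["V", "N", "N"]], [["N", "N", "N"]],
                           exclude_ends=True) == 1.0


class TestFolds:
    def test_ten_patients_five_equal_folds(self):
        split = interpatient_folds([f"p{i}" for i in range(10)], 5, seed=0)
        sizes = [len(split.fold_patients(f)) for f in range(5)]
        assert sizes == [2] * 5

    def test_partition_properties(self):
        ids = [f"p{i}" for i in range(13)]
        split = interpatient_folds(ids, 5, seed=1)
        folds = [split.fold_patients(f) for f in range(5)]
        assert set().union(*folds) == set(ids)
        assert sum(len(f) for f in folds) == 13
        assert max(len(f) for f in folds) - min(len(f) for f in folds) <= 1

    def test_too_few_patients_rejected(self):
        with pytest.raises(ValueError):
            interpatient_folds(["a", "b"], 5)


class TestTraining:
    def test_patient_overlap_rejected(self, small_graphs):
        with pytest.raises(ValueError, match="leakage"):
            train_model(ArchitectureConfig(), small_graphs, small_graphs[:2])

    def test_zero_lr_plateau_stops_after_patience(self, small_graphs):
        tr = [g for g in small_graphs if g.patient_id < "p008"]
        va = [g for g in small_graphs if g.patient_id >= "p008"]
        tc = TrainConfig(lr=0.0, max_epochs=100, patience=7)
        _, history = train_model(ArchitectureConfig(), tr, va, seed=0, train_cfg=tc)
        # epoch 0 sets the best loss; 7 non-improving epochs follow
        assert len(history) == 8

    def test_fixed_seed_reproduces_parameters(self, small_graphs):
        tr = [g for g in small_graphs if g.patient_id < "p008"]
        va = [g for g in small_graphs if g.patient_id >= "p008"]
        tc = TrainConfig(max_epochs=15, patience=15)
        m1, _ = train_model(ArchitectureConfig(), tr, va, seed=4, train_cfg=tc)
        m2, _ = train_model(ArchitectureConfig(), tr, va, seed=4, train_cfg=tc)
        for a, b in zip(m1.layers, m2.layers):
            for k in a.params:
                np.testing.assert_array_equal(a.params[k], b.params[k])

    def test_empty_training_set_rejected(self, small_graphs):
        with pytest.raises(ValueError, match="empty"):
            train_model(ArchitectureConfig(), [], small_graphs)


class TestEnsemble:
    def test_mean_of_identical_members_is_member(self, small_graphs):
        model = BeatClassifier(ArchitectureConfig(), seed=0)
        g = small_graphs[0]
        single = model.predict_proba(g).probs
        np.testing.assert_allclose(ensemble_predict([model, model], g).probs,
                                   single, atol=1e-15)

    def test_soft_voting_arithmetic_and_tie_break(self):
        a = BeatPrediction(np.array([[0.6, 0.3, 0.1]]))
        b = BeatPrediction(np.array([[0.2, 0.5, 0.3]]))
        mean = np.mean([a.probs, b.probs], axis=0)
        np.testing.assert_allclose(mean, [[0.4, 0.4, 0.2]])
        assert BeatPrediction(mean).label_names == ("N",)  # tie -> N < S < V

    def test_rows_remain_simplices(self, small_graphs):
        models = [BeatClassifier(ArchitectureConfig(), seed=s) for s in range(3)]
        pred = ensemble_predict(models, small_graphs[0])
        np.testing.assert_allclose(pred.probs.sum(axis=1), 1.0, atol=1e-12)

    def test_empty_ensemble_rejected(self, small_graphs):
        with pytest.raises(ValueError):
            ensemble_predict([], small_graphs[0])


class TestGridSearch:
    def test_single_cell_grid_wins(self, small_dataset):
        tc = TrainConfig(max_epochs=5, patience=5)
        best, cells = grid_search({"fc_hidden": [8]}, small_dataset, k=3,
                                  seed=0, train_cfg=tc)
        assert best.fc_hidden == 8
        assert len(cells) == 1 and not cells[0]["failed"]

    def test_broken_cell_reported_and_skipped(self, small_dataset):
        tc = TrainConfig(max_epochs=5, patience=5)
        best, cells = grid_search({"fc_hidden": [0, 8]}, small_dataset, k=3,
                                  seed=0, train_cfg=tc)
        assert best.fc_hidden == 8
        failed = [c for c in cells if c["failed"]]
        assert len(failed) == 1 and failed[0]["overrides"] == {"fc_hidden": 0}

    def test_winner_has_max_mean_macro_f1(self, small_dataset):
        tc = TrainConfig(max_epochs=8, patience=8)
        best, cells = grid_search({"fc_hidden": [4, 16]}, small_dataset, k=3,
                                  seed=0, train_cfg=tc)
        ok = [c for c in cells if not c["failed"]]
        assert max(c["macro_f1"] for c in ok) == \
            next(c["macro_f1"] for c in ok
                 if c["overrides"] == {"fc_hidden": best.fc_hidden})


def _rec(pid, rid, labels):
    fs = 100.0
    beats = []
    for i, lab in enumerate(labels):
        on = int((0.5 + i) * fs)
        segs = {"QRS": (on, on + 10), "T": (on + 20, on + 40)}
        beats.append(Beat(lab, segs))
    n = int(fs * 10) if len(labels) <= 9 else int(fs * (len(labels) + 1))
    return AnnotatedECGRecord(pid, rid, fs, np.zeros(n), tuple(beats))


class TestScalabilitySplits:
    def test_rule_applied_by_hand_on_toy_dataset(self):
        recs = [
            _rec("p1", "a", "NNNNNNNN"),
            _rec("p2", "a", "NNSNNVNN"),
            _rec("p3", "a", "NNNNSSSS"),   # qualifies -> p3 is a test patient
            _rec("p3", "b", "NNNNNNNN"),   # control
            _rec("p3", "c", "NNNNNNNNNNN"),  # >= 9 beats -> size
            _rec("p7", "a", "NVVVVNNN"),   # qualifies -> p7 is a test patient
            _rec("p7", "b", "NNSNNNNN"),   # control
        ]
        sp = scalability_splits(recs)
        assert sp.test_patients == {"p3", "p7"}
        assert {r.patient_id for r in sp.train_records} == {"p1", "p2"}
        assert [(r.patient_id, r.record_id) for r in sp.pattern] == \
            [("p3", "a"), ("p7", "a")]
        assert [(r.patient_id, r.record_id) for r in sp.size] == [("p3", "c")]
        assert [(r.patient_id, r.record_id) for r in sp.control] == \
            [("p3", "b"), ("p7", "b")]

    def test_all_s_run_without_n_does_not_qualify(self):
        recs = [_rec("p1", "a", "SSSSSSSS"), _rec("p2", "a", "NNNNSSSS")]
        sp = scalability_splits(recs)
        assert sp.test_patients == {"p2"}

    def test_no_qualifying_patient_rejected(self):
        with pytest.raises(ValueError, match="pattern"):
            scalability_splits([_rec("p1", "a", "NNNNNNNN")])
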