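"""Graph construction, edge weighting, and QRS-centered pooling."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ecg_graphnet import (GraphConfig, build_graph, build_qrs_graph,
                          edge_weight, qrs_centered_pool)
from ecg_graphnet.graphs import NodeMeta, extract_beat_subgraph, pooling_weights
from ecg_graphnet.synthetic import Beat, generate_record, MorphologyConfig

from oracle_helpers import naive_qrs_centered_pool, random_node_types


class TestEdgeWeight:
    def test_midpoint_is_half(self):
        assert edge_weight(0.3, alpha=10, delta0=0.3) == pytest.approx(0.5)

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(0.0, 5.0), st.floats(0.0, 5.0))
    def test_strictly_decreasing(self, a, b):
        lo, hi = sorted((a, b))
        if hi - lo > 1e-12:
            assert edge_weight(lo) > edge_weight(hi)

    def test_vanishes_for_large_gaps(self):
        assert edge_weight(50.0) < 1e-30

    def test_nonpositive_alpha_rejected(self):
        with pytest.raises(ValueError):
            edge_weight(0.5, alpha=0.0)
        with pytest.raises(ValueError):
            GraphConfig(alpha=-1.0)


def _n_record(rng, pattern="NNN"):
    return generate_record(pattern, MorphologyConfig(width_jitter=0.0), rng)


class TestBuildGraph:
    def test_three_complete_beats_node_and_edge_counts(self, rng, trained_aes):
        g = build_graph(_n_record(rng), trained_aes, GraphConfig(edges="none"))
        assert g.n_nodes == 9
        assert g.X.shape == (9, 22)
        assert np.all(np.diag(g.A) == 1.0)
        off = g.A - np.diag(np.diag(g.A))
        # chain of 8 chronologically adjacent undirected edges
        assert (off > 0).sum() == 16
        assert np.all(off[np.nonzero(off)] < 1.0)

    def test_qrs_window_pairs_for_four_beats(self, rng, trained_aes):
        g = build_graph(_n_record(rng, "NNNN"), trained_aes, GraphConfig(edges="qrs"))
        qrs = list(g.qrs_positions)
        assert len(qrs) == 4
        pairs = {(a, b) for a in range(4) for b in range(4) if a < b
                 and g.A[qrs[a], qrs[b]] > 0
                 and abs(qrs[a] - qrs[b]) > 1}
        assert pairs == {(0, 1), (0, 2), (1, 2), (1, 3), (2, 3)}

    def test_adjacency_symmetric_and_translation_invariant(self, rng, trained_aes):
        rec = _n_record(rng, "NSVN")
        g = build_graph(rec, trained_aes)
        np.testing.assert_array_equal(g.A, g.A.T)
        # shifting every annotation by a constant leaves weights unchanged
        shift = int(0.5 * rec.fs)
        beats = tuple(
            Beat(b.label, {k: (on + shift, off + shift)
                           for k, (on, off) in b.segments.items()})
            for b in rec.beats)
        rec2 = dataclasses.replace(
            rec, samples=np.concatenate([np.zeros(shift), rec.samples]),
            beats=beats)
        g2 = build_graph(rec2, trained_aes)
        np.testing.assert_allclose(g2.A, g.A, atol=1e-12)
        np.testing.assert_allclose(g2.X[:, 3], g.X[:, 3], atol=1e-12)
        np.testing.assert_allclose(g2.X[:, -2:], g.X[:, -2:], atol=1e-12)

    def test_dimension_constant_across_beat_counts(self, rng, trained_aes):
        for pattern in ("N", "NNNNN", "NSVNSVNSV"):
            g = build_graph(_n_record(rng, pattern), trained_aes)
            assert g.X.shape[1] == 22

    def test_removing_p_annotation_shrinks_by_one_node(self, rng, trained_aes):
        rec = _n_record(rng, "NNNN")
        g = build_graph(rec, trained_aes)
        beats = list(rec.beats)
        segs = dict(beats[2].segments)
        del segs["P"]
        beats[2] = Beat(beats[2].label, segs)
        g2 = build_graph(dataclasses.replace(rec, beats=tuple(beats)), trained_aes)
        assert g2.n_nodes == g.n_nodes - 1
        # an untouched far-away pair keeps its weight
        assert g2.A[0, 1] == pytest.approx(g.A[0, 1], abs=1e-12)

    def test_empty_record_rejected(self, trained_aes, rng):
        rec = dataclasses.replace(_n_record(rng), beats=())
        with pytest.raises(ValueError, match="no beats"):
            build_graph(rec, trained_aes)


class TestQRSGraph:
    def test_path_topology_and_monotone_weights(self, rng, trained_aes):
        g = build_graph(_n_record(rng, "N" * 8), trained_aes)
        qg = build_qrs_graph(g)
        assert qg.A.shape == (8, 8)
        assert np.all(np.diag(qg.A) == 1.0)
        off = qg.A - np.diag(np.diag(qg.A))
        assert (off > 0).sum() == 14  # 7 undirected consecutive edges
        assert np.array_equal(np.nonzero(off)[0],
                              np.sort(np.concatenate([np.arange(7), np.arange(1, 8)])))

    def test_shorter_rr_gets_larger_weight(self):
        cfg = GraphConfig()
        assert edge_weight(0.6, cfg.rr_alpha, cfg.rr_delta0) > \
            edge_weight(1.0, cfg.rr_alpha, cfg.rr_delta0)

    def test_single_beat_graph_has_self_loop_only(self, rng, trained_aes):
        g = build_graph(_n_record(rng, "N"), trained_aes)
        qg = build_qrs_graph(g)
        np.testing.assert_array_equal(qg.A, np.eye(1))


def _meta_from_types(types):
    out = []
    beat = 0
    for i, t in enumerate(types):
        if t == "QRS":
            beat += 1
        out.append(NodeMeta(t, beat, 0.3 * i, 0.3 * i + 0.2))
    return out


class TestPooling:
    def test_worked_scalar_case(self):
        types = ["P", "T", "QRS", "P", "T"]
        H = np.array([[1.0], [2.0], [3.0], [4.0], [5.0]])
        pm = qrs_centered_pool(H, _meta_from_types(types), c=0.1)
        assert pm.values[0, 0] == pytest.approx(2.64, abs=1e-12)
        assert pm.ks[0] == 2 and pm.js[0] == 2

    def test_isolated_qrs_returns_own_features(self):
        pm = qrs_centered_pool(np.array([[7.0, 1.0]]),
                               [NodeMeta("QRS", 0, 0.0, 0.1)], c=0.9)
        np.testing.assert_allclose(pm.values, [[7.0, 1.0]])

    def test_zero_decay_is_plain_average(self):
        types = ["P", "T", "P", "QRS", "T", "P", "T"]
        H = np.tile([[2.5, -1.0]], (7, 1))
        pm = qrs_centered_pool(H, _meta_from_types(types), c=0.0)
        np.testing.assert_allclose(pm.values, [[2.5, -1.0]])

    def test_matches_naive_loop_on_randomized_instances(self, rng):
        for _ in range(300):
            types = random_node_types(rng, int(rng.integers(1, 10)))
            H = rng.normal(size=(len(types), int(rng.integers(1, 6))))
            c = float(rng.uniform(0.0, 0.6))
            got = qrs_centered_pool(H, _meta_from_types(types), c).values
            want = naive_qrs_centered_pool(H, types, c)
            np.testing.assert_allclose(got, want, atol=1e-12)

    def test_weights_non_increasing_away_from_center(self, rng):
        types = random_node_types(rng, 6)
        rows, ks, js = pooling_weights(_meta_from_types(types), c=0.15)
        for row, k, j in zip(rows, ks, js):
            center = row[k][0]
            ws = {idx - center: w for idx, w in row}
            for off in range(1, max(k, j) + 1):
                for sgn in (-1, 1):
                    if sgn * off in ws and sgn * (off - 1) in ws:
                        assert ws[sgn * off] <= ws[sgn * (off - 1)] + 1e-15

    def test_no_qrs_rejected(self):
        with pytest.raises(ValueError, match="QRS"):
            qrs_centered_pool(np.ones((2, 1)), _meta_from_types(["P", "T"]), 0.1)

    def test_exclusive_mode_stops_short_of_neighbor_qrs(self):
        types = ["QRS", "P", "QRS", "P", "QRS"]
        H = np.arange(5, dtype=float)[:, None]
        rows, ks, js = pooling_weights(_meta_from_types(types), 0.0,
                                       inclusive=False)
        # middle beat reaches only the adjacent P nodes, not the QRS nodes
        assert (ks[1], js[1]) == (1, 1)
        assert [idx for idx, _ in rows[1]] == [1, 2, 3]


class TestSubgraphExtraction:
    def test_subgraph_rebuilds_invariants(self, small_graphs):
        g = next(g for g in small_graphs if g.n_beats >= 4)
        sub = extract_beat_subgraph(g, 1, 2)
        assert sub.n_beats == 2
        assert sub.X.shape[1] == 22
        np.testing.assert_array_equal(sub.A, sub.A.T)
        assert np.all(np.diag(sub.A) == 1.0)
        assert sub.X[0, -2] == 0.0 and sub.X[-1, -1] == 0.0
        assert sub.beat_labels == g.beat_labels[1:3]
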