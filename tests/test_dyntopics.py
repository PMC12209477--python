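"""Two-layer NMF, coherence scoring, model selection and topic series."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from discoursetrends.corpus import DocTermMatrix, TokenDoc, Vocabulary, build_dtm
from discoursetrends.dyntopics import (
    CoherenceTable,
    TopicSeries,
    coherence_tcw2v,
    doc_topic_distributions,
    filter_topics,
    fit_dynamic_nmf,
    fit_window_nmf,
    model_coherence,
    select_num_topics,
    stack_window_topics,
    topic_series,
)
from discoursetrends.trendstats import TrendResult, ols_trend
from discoursetrends.wordvec import EmbeddingModel

import scipy.sparse as sp


def _dtm(matrix, quarter=0, terms=None):
    m = np.asarray(matrix, dtype=float)
    terms = terms or [f"w{j}" for j in range(m.shape[1])]
    return DocTermMatrix(
        quarter_index=quarter,
        row_ids=[f"d{i}" for i in range(m.shape[0])],
        vocab=Vocabulary(terms),
        weights=sp.csr_matrix(m),
        weighting_scheme="count",
    )


class TestWindowNMF:
    def test_rank_one_exact(self):
        rng = np.random.default_rng(0)
        m = np.outer(rng.random(8) + 0.1, rng.random(12) + 0.1)
        wm = fit_window_nmf(_dtm(m), k_w=1, seed=0)
        rel_err = np.linalg.norm(m - wm.W @ wm.H) / np.linalg.norm(m)
        assert rel_err < 1e-6
        assert np.all(wm.W >= 0) and np.all(wm.H >= 0)

    def test_h_rows_unit_norm_scale_folded_into_w(self):
        rng = np.random.default_rng(1)
        m = rng.random((20, 30))
        wm = fit_window_nmf(_dtm(m), k_w=3, seed=0)
        np.testing.assert_allclose(np.linalg.norm(wm.H, axis=1), 1.0, atol=1e-10)

    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(2)
        m = rng.random((20, 30))
        a = fit_window_nmf(_dtm(m), k_w=3, seed=7)
        b = fit_window_nmf(_dtm(m), k_w=3, seed=7)
        np.testing.assert_array_equal(a.W, b.W)
        np.testing.assert_array_equal(a.H, b.H)

    def test_k_exceeding_shape_rejected(self):
        with pytest.raises(ValueError):
            fit_window_nmf(_dtm(np.ones((3, 5))), k_w=4, seed=0)

    def test_objective_nonincreasing_in_iterations(self):
        rng = np.random.default_rng(3)
        m = rng.random((30, 40))
        errs = []
        for it in (5, 20, 100, 400):
            wm = fit_window_nmf(_dtm(m), k_w=4, seed=0, max_iter=it)
            errs.append(np.linalg.norm(m - wm.W @ wm.H))
        assert all(e2 <= e1 + 1e-9 for e1, e2 in zip(errs, errs[1:]))

    def test_recovers_planted_quarter_topics(self, spec, truth, docs, vocab):
        q0 = [d for d in docs if d.quarter_index == 0]
        At = build_dtm(q0, vocab, "tfidf", quarter_index=0)
        wm = fit_window_nmf(At, k_w=6, seed=1)
        widx = {w: i for i, w in enumerate(truth.vocab)}
        P = np.array(
            [[truth.topic_term_dists[k, widx[t]] if t in widx else 0 for t in vocab.terms]
             for k in range(spec.K_true)]
        )
        Pn = P / np.linalg.norm(P, axis=1, keepdims=True)
        C = Pn @ wm.H.T  # H rows already unit norm
        rows, cols = linear_sum_assignment(-C)
        assert np.all(C[rows, cols] >= 0.8)


class TestStacking:
    def test_row_count_and_provenance(self):
        rng = np.random.default_rng(4)
        models = [
            fit_window_nmf(_dtm(rng.random((10, 12)), quarter=q), k_w=2, seed=0)
            for q in range(2)
        ]
        B = stack_window_topics(models)
        assert B.matrix.shape == (4, 12)
        assert B.provenance == [(0, 0), (0, 1), (1, 0), (1, 1)]

    def test_single_quarter_identity(self):
        rng = np.random.default_rng(5)
        wm = fit_window_nmf(_dtm(rng.random((10, 12))), k_w=3, seed=0)
        B = stack_window_topics([wm])
        np.testing.assert_array_equal(B.matrix, wm.H)

    def test_processing_order_invariant(self):
        rng = np.random.default_rng(6)
        models = [
            fit_window_nmf(_dtm(rng.random((10, 12)), quarter=q), k_w=2, seed=0)
            for q in range(3)
        ]
        B1 = stack_window_topics(models)
        B2 = stack_window_topics(models[::-1])
        np.testing.assert_array_equal(B1.matrix, B2.matrix)
        assert B1.provenance == B2.provenance

    def test_vocabulary_mismatch_rejected(self):
        rng = np.random.default_rng(7)
        a = fit_window_nmf(_dtm(rng.random((6, 4)), quarter=0), k_w=2, seed=0)
        b = fit_window_nmf(
            _dtm(rng.random((6, 4)), quarter=1, terms=["x0", "x1", "x2", "x3"]), k_w=2, seed=0
        )
        with pytest.raises(ValueError):
            stack_window_topics([a, b])


class TestDynamicNMF:
    def test_separated_topics_assigned_to_origin(self):
        # B built from 2 disjoint-support topics repeated across quarters
        h1 = np.array([1.0, 1.0, 0.0, 0.0]) / np.sqrt(2)
        h2 = np.array([0.0, 0.0, 1.0, 1.0]) / np.sqrt(2)
        rows, prov = [], []
        for q in range(4):
            rows += [h1, h2]
            prov += [(q, 0), (q, 1)]
        from discoursetrends.dyntopics import StackedTopicTermMatrix

        B = StackedTopicTermMatrix(np.vstack(rows), Vocabulary(["a", "b", "c", "d"]), prov)
        dyn = fit_dynamic_nmf(B, K=2, seed=0)
        labels = dyn.assignment.reshape(4, 2)
        assert np.all(labels[:, 0] == labels[0, 0]) and np.all(labels[:, 1] == labels[0, 1])
        assert labels[0, 0] != labels[0, 1]

    def test_full_rank_near_zero_error(self):
        rng = np.random.default_rng(8)
        from discoursetrends.dyntopics import StackedTopicTermMatrix

        M = rng.random((5, 9))
        B = StackedTopicTermMatrix(M, Vocabulary([f"w{j}" for j in range(9)]), [(0, j) for j in range(5)])
        dyn = fit_dynamic_nmf(B, K=5, seed=0, max_iter=20000, tol=1e-10)
        assert np.linalg.norm(M - dyn.W2 @ dyn.H2) / np.linalg.norm(M) < 1e-3

    def test_assignment_deterministic(self, fitted):
        dyn2 = fit_dynamic_nmf(fitted["B"], fitted["dyn"].K, seed=1)
        np.testing.assert_array_equal(dyn2.assignment, fitted["dyn"].assignment)


class TestCoherence:
    def test_identical_vectors_score_one(self):
        v = np.array([1.0, 2.0, 3.0])
        emb = EmbeddingModel({"a": v, "b": v, "c": v}, 3)
        assert coherence_tcw2v(["a", "b", "c"], emb) == pytest.approx(1.0)

    def test_orthogonal_vectors_score_zero(self):
        emb = EmbeddingModel({"a": np.array([1.0, 0.0]), "b": np.array([0.0, 1.0])}, 2)
        assert coherence_tcw2v(["a", "b"], emb) == pytest.approx(0.0)

    def test_hand_computed_three_vectors(self):
        vs = {
            "a": np.array([1.0, 0.0]),
            "b": np.array([1.0, 1.0]),
            "c": np.array([0.0, 1.0]),
        }
        emb = EmbeddingModel(vs, 2)

        def cos(u, v):
            return float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))

        expected = np.mean([cos(vs["a"], vs["b"]), cos(vs["a"], vs["c"]), cos(vs["b"], vs["c"])])
        assert coherence_tcw2v(["a", "b", "c"], emb) == pytest.approx(expected, abs=1e-12)

    def test_bounded_and_missing_terms_dropped(self):
        rng = np.random.default_rng(9)
        emb = EmbeddingModel({f"w{i}": rng.normal(size=5) for i in range(10)}, 5)
        s = coherence_tcw2v([f"w{i}" for i in range(10)] + ["missing"], emb)
        assert -1.0 <= s <= 1.0

    def test_fewer_than_two_embedded_terms_undefined(self):
        emb = EmbeddingModel({"a": np.ones(2)}, 2)
        assert coherence_tcw2v(["a", "zz"], emb) is None


class TestSelection:
    def test_tie_breaks_to_smallest_k(self, fitted):
        # every term embedded identically -> all scores 1.0 -> minimum K wins
        v = np.ones(4)
        emb = EmbeddingModel({t: v for t in fitted["B"].vocab.terms}, 4)
        k_best, table = select_num_topics(fitted["B"], (2, 5), emb, seed=1)
        assert k_best == 2
        assert all(s == pytest.approx(1.0) for s in table.entries.values())

    def test_table_covers_range_once(self, fitted, embeddings):
        k_best, table = select_num_topics(fitted["B"], (2, 6), embeddings, seed=1)
        assert table.evaluated_range == [2, 3, 4, 5, 6]
        assert sorted(table.entries) == [2, 3, 4, 5, 6]
        assert k_best in table.entries

    def test_empty_range_rejected(self, fitted, embeddings):
        with pytest.raises(ValueError):
            select_num_topics(fitted["B"], (50, 60), embeddings, seed=1)


class TestDocDistributions:
    def test_pure_document_gets_indicator(self):
        # single window topic wholly assigned to one dynamic topic
        rng = np.random.default_rng(10)
        m = np.outer(rng.random(6) + 0.5, rng.random(8) + 0.5)
        wm = fit_window_nmf(_dtm(m), k_w=1, seed=0)
        B = stack_window_topics([wm])
        dyn = fit_dynamic_nmf(B, K=1, seed=0)
        dists, _, _ = doc_topic_distributions([wm], dyn)
        np.testing.assert_allclose(dists, 1.0)

    def test_distributions_sum_to_one(self, fitted):
        np.testing.assert_allclose(fitted["dists"].sum(axis=1), 1.0, atol=1e-9)
        assert np.all(fitted["dists"] >= 0)

    def test_dominant_topic_recovery(self, fitted, truth, matched_topics):
        _, rec_to_planted = matched_topics
        sel = [
            (i, did)
            for i, did in enumerate(fitted["doc_ids"])
            if truth.doc_mixtures[did].max() >= 0.9
        ]
        assert len(sel) > 100
        correct = [
            rec_to_planted[int(np.argmax(fitted["dists"][i]))] == truth.doc_dominant[did]
            for i, did in sel
        ]
        assert np.mean(correct) >= 0.9


class TestTopicSeries:
    def test_two_doc_split(self):
        dists = np.array([[1.0, 0.0], [0.0, 1.0]])
        series = topic_series(dists, np.array([0, 0]))
        assert series[0].per_quarter_pct == [50.0]
        assert series[1].per_quarter_pct == [50.0]

    def test_per_quarter_sums_to_100(self, fitted):
        series = topic_series(fitted["dists"], fitted["q_per_doc"])
        for qi in range(len(series[0].quarters)):
            total = sum(s.per_quarter_pct[qi] for s in series)
            assert total == pytest.approx(100.0, abs=1e-6)

    def test_recovered_prevalence_tracks_planted(self, fitted, truth, matched_topics):
        series = topic_series(fitted["dists"], fitted["q_per_doc"])
        _, rec_to_planted = matched_topics
        for s in series:
            planted = truth.prevalence[:, rec_to_planted[s.dynamic_topic_id]] * 100
            # mean absolute deviation small relative to the 0-100 scale
            assert np.mean(np.abs(np.array(s.per_quarter_pct) - planted)) < 5.0


class TestFilterTopics:
    def _series(self, tid, mean):
        return TopicSeries(tid, [0], [mean], overall_mean_pct=mean)

    def _trend(self, r2):
        return TrendResult(0, 0, r2, 0.5, 8, 1.0)

    def test_mean_threshold_edge(self):
        series = [self._series(0, 3.4), self._series(1, 3.5)]
        trends = {0: self._trend(0.5), 1: self._trend(0.5)}
        s1, s2 = filter_topics(series, trends)
        assert s1 == [1] and s2 == [1]

    def test_trend_stage(self):
        series = [self._series(0, 5.0)]
        s1, s2 = filter_topics(series, {0: self._trend(0.05)})
        assert s1 == [0] and s2 == []

    def test_matches_bruteforce_thresholds(self):
        rng = np.random.default_rng(11)
        series = [self._series(i, float(rng.uniform(0, 10))) for i in range(40)]
        trends = {i: self._trend(float(rng.uniform(0, 0.4))) for i in range(40)}
        s1, s2 = filter_topics(series, trends, min_mean_pct=3.5, min_r2=0.1)
        b1 = [s.dynamic_topic_id for s in series if s.overall_mean_pct >= 3.5]
        b2 = [i for i in b1 if trends[i].r_squared > 0.1]
        assert s1 == b1 and s2 == b2
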