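"""Metric suite: F1/confusion, TP/FP entropy, state matching, homogeneity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ethoseg.evaluation import (UNMATCHED, apply_state_map, entropy_report,
                                f1_report, homogeneity, latent_cluster_scores,
                                match_states)
from ethoseg.features import LabelSequence


def _ls(labels, K=None):
    K = K or int(max(labels)) + 1
    return LabelSequence(np.asarray(labels), [f"c{i}" for i in range(K)])


class TestF1:
    def test_perfect_prediction_scores_one(self):
        y = np.array([0, 1, 2, 0, 1, 2])
        rep = f1_report(y, _ls(y))
        assert rep.macro_f1 == 1.0
        assert np.all(rep.f1 == 1.0)

    def test_binary_half_precision_full_recall(self):
        labels = np.array([1, 1, 0, 0])
        pred = np.array([1, 1, 1, 1])
        rep = f1_report(pred, _ls(labels, K=2))
        assert np.isclose(rep.precision[1], 0.5)
        assert np.isclose(rep.recall[1], 1.0)
        assert np.isclose(rep.f1[1], 2 / 3)

    def test_never_predicted_class_scores_zero(self):
        labels = np.array([0, 1, 0, 1])
        pred = np.array([0, 0, 0, 0])
        rep = f1_report(pred, _ls(labels, K=2))
        assert rep.f1[1] == 0.0

    def test_confusion_rows_conserve_labeled_counts(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(-1, 3, size=200)
        pred = rng.integers(0, 3, size=200)
        ls = _ls(labels, K=3)
        rep = f1_report(pred, ls)
        counts = np.bincount(labels[labels >= 0], minlength=3)
        assert np.array_equal(rep.confusion.sum(axis=1), counts)

    def test_unlabeled_and_background_frames_are_excluded(self):
        labels = np.array([0, -1, -2, 1])
        pred = np.array([0, 1, 0, 1])
        rep = f1_report(pred, _ls(labels, K=2))
        assert rep.confusion.sum() == 2
        assert rep.macro_f1 == 1.0

    def test_empty_labeled_set_raises(self):
        with pytest.raises(ValueError, match="empty labeled set"):
            f1_report(np.array([0, 0]), _ls([-1, -1], K=2))

    def test_permuting_classes_permutes_the_report(self):
        rng = np.random.default_rng(1)
        labels = rng.integers(0, 3, size=300)
        pred = rng.integers(0, 3, size=300)
        rep = f1_report(pred, _ls(labels, K=3))
        perm = np.array([2, 0, 1])
        rep_p = f1_report(perm[pred], _ls(perm[labels], K=3))
        assert np.isclose(rep.macro_f1, rep_p.macro_f1)
        assert np.allclose(rep.f1[[0, 1, 2]], rep_p.f1[perm[[0, 1, 2]]])


class TestEntropyReport:
    def test_one_hot_rows_have_zero_entropy(self):
        probs = np.eye(3)[[0, 1, 2, 0]]
        labels = np.array([0, 1, 2, 0])
        tp, fp = entropy_report(probs, labels, _ls(labels))
        assert all(np.isclose(v, 0.0) for v in tp.values())
        assert fp == {}

    def test_uniform_rows_hit_log_k(self):
        K = 5
        probs = np.full((4, K), 1.0 / K)
        labels = np.array([0, 1, 2, 3])
        pred = np.array([0, 1, 2, 3])
        tp, _ = entropy_report(probs, pred, _ls(labels, K=K))
        for v in tp.values():
            assert np.isclose(v, np.log(5), atol=1e-12)

    def test_toy_case_matches_hand_computation(self):
        def H(p):
            p = np.asarray(p, float)
            return float(-(p[p > 0] * np.log(p[p > 0])).sum())

        probs = np.array([[1.0, 0.0], [0.5, 0.5], [0.9, 0.1],
                          [0.8, 0.2], [0.6, 0.4], [0.3, 0.7]])
        labels = np.array([0, 0, 1, 1, 0, -1])
        pred = np.array([0, 1, 1, 0, 0, 0])
        tp, fp = entropy_report(probs, pred, _ls(labels, K=2))
        assert np.isclose(tp[0], (H([1, 0]) + H([0.6, 0.4])) / 2)
        assert np.isclose(fp[0], H([0.8, 0.2]))
        assert np.isclose(tp[1], H([0.9, 0.1]))
        assert np.isclose(fp[1], H([0.5, 0.5]))

    def test_empty_sets_are_absent_not_zero(self):
        probs = np.array([[0.9, 0.1]])
        labels = np.array([0])
        pred = np.array([0])
        tp, fp = entropy_report(probs, pred, _ls(labels, K=2))
        assert 1 not in tp and 1 not in fp and fp == {}


class TestMatchStates:
    def test_argmax_overlap_mapping(self):
        # state 1 overlaps class A 10/2, state 2 overlaps B 0/7
        labels = np.array([0] * 10 + [1] * 2 + [1] * 7)
        states = np.array([1] * 12 + [2] * 7)
        mapping = match_states(states, _ls(labels, K=2))
        assert mapping == {1: 0, 2: 1}

    def test_ties_break_to_lowest_class_index(self):
        labels = np.array([0, 1, 1, 0])
        states = np.array([3, 3, 3, 3])
        assert match_states(states, _ls(labels, K=2)) == {3: 0}

    def test_states_without_labeled_overlap_are_unmatched(self):
        labels = np.array([0, 0, -1, -1])
        states = np.array([1, 1, 9, 9])
        mapping = match_states(states, _ls(labels, K=2))
        assert mapping[9] == UNMATCHED
        mapped = apply_state_map(states, mapping)
        assert list(mapped) == [0, 0, UNMATCHED, UNMATCHED]


class TestHomogeneity:
    def test_pure_clusters_score_one(self):
        assert homogeneity([0, 0, 1, 1, 2], [5, 5, 3, 3, 1]) == 1.0

    def test_single_mixed_cluster_scores_zero(self):
        assert homogeneity([0, 0, 0, 0], [0, 0, 1, 1]) == 0.0

    def test_count_table_3113_matches_direct_entropy_computation(self):
        # clusters x classes counts [[3,1],[1,3]]
        clusters = np.array([0] * 4 + [1] * 4)
        classes = np.array([0, 0, 0, 1, 0, 1, 1, 1])
        h_cond = -(0.75 * np.log(0.75) + 0.25 * np.log(0.25))
        expected = 1 - h_cond / np.log(2)  # ~0.18872
        assert np.isclose(homogeneity(clusters, classes), expected, atol=1e-9)
        assert np.isclose(expected, 0.1887, atol=5e-4)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10 ** 6))
    def test_invariant_to_cluster_relabeling(self, seed):
        rng = np.random.default_rng(seed)
        clusters = rng.integers(0, 4, size=60)
        classes = rng.integers(0, 3, size=60)
        perm = rng.permutation(4)
        assert np.isclose(homogeneity(clusters, classes),
                          homogeneity(perm[clusters], classes), atol=1e-12)

    def test_duplicating_every_point_leaves_score_unchanged(self):
        rng = np.random.default_rng(2)
        clusters = rng.integers(0, 3, size=50)
        classes = rng.integers(0, 2, size=50)
        base = homogeneity(clusters, classes)
        doubled = homogeneity(np.repeat(clusters, 2), np.repeat(classes, 2))
        assert np.isclose(base, doubled, atol=1e-12)


class TestLatentClusterScores:
    def test_one_hot_class_indicators_are_perfectly_homogeneous(self):
        rng = np.random.default_rng(3)
        classes = rng.integers(0, 3, size=120)
        latents = np.eye(3)[classes]
        scores = latent_cluster_scores(latents, _ls(classes), [3], seed=0)
        assert np.isclose(scores[3], 1.0)

    def test_pure_noise_latents_score_near_zero(self):
        rng = np.random.default_rng(4)
        n = 3000
        classes = rng.integers(0, 2, size=n)
        latents = rng.standard_normal((n, 4))
        scores = latent_cluster_scores(latents, _ls(classes, K=2), [4], seed=0)
        assert scores[4] < 0.05

    def test_cluster_count_exceeding_points_raises(self):
        with pytest.raises(ValueError):
            latent_cluster_scores(np.zeros((3, 2)), _ls([0, 1, 0], K=2), [10])
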