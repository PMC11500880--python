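"""Fusion rules: weighted average, baselines, top-k selection."""

import numpy as np
import pytest

from igpa import (
    FIXED_WEIGHT_PROFILES,
    LabelVector,
    PredictionMatrix,
    WeightVector,
    correctness,
    fixed_weight_average,
    igpa_ensemble,
    majority_vote,
    select_top_k,
    softmax_average,
    weighted_average,
)
from conftest import random_prediction


def pm(rows, names=("a", "b"), source_id=""):
    return PredictionMatrix(np.asarray(rows, dtype=float), names, source_id)


def naive_weighted_average(preds, weights):
    out = np.zeros_like(preds[0].probs)
    for j in range(preds[0].n_samples):
        for k in range(preds[0].n_classes):
            out[j, k] = sum(w * p.probs[j, k] for w, p in zip(weights, preds))
    return out


def naive_majority_vote(preds):
    n, k = preds[0].n_samples, preds[0].n_classes
    winners = []
    for j in range(n):
        votes = [int(np.argmax(p.probs[j])) for p in preds]
        counts = [votes.count(c) for c in range(k)]
        top = max(counts)
        tied = [c for c in range(k) if counts[c] == top]
        if len(tied) > 1:
            mass = [sum(p.probs[j, c] for p in preds) for c in tied]
            best = max(mass)
            tied = [c for c, m in zip(tied, mass) if m == best]
        winners.append(min(tied))
    return winners


class TestWeightedAverage:
    def test_identical_inputs_fixed_point(self, rng):
        p = random_prediction(rng, 20, 3)
        w = WeightVector(np.array([0.5, 0.3, 0.2]))
        fused = weighted_average(
            [p, PredictionMatrix(p.probs, p.class_names), PredictionMatrix(p.probs, p.class_names)], w
        )
        assert np.allclose(fused.probs, p.probs)

    def test_single_matrix_identity(self, rng):
        p = random_prediction(rng, 10, 4)
        fused = weighted_average([p], WeightVector(np.array([1.0])))
        assert np.allclose(fused.probs, p.probs)

    def test_hand_example(self):
        fused = weighted_average(
            [pm([[1, 0]]), pm([[0, 1]])], WeightVector(np.array([0.75, 0.25]))
        )
        assert np.allclose(fused.probs, [[0.75, 0.25]])

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            weighted_average(
                [random_prediction(rng, 5, 2), random_prediction(rng, 5, 3)],
                WeightVector(np.array([0.5, 0.5])),
            )

    def test_matches_naive_loop_and_row_stochastic(self, rng):
        for _ in range(25):
            m = int(rng.integers(1, 11))
            n = int(rng.integers(1, 201))
            k = int(rng.integers(2, 8))
            preds = [random_prediction(rng, n, k, f"c{i}") for i in range(m)]
            raw = rng.random(m) + 1e-9
            w = WeightVector(raw / raw.sum())
            fused = weighted_average(preds, w)
            assert np.allclose(fused.probs, naive_weighted_average(preds, w.weights), atol=1e-12)
            assert np.allclose(fused.probs.sum(axis=1), 1.0, atol=1e-9)


class TestSoftmaxAverage:
    def test_midpoint(self):
        fused = softmax_average([pm([[1, 0]]), pm([[0, 1]])])
        assert np.allclose(fused.probs, [[0.5, 0.5]])

    def test_equals_uniform_weighted_average(self, rng):
        preds = [random_prediction(rng, 50, 4, f"c{i}") for i in range(5)]
        uniform = WeightVector(np.full(5, 0.2))
        assert np.allclose(
            softmax_average(preds).probs,
            weighted_average(preds, uniform).probs,
            atol=1e-12,
        )


class TestIgpaEnsemble:
    def test_single_classifier_identity(self, rng):
        p = random_prediction(rng, 30, 3, "only")
        truth = LabelVector(rng.integers(0, 3, size=30))
        fused, w = igpa_ensemble([p], truth)
        assert np.allclose(fused.probs, p.probs)
        assert w.weights.tolist() == [1.0]

    def test_equal_accuracy_reduces_to_mean(self, rng):
        # same correctness pattern => identical IG => uniform weights
        names = ("a", "b", "c")
        truth = LabelVector(rng.integers(0, 3, size=40))
        preds = []
        for i in range(3):
            probs = np.full((40, 3), 0.1)
            for j, t in enumerate(truth.labels):
                probs[j, t] = 0.8  # all classifiers correct everywhere
            noise = rng.dirichlet(np.ones(3) * 50, size=40) * 0.0
            probs = probs + noise
            probs /= probs.sum(axis=1, keepdims=True)
            preds.append(PredictionMatrix(probs, names, f"c{i}"))
        fused, w = igpa_ensemble(preds, truth)
        assert np.allclose(w.weights, 1 / 3, atol=1e-12)
        assert np.allclose(fused.probs, softmax_average(preds).probs, atol=1e-9)

    def test_superior_classifier_dominates(self, simulated_bank):
        preds, truth = simulated_bank
        fused, w = igpa_ensemble(preds, truth)
        assert w.weights[0] > w.weights[1]
        assert w.weights[0] > w.weights[2]

    def test_weighting_rows_match_explicit_slicing(self, simulated_bank):
        # weights from a validation subset equal weights computed on the
        # sliced matrices, while fusion still covers every row
        preds, truth = simulated_bank
        rows = np.arange(0, 2000, 3)
        sub_truth = LabelVector(truth.labels[rows])
        fused, w = igpa_ensemble(preds, sub_truth, weighting_rows=rows)
        sliced = [
            PredictionMatrix(p.probs[rows], p.class_names, p.source_id)
            for p in preds
        ]
        _, w_ref = igpa_ensemble(sliced, sub_truth)
        assert np.allclose(w.weights, w_ref.weights, atol=1e-12)
        assert fused.probs.shape == preds[0].probs.shape


class TestMajorityVote:
    def test_strict_majority(self):
        preds = [pm([[0.9, 0.1]], source_id="x"), pm([[0.8, 0.2]]), pm([[0.1, 0.9]])]
        labels, one_hot = majority_vote(preds)
        assert labels.labels.tolist() == [0]
        assert one_hot.probs.tolist() == [[1.0, 0.0]]

    def test_tie_broken_by_summed_probability(self):
        preds = [pm([[0.7, 0.3]]), pm([[0.4, 0.6]])]
        labels, _ = majority_vote(preds)
        # votes 0 vs 1; mass 1.1 vs 0.9 -> class 0
        assert labels.labels.tolist() == [0]

    def test_identical_classifiers_vote_own_labels(self, rng):
        p = random_prediction(rng, 25, 4, "p")
        labels, _ = majority_vote([p, PredictionMatrix(p.probs, p.class_names)])
        assert labels.labels.tolist() == p.hard_labels().tolist()

    def test_matches_naive_loop(self, rng):
        for _ in range(25):
            m = int(rng.integers(1, 11))
            n = int(rng.integers(1, 201))
            k = int(rng.integers(2, 8))
            preds = [random_prediction(rng, n, k, f"c{i}") for i in range(m)]
            labels, _ = majority_vote(preds)
            assert labels.labels.tolist() == naive_majority_vote(preds)


class TestFixedWeightAverage:
    def test_profiles_match_printed_percentages(self):
        assert FIXED_WEIGHT_PROFILES["wa4"] == (0.30, 0.26, 0.24, 0.20)
        assert FIXED_WEIGHT_PROFILES["wa3"] == (0.35, 0.35, 0.30)

    def test_identical_classifiers_fixed_point(self, rng):
        p = random_prediction(rng, 20, 3, "p0")
        preds = [
            PredictionMatrix(p.probs, p.class_names, f"p{i}") for i in range(4)
        ]
        truth = LabelVector(rng.integers(0, 3, size=20))
        fused = fixed_weight_average(preds, truth, "wa4")
        assert np.allclose(fused.probs, p.probs, atol=1e-12)

    def test_wa4_rank_assignment(self, rng):
        # accuracies in input order (0.7, 0.9, 0.8, 0.6) -> (0.24, 0.30, 0.26, 0.20)
        truth = LabelVector(np.zeros(10, dtype=int))
        accs = (0.7, 0.9, 0.8, 0.6)
        preds = []
        for i, a in enumerate(accs):
            probs = np.tile([0.9, 0.1], (10, 1))
            wrong = int(round((1 - a) * 10))
            probs[:wrong] = [0.1, 0.9]
            preds.append(PredictionMatrix(probs, ("a", "b"), f"p{i}"))
        measured = [correctness(p, truth).accuracy for p in preds]
        assert measured == pytest.approx(list(accs))
        fused = fixed_weight_average(preds, truth, "wa4")
        expected = naive_weighted_average(preds, [0.24, 0.30, 0.26, 0.20])
        assert np.allclose(fused.probs, expected, atol=1e-12)

    def test_wrong_count_rejected(self, rng):
        preds = [random_prediction(rng, 5, 2, f"p{i}") for i in range(3)]
        truth = LabelVector(np.zeros(5, dtype=int))
        with pytest.raises(ValueError, match="exactly 4"):
            fixed_weight_average(preds, truth, "wa4")

    def test_custom_weight_sequence(self, rng):
        preds = [random_prediction(rng, 8, 2, f"p{i}") for i in range(2)]
        truth = LabelVector(np.zeros(8, dtype=int))
        fused = fixed_weight_average(preds, truth, profile=(0.9, 0.1))
        assert fused.probs.shape == (8, 2)


class TestSelectTopK:
    @staticmethod
    def bank(accs, rng, ids=None):
        truth = LabelVector(np.zeros(100, dtype=int))
        preds = []
        for i, a in enumerate(accs):
            probs = np.tile([0.9, 0.1], (100, 1))
            probs[: int(round((1 - a) * 100))] = [0.1, 0.9]
            sid = ids[i] if ids else f"p{i}"
            preds.append(PredictionMatrix(probs, ("a", "b"), sid))
        return preds, truth

    def test_k_equals_all_identity(self, rng):
        preds, truth = self.bank((0.9, 0.8), rng)
        assert select_top_k(preds, truth, 2) == preds

    def test_selects_highest_accuracy_preserving_order(self, rng):
        preds, truth = self.bank((0.92, 0.90, 0.93, 0.91), rng)
        kept = select_top_k(preds, truth, 3)
        assert [p.source_id for p in kept] == ["p0", "p2", "p3"]

    def test_tie_broken_lexicographically(self, rng):
        preds, truth = self.bank((0.9, 0.9), rng, ids=["zz", "aa"])
        kept = select_top_k(preds, truth, 1)
        assert kept[0].source_id == "aa"

    def test_k_out_of_range(self, rng):
        preds, truth = self.bank((0.9,), rng)
        with pytest.raises(ValueError):
            select_top_k(preds, truth, 2)
        with pytest.raises(ValueError):
            select_top_k(preds, truth, 0)
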