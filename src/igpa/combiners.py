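"""Prediction fusion rules.

The headline combiner is :func:`igpa_ensemble` — information-gain
proportioned weighted averaging — alongside the classical baselines it is
compared against: unweighted softmax averaging, majority voting, and
fixed-profile weighted averaging where ranks get preset percentages.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .core import (
    CorrectnessVector,
    LabelVector,
    PredictionMatrix,
    WeightVector,
    correctness,
    igpa_weights,
    information_gain,
)

__all__ = [
    "weighted_average",
    "igpa_ensemble",
    "softmax_average",
    "majority_vote",
    "fixed_weight_average",
    "FIXED_WEIGHT_PROFILES",
    "select_top_k",
]

# Rank-ordered (best -> worst) preset weights for the fixed baselines.
FIXED_WEIGHT_PROFILES: dict[str, tuple[float, ...]] = {
    "wa4": (0.30, 0.26, 0.24, 0.20),
    "wa3": (0.35, 0.35, 0.30),
}


def _check_aligned(preds: Sequence[PredictionMatrix]) -> None:
    if len(preds) == 0:
        raise ValueError("need at least one prediction matrix")
    ref = preds[0]
    for p in preds[1:]:
        if p.probs.shape != ref.probs.shape:
            raise ValueError(
                f"shape mismatch: {p.source_id or '?'} {p.probs.shape} vs "
                f"{ref.source_id or '?'} {ref.probs.shape}"
            )
        if p.class_names != ref.class_names:
            raise ValueError("class_names differ between prediction matrices")


def weighted_average(
    preds: Sequence[PredictionMatrix], w: WeightVector, source_id: str = "ensemble"
) -> PredictionMatrix:
    """Convex combination of probability matrices: E[j,k] = sum_i w_i p_i[j,k]."""
    _check_aligned(preds)
    if len(w) != len(preds):
        raise ValueError(f"{len(w)} weights for {len(preds)} matrices")
    stacked = np.stack([p.probs for p in preds])
    fused = np.tensordot(w.weights, stacked, axes=1)
    return PredictionMatrix(fused, preds[0].class_names, source_id=source_id)


def _weighting_view(p: PredictionMatrix, rows) -> PredictionMatrix:
    if rows is None:
        return p
    return PredictionMatrix(p.probs[rows], p.class_names, p.source_id)


def igpa_ensemble(
    preds: Sequence[PredictionMatrix],
    weighting_truth: LabelVector,
    alpha: float = 1.0,
    h_prior: float = 1.0,
    mode: str = "multiplicative",
    source_id: str = "igpa",
    weighting_rows: np.ndarray | None = None,
) -> tuple[PredictionMatrix, WeightVector]:
    """Fuse classifier outputs with information-gain proportioned weights.

    Pipeline: correctness bits on the weighting labels -> entropy-gap
    information gain at level ``alpha`` -> normalised weights -> weighted
    average.  Returns the fused matrix together with the weights so every
    report can audit the arithmetic.

    ``weighting_rows`` restricts the correctness computation to a subset of
    rows (e.g. a validation partition, keeping held-out rows leak-free)
    while the fusion still covers every row; ``weighting_truth`` must then
    align with that subset.
    """
    _check_aligned(preds)
    scores = [
        information_gain(
            correctness(_weighting_view(p, weighting_rows), weighting_truth),
            alpha,
            h_prior,
            mode,
        )
        for p in preds
    ]
    w = igpa_weights(scores)
    return weighted_average(preds, w, source_id=source_id), w


def softmax_average(
    preds: Sequence[PredictionMatrix], source_id: str = "softmax_avg"
) -> PredictionMatrix:
    """Unweighted arithmetic mean of the probability matrices."""
    _check_aligned(preds)
    uniform = WeightVector(
        np.full(len(preds), 1.0 / len(preds)), tuple(p.source_id for p in preds)
    )
    return weighted_average(preds, uniform, source_id=source_id)


def majority_vote(
    preds: Sequence[PredictionMatrix], source_id: str = "majority_vote"
) -> tuple[LabelVector, PredictionMatrix]:
    """Modal hard-label vote across classifiers.

    Each classifier votes its max-probability class.  Vote ties resolve by
    the larger total probability mass over the tied classes, then by the
    lowest class index.  Returns the winning labels and their one-hot
    encoding as a degenerate probability matrix.
    """
    _check_aligned(preds)
    n, k = preds[0].n_samples, preds[0].n_classes
    votes = np.stack([p.hard_labels() for p in preds])  # (m, n)
    counts = np.zeros((n, k), dtype=int)
    for row in votes:
        counts[np.arange(n), row] += 1
    mass = np.sum([p.probs for p in preds], axis=0)  # (n, k) tie-break score
    top = counts.max(axis=1, keepdims=True)
    tied = counts == top
    # among tied classes, prefer larger summed probability, then lower index
    tie_score = np.where(tied, mass, -np.inf)
    winners = np.argmax(tie_score, axis=1)
    one_hot = np.zeros((n, k))
    one_hot[np.arange(n), winners] = 1.0
    return (
        LabelVector(winners, n_classes=k),
        PredictionMatrix(one_hot, preds[0].class_names, source_id=source_id),
    )


def _rank_by_accuracy(
    preds: Sequence[PredictionMatrix], truth: LabelVector
) -> list[int]:
    """Indices sorted best-first by accuracy; ties by source_id, then position."""
    accs = [correctness(p, truth).accuracy for p in preds]
    return sorted(
        range(len(preds)), key=lambda i: (-accs[i], preds[i].source_id, i)
    )


def fixed_weight_average(
    preds: Sequence[PredictionMatrix],
    ranking_truth: LabelVector,
    profile: str | Sequence[float] = "wa4",
    source_id: str | None = None,
) -> PredictionMatrix:
    """Weighted average with preset rank-based weights.

    Profile ``wa4`` (exactly 4 classifiers) assigns 30/26/24/20 % from best
    to worst; ``wa3`` (exactly 3) assigns 35/35/30 %.  An explicit weight
    sequence (best -> worst) is also accepted.
    """
    _check_aligned(preds)
    if isinstance(profile, str):
        try:
            rank_weights = FIXED_WEIGHT_PROFILES[profile]
        except KeyError:
            raise ValueError(f"unknown profile {profile!r}") from None
        name = profile
    else:
        rank_weights = tuple(float(x) for x in profile)
        name = "custom"
    if len(preds) != len(rank_weights):
        raise ValueError(
            f"profile {name!r} needs exactly {len(rank_weights)} classifiers, "
            f"got {len(preds)}"
        )
    order = _rank_by_accuracy(preds, ranking_truth)
    weights = np.empty(len(preds))
    for rank, idx in enumerate(order):
        weights[idx] = rank_weights[rank]
    w = WeightVector(weights / weights.sum(), tuple(p.source_id for p in preds))
    return weighted_average(preds, w, source_id=source_id or name)


def select_top_k(
    preds: Sequence[PredictionMatrix], truth: LabelVector, k: int
) -> list[PredictionMatrix]:
    """Keep the k most accurate classifiers, preserving input order.

    Accuracy ties break toward the lexicographically smaller ``source_id``.
    """
    if not 1 <= k <= len(preds):
        raise ValueError(f"k={k} out of range for {len(preds)} classifiers")
    keep = set(_rank_by_accuracy(preds, truth)[:k])
    return [p for i, p in enumerate(preds) if i in keep]
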