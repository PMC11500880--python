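"""Information-gain proportioned classifier weighting.

The weighting scheme scores each classifier by how much the binary
correct/incorrect indicator of its predictions reduces entropy relative to
a reference ("no information") state, then normalises those scores into a
convex weight vector.  For a classifier with empirical accuracy ``a`` the
score is

    IG = alpha * max(0, H_prior - H(a)),        H(a) = binary entropy in bits

and the weight of classifier *i* among *m* classifiers is
``IG_i / sum_j IG_j``.  ``alpha`` is the ensemble level; because it enters
multiplicatively it cancels in the normalisation (the *faithful* mode).  An
opt-in *exponent* mode computes ``(H_prior - H(a)) ** alpha`` instead, which
amplifies the dominance of stronger classifiers as the level grows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "PredictionMatrix",
    "LabelVector",
    "CorrectnessVector",
    "InformationGainScore",
    "WeightVector",
    "IGPAWarning",
    "binary_entropy",
    "correctness",
    "information_gain",
    "igpa_weights",
]

ROW_SUM_TOL = 1e-6
WEIGHT_SUM_TOL = 1e-9


class IGPAWarning(UserWarning):
    """Raised when a weighting falls into a degenerate or ambiguous regime."""


@dataclass(frozen=True)
class PredictionMatrix:
    """Per-classifier class-probability output.

    ``probs`` is an (n_samples, n_classes) row-stochastic matrix;
    ``class_names`` fixes the column order; ``source_id`` identifies the
    classifier that produced the rows.
    """

    probs: np.ndarray
    class_names: tuple[str, ...]
    source_id: str = ""

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "class_names", tuple(str(c) for c in self.class_names))
        if probs.ndim != 2 or probs.size == 0:
            raise ValueError("probs must be a non-empty 2-D matrix")
        if len(self.class_names) != probs.shape[1]:
            raise ValueError(
                f"{len(self.class_names)} class names for {probs.shape[1]} columns"
            )
        if np.any(probs < -ROW_SUM_TOL) or np.any(probs > 1 + ROW_SUM_TOL):
            raise ValueError("probabilities must lie in [0, 1]")
        row_sums = probs.sum(axis=1)
        bad = np.where(np.abs(row_sums - 1.0) > ROW_SUM_TOL)[0]
        if bad.size:
            raise ValueError(
                f"row {bad[0]} sums to {row_sums[bad[0]]:.9f}, expected 1 ± {ROW_SUM_TOL}"
            )

    @property
    def n_samples(self) -> int:
        return self.probs.shape[0]

    @property
    def n_classes(self) -> int:
        return self.probs.shape[1]

    def hard_labels(self) -> np.ndarray:
        """Max-probability class per row; ties go to the lowest class index."""
        return np.argmax(self.probs, axis=1)


@dataclass(frozen=True)
class LabelVector:
    """True class index per sample (0-based)."""

    labels: np.ndarray
    n_classes: int | None = None

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 1 or labels.size == 0:
            raise ValueError("labels must be a non-empty 1-D vector")
        if not np.issubdtype(labels.dtype, np.integer):
            as_int = labels.astype(int)
            if not np.array_equal(as_int, labels):
                raise ValueError("labels must be integers")
            labels = as_int
        if np.any(labels < 0):
            raise ValueError("labels must be non-negative")
        if self.n_classes is not None and np.any(labels >= self.n_classes):
            raise ValueError(f"label out of range for {self.n_classes} classes")
        object.__setattr__(self, "labels", labels)

    def __len__(self) -> int:
        return self.labels.size


@dataclass(frozen=True)
class CorrectnessVector:
    """Binary per-sample indicator that a classifier got the sample right."""

    bits: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        bits = np.asarray(self.bits, dtype=int)
        if bits.ndim != 1 or bits.size == 0:
            raise ValueError("bits must be a non-empty 1-D vector")
        if not np.isin(bits, (0, 1)).all():
            raise ValueError("bits must be 0/1")
        object.__setattr__(self, "bits", bits)

    @property
    def n(self) -> int:
        return self.bits.size

    @property
    def accuracy(self) -> float:
        return float(self.bits.mean())


@dataclass(frozen=True)
class InformationGainScore:
    """Entropy reduction of the correctness indicator, scaled by level."""

    value: float
    accuracy: float
    h_correctness: float
    h_prior: float
    alpha: float
    mode: str = "multiplicative"
    source_id: str = ""


@dataclass(frozen=True)
class WeightVector:
    """Convex classifier weights aligned with ``source_ids``."""

    weights: np.ndarray
    source_ids: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        weights = np.asarray(self.weights, dtype=float)
        if weights.ndim != 1 or weights.size == 0:
            raise ValueError("weights must be a non-empty 1-D vector")
        if np.any(weights < 0):
            raise ValueError("weights must be non-negative")
        if abs(weights.sum() - 1.0) > WEIGHT_SUM_TOL:
            raise ValueError(f"weights sum to {weights.sum():.12f}, expected 1")
        object.__setattr__(self, "weights", weights)
        ids = tuple(self.source_ids) or tuple("" for _ in weights)
        if len(ids) != weights.size:
            raise ValueError("source_ids misaligned with weights")
        object.__setattr__(self, "source_ids", ids)

    def __len__(self) -> int:
        return self.weights.size


def binary_entropy(p: float | np.ndarray) -> float | np.ndarray:
    """Entropy in bits of a two-outcome distribution (p, 1-p).

    H(p) = -p log2 p - (1-p) log2 (1-p), with 0 log2 0 := 0.  Symmetric
    about p = 1/2 where it attains its maximum of 1 bit.
    """
    arr = np.asarray(p, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("p must lie in [0, 1]")
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -np.where(arr > 0, arr * np.log2(arr), 0.0) - np.where(
            arr < 1, (1 - arr) * np.log2(1 - arr), 0.0
        )
    h = np.clip(h, 0.0, 1.0)
    return float(h) if np.isscalar(p) or arr.ndim == 0 else h


def correctness(pred: PredictionMatrix, truth: LabelVector) -> CorrectnessVector:
    """Per-sample indicator that the max-probability class matches the truth.

    Ties in the maximal probability resolve to the lowest class index, so a
    (0.5, 0.5) row counts as predicting class 0.
    """
    truth_arr = truth.labels if isinstance(truth, LabelVector) else LabelVector(np.asarray(truth)).labels
    if pred.n_samples != truth_arr.size:
        raise ValueError(
            f"prediction rows ({pred.n_samples}) != labels ({truth_arr.size})"
        )
    if np.any(truth_arr >= pred.n_classes):
        raise ValueError("label out of range for prediction columns")
    bits = (pred.hard_labels() == truth_arr).astype(int)
    return CorrectnessVector(bits=bits, source_id=pred.source_id)


def information_gain(
    c: CorrectnessVector,
    alpha: float,
    h_prior: float = 1.0,
    mode: str = "multiplicative",
) -> InformationGainScore:
    """Score a classifier by the entropy reduction of its correctness bits.

    ``h_prior`` is the reference entropy before conditioning on the
    classifier (default 1 bit, the maximal-uncertainty state).  In the
    default multiplicative mode the score is
    ``alpha * max(0, h_prior - H(accuracy))``; the exponent mode raises the
    entropy gap to the power ``alpha`` instead, so higher levels amplify
    the relative dominance of more accurate classifiers.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if not 0.0 <= h_prior <= 1.0:
        raise ValueError("h_prior must lie in [0, 1]")
    if mode not in ("multiplicative", "exponent"):
        raise ValueError(f"unknown mode {mode!r}")
    acc = c.accuracy
    if acc < 0.5:
        warnings.warn(
            f"classifier {c.source_id or '<unnamed>'} accuracy {acc:.3f} < 0.5: "
            "the entropy gap is symmetric about 0.5, so its weight no longer "
            "reflects skill",
            IGPAWarning,
            stacklevel=2,
        )
    h_c = float(binary_entropy(acc))
    gap = max(0.0, h_prior - h_c)
    value = alpha * gap if mode == "multiplicative" else gap**alpha
    return InformationGainScore(
        value=value,
        accuracy=acc,
        h_correctness=h_c,
        h_prior=h_prior,
        alpha=alpha,
        mode=mode,
        source_id=c.source_id,
    )


def igpa_weights(scores: Sequence[InformationGainScore]) -> WeightVector:
    """Normalise information-gain scores into convex ensemble weights.

    weight_i = IG_i / sum_j IG_j.  If every score is zero (all classifiers
    at chance) the ratio is undefined and a uniform vector is returned with
    a warning.
    """
    if len(scores) == 0:
        raise ValueError("need at least one score")
    values = np.array([s.value for s in scores], dtype=float)
    if np.any(values < 0):
        raise ValueError("information gain scores must be non-negative")
    ids = tuple(s.source_id for s in scores)
    total = values.sum()
    if total == 0.0:
        warnings.warn(
            "total information gain is zero; falling back to uniform weights",
            IGPAWarning,
            stacklevel=2,
        )
        return WeightVector(np.full(len(scores), 1.0 / len(scores)), ids)
    return WeightVector(values / total, ids)
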