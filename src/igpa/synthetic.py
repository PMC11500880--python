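"""Synthetic classifier-prediction and manifest generation.

Emulates the experimental setting the ensemble machinery targets: a bank
of image classifiers of heterogeneous accuracy (typically 0.85-0.95) over a
7-class, heavily imbalanced dermoscopy label distribution (nevus-dominated,
HAM10000-like), with image records carrying lesion IDs so that
train/validation/test splits can be grouped by lesion and leak-free.

Per classifier and sample the simulator first decides correctness — either
from an independent Bernoulli draw at the classifier's target accuracy or,
with probability ``correlation``, from a per-sample shared difficulty draw
so classifiers err on the same hard samples — then emits a probability row
concentrated on the (correct or uniformly-wrong) predicted class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import LabelVector, PredictionMatrix

__all__ = [
    "HAM10000_CLASSES",
    "HAM10000_CLASS_PROBS",
    "SimulatorConfig",
    "SampleManifest",
    "Partition",
    "simulate_predictions",
    "make_manifest",
    "grouped_split",
]

# Seven dermoscopy categories with the empirical HAM10000 frequencies
# (10015 images: AK 327, BCC 514, BKL 1099, DF 115, MEL 1113, NV 6705,
# VASC 142) — one dominant class at ~67%.
HAM10000_CLASSES = ("AK", "BCC", "BKL", "DF", "MEL", "NV", "VASC")
HAM10000_CLASS_PROBS = tuple(
    np.array([327, 514, 1099, 115, 1113, 6705, 142]) / 10015.0
)


@dataclass(frozen=True)
class SimulatorConfig:
    """Study conditions for the prediction simulator."""

    n_samples: int
    classifier_accuracies: tuple[float, ...]
    n_classes: int = 7
    class_probs: tuple[float, ...] = HAM10000_CLASS_PROBS
    class_names: tuple[str, ...] | None = None
    concentration: float = 8.0
    correlation: float = 0.0
    seed: int = 0
    confusion_bias: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.n_classes < 2:
            raise ValueError("need at least two classes")
        if len(self.class_probs) != self.n_classes:
            raise ValueError("class_probs length must equal n_classes")
        if abs(sum(self.class_probs) - 1.0) > 1e-9:
            raise ValueError("class_probs must sum to 1")
        if not self.classifier_accuracies:
            raise ValueError("need at least one classifier accuracy")
        if any(not 0.0 <= a <= 1.0 for a in self.classifier_accuracies):
            raise ValueError("accuracies must lie in [0, 1]")
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")
        if not 0.0 <= self.correlation <= 1.0:
            raise ValueError("correlation must lie in [0, 1]")
        if self.confusion_bias is not None:
            cb = np.asarray(self.confusion_bias, dtype=float)
            if cb.shape != (self.n_classes, self.n_classes):
                raise ValueError("confusion_bias must be (n_classes, n_classes)")
            object.__setattr__(self, "confusion_bias", cb)

    @property
    def names(self) -> tuple[str, ...]:
        if self.class_names is not None:
            return tuple(self.class_names)
        if self.n_classes == len(HAM10000_CLASSES) and self.class_probs == HAM10000_CLASS_PROBS:
            return HAM10000_CLASSES
        return tuple(f"C{i}" for i in range(self.n_classes))


@dataclass(frozen=True)
class SampleManifest:
    """Image records (image_id, lesion_id, class_label) for grouped splitting."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.records
        required = {"image_id", "lesion_id", "class_label"}
        if not required.issubset(df.columns):
            raise ValueError(f"manifest needs columns {sorted(required)}")
        if df["image_id"].duplicated().any():
            raise ValueError("image_ids must be unique")
        per_lesion = df.groupby("lesion_id")["class_label"].nunique()
        if (per_lesion > 1).any():
            raise ValueError("every lesion_id must map to a single class_label")
        object.__setattr__(self, "records", df.reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class Partition:
    """Disjoint lesion-grouped train/validation/test image-id sets."""

    train: frozenset[str]
    validation: frozenset[str]
    test: frozenset[str]

    def __post_init__(self) -> None:
        if (
            self.train & self.validation
            or self.train & self.test
            or self.validation & self.test
        ):
            raise ValueError("partitions must be pairwise disjoint")

    def sizes(self) -> tuple[int, int, int]:
        return len(self.train), len(self.validation), len(self.test)


def _wrong_class(rng: np.random.Generator, truth: int, cfg: SimulatorConfig) -> int:
    if cfg.confusion_bias is not None:
        p = cfg.confusion_bias[truth].copy()
        p[truth] = 0.0
        if p.sum() <= 0:
            raise ValueError("confusion_bias row has no off-diagonal mass")
        return int(rng.choice(cfg.n_classes, p=p / p.sum()))
    others = [k for k in range(cfg.n_classes) if k != truth]
    return int(rng.choice(others))


def simulate_predictions(
    cfg: SimulatorConfig,
) -> tuple[list[PredictionMatrix], LabelVector]:
    """Draw truth labels and one probability matrix per configured classifier.

    Each row is a Dirichlet(1,...,1) noise vector plus ``concentration``
    extra mass on the predicted class, renormalised — for concentration > 1
    the row's argmax is guaranteed to be the intended prediction, so the
    designed correctness draw is realised exactly.  Fully reproducible from
    ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    n, k = cfg.n_samples, cfg.n_classes
    truth = rng.choice(k, size=n, p=np.asarray(cfg.class_probs))
    shared_u = rng.random(n)  # per-sample difficulty, shared across classifiers
    preds: list[PredictionMatrix] = []
    for i, acc in enumerate(cfg.classifier_accuracies):
        use_shared = rng.random(n) < cfg.correlation
        independent = rng.random(n) < acc
        correct = np.where(use_shared, shared_u < acc, independent)
        predicted = truth.copy()
        for j in np.where(~correct)[0]:
            predicted[j] = _wrong_class(rng, int(truth[j]), cfg)
        noise = rng.dirichlet(np.ones(k), size=n)
        rows = noise.copy()
        rows[np.arange(n), predicted] += cfg.concentration
        rows /= rows.sum(axis=1, keepdims=True)
        preds.append(
            PredictionMatrix(rows, cfg.names, source_id=f"clf{i:02d}")
        )
    return preds, LabelVector(truth, n_classes=k)


def make_manifest(
    n_images: int,
    n_lesions: int,
    class_probs: tuple[float, ...] = HAM10000_CLASS_PROBS,
    seed: int = 0,
    class_names: tuple[str, ...] | None = None,
) -> SampleManifest:
    """Assign lesions to classes and distribute images over lesions.

    Every lesion gets at least one image; surplus images land on random
    lesions, emulating lesions photographed more than once.
    """
    if n_lesions < 1 or n_images < n_lesions:
        raise ValueError("need 1 <= n_lesions <= n_images")
    probs = np.asarray(class_probs, dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("class_probs must sum to 1")
    names = class_names or (
        HAM10000_CLASSES
        if probs.size == len(HAM10000_CLASSES)
        else tuple(f"C{i}" for i in range(probs.size))
    )
    rng = np.random.default_rng(seed)
    lesion_class = rng.choice(probs.size, size=n_lesions, p=probs)
    owner = np.concatenate(
        [np.arange(n_lesions), rng.integers(0, n_lesions, size=n_images - n_lesions)]
    )
    rng.shuffle(owner)
    df = pd.DataFrame(
        {
            "image_id": [f"IMG_{i:06d}" for i in range(n_images)],
            "lesion_id": [f"LES_{l:06d}" for l in owner],
            "class_label": [names[lesion_class[l]] for l in owner],
        }
    )
    return SampleManifest(df)


def grouped_split(
    m: SampleManifest,
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
) -> Partition:
    """Lesion-grouped train/validation/test split.

    Lesions are shuffled by ``seed`` and greedily assigned — whole lesions
    at a time — to fill the test quota, then the validation quota; the
    remainder is training data.  No lesion ever spans two partitions.  With
    one image per lesion and exactly divisible counts the partition sizes
    are exact.
    """
    train_f, val_f, test_f = fractions
    if min(fractions) <= 0:
        raise ValueError("fractions must be positive")
    if abs(train_f + val_f + test_f - 1.0) > 1e-9:
        raise ValueError(f"fractions sum to {sum(fractions)}, expected 1")
    n = len(m)
    test_quota = int(round(n * test_f))
    val_quota = int(round(n * val_f))
    rng = np.random.default_rng(seed)
    lesions = m.records["lesion_id"].unique()
    rng.shuffle(lesions)
    images_of = m.records.groupby("lesion_id")["image_id"].apply(list)
    test: set[str] = set()
    val: set[str] = set()
    train: set[str] = set()
    for lesion in lesions:
        imgs = images_of[lesion]
        if len(test) < test_quota:
            test.update(imgs)
        elif len(val) < val_quota:
            val.update(imgs)
        else:
            train.update(imgs)
    return Partition(frozenset(train), frozenset(val), frozenset(test))
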