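"""Forward passes of the three attention operators.

These are inference-only: the caller supplies the weight matrices, there is
no learning.  Feature maps are channel-first arrays of shape (C, H, W).

* Channel attention gates each channel by
  ``sigmoid(W2 @ relu(W1 @ d))`` where ``d`` is a per-channel descriptor —
  the channel means, optionally concatenated with the channel standard
  deviations (descriptor length C or 2C).
* Squeeze-and-excitation pools each channel to its global average ``z``
  and scales by ``relu(W2 @ sigmoid(W1 @ z))``.  Note the activation order
  (outer ReLU, inner sigmoid) inverts the usual squeeze-excitation design;
  it is implemented exactly as specified, so zero weight matrices
  annihilate the output rather than halving it.
* Soft attention is a numerically safe softmax over scalar scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, softmax

__all__ = [
    "FeatureMap",
    "AttentionParams",
    "channel_attention",
    "squeeze_excitation",
    "soft_attention_weights",
    "default_hidden_width",
]


def default_hidden_width(channels: int, reduction: int = 8) -> int:
    """Bottleneck width for the attention MLPs: channels/reduction, floor 1."""
    return max(1, channels // reduction)


@dataclass(frozen=True)
class FeatureMap:
    """A (channels, height, width) activation tensor."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 3 or min(values.shape) < 1:
            raise ValueError("feature map must be a (C, H, W) array, all dims >= 1")
        if not np.isfinite(values).all():
            raise ValueError("feature map must be finite")
        object.__setattr__(self, "values", values)

    @property
    def channels(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class AttentionParams:
    """Weight matrices of the two-layer attention MLP.

    ``W1`` maps the channel descriptor (length C or 2C depending on
    ``descriptor_mode``) to the hidden width; ``W2`` maps hidden back to C.
    """

    W1: np.ndarray
    W2: np.ndarray
    descriptor_mode: str = "mean_std"

    def __post_init__(self) -> None:
        W1 = np.atleast_2d(np.asarray(self.W1, dtype=float))
        W2 = np.atleast_2d(np.asarray(self.W2, dtype=float))
        if self.descriptor_mode not in ("mean", "mean_std"):
            raise ValueError(f"unknown descriptor_mode {self.descriptor_mode!r}")
        if W2.shape[1] != W1.shape[0]:
            raise ValueError(
                f"inner dimensions mismatch: W1 is {W1.shape}, W2 is {W2.shape}"
            )
        object.__setattr__(self, "W1", W1)
        object.__setattr__(self, "W2", W2)

    def check_channels(self, channels: int, descriptor_len: int) -> None:
        if self.W1.shape[1] != descriptor_len:
            raise ValueError(
                f"W1 expects descriptor length {self.W1.shape[1]}, got {descriptor_len}"
            )
        if self.W2.shape[0] != channels:
            raise ValueError(
                f"W2 produces {self.W2.shape[0]} channels, feature map has {channels}"
            )


def _descriptor(x: FeatureMap, mode: str) -> np.ndarray:
    means = x.values.mean(axis=(1, 2))
    if mode == "mean":
        return means
    stds = x.values.std(axis=(1, 2))
    return np.concatenate([means, stds])


def channel_attention(x: FeatureMap, p: AttentionParams) -> FeatureMap:
    """Sigmoid-gated channel re-weighting from a mean(/std) descriptor.

    w_c = sigmoid(W2 @ relu(W1 @ d)); each channel plane is scaled by its
    gate, so the output never exceeds the input in magnitude.
    """
    d = _descriptor(x, p.descriptor_mode)
    p.check_channels(x.channels, d.size)
    hidden = np.maximum(p.W1 @ d, 0.0)
    gates = expit(p.W2 @ hidden)  # in (0, 1)
    return FeatureMap(gates[:, None, None] * x.values)


def squeeze_excitation(x: FeatureMap, p: AttentionParams) -> FeatureMap:
    """Global-average squeeze, then s = relu(W2 @ sigmoid(W1 @ z)) excitation."""
    z = x.values.mean(axis=(1, 2))
    p.check_channels(x.channels, z.size)
    hidden = expit(p.W1 @ z)
    s = np.maximum(p.W2 @ hidden, 0.0)  # non-negative, unbounded above
    return FeatureMap(s[:, None, None] * x.values)


def soft_attention_weights(e: np.ndarray) -> np.ndarray:
    """Softmax of scalar scores: a_i = exp(e_i) / sum_j exp(e_j).

    Computed with the max-shift trick, hence invariant to adding a constant
    to every score and safe against overflow.
    """
    scores = np.asarray(e, dtype=float).ravel()
    if scores.size < 1:
        raise ValueError("need at least one score")
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    return softmax(scores)
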