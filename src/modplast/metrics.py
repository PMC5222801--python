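"""Receptive-field summary statistics.

All metrics are pure functions of a weight vector indexed by input neuron
(1-based indices, matching "input 4", "input 7").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "TuningSummary",
    "input_specificity",
    "rescale_tuning",
    "bimodality_fraction",
    "width_at_half_max",
    "summarize_tuning",
]


def input_specificity(
    weights: np.ndarray, training_index: int, initial_pref_index: int
) -> float:
    """``w[training] - w[initial preferred]`` (1-based indices).

    Positive values indicate a receptive field shifted toward the trained
    stimulus.
    """
    w = np.asarray(weights, float)
    for idx in (training_index, initial_pref_index):
        if not 1 <= idx <= len(w):
            raise ConfigurationError(f"index {idx} outside 1..{len(w)}")
    return float(w[training_index - 1] - w[initial_pref_index - 1])


def rescale_tuning(weights: np.ndarray) -> np.ndarray:
    """Divide the tuning curve by its maximum so the peak equals 1."""
    w = np.asarray(weights, float)
    m = w.max()
    if m <= 0:
        raise ConfigurationError("cannot rescale an all-zero tuning curve")
    return w / m


def bimodality_fraction(
    weights: np.ndarray, w_min: float, w_max: float, margin: float | None = None
) -> float:
    """Fraction of weights within ``margin`` of either bound.

    ``margin`` defaults to 5% of the bound range.  Values near 1 indicate the
    bimodal (symmetry-broken) distribution of additive STDP with hard bounds.
    """
    w = np.asarray(weights, float)
    if margin is None:
        margin = 0.05 * (w_max - w_min)
    if not 0 < margin < 0.5 * (w_max - w_min):
        raise ConfigurationError(
            f"margin must lie in (0, {(w_max - w_min) / 2}), got {margin}"
        )
    at_bound = (w <= w_min + margin) | (w >= w_max - margin)
    return float(at_bound.mean())


def width_at_half_max(rescaled_curve: np.ndarray) -> float:
    """Linearly interpolated width (in index units) of the region >= 0.5.

    Expects a curve rescaled to maximum 1 (approximately unimodal).  A flat
    curve at or above 0.5 everywhere returns the full extent ``n - 1`` by
    convention; a delta-like curve returns at most 1.
    """
    c = np.asarray(rescaled_curve, float)
    n = len(c)
    if n == 0:
        raise ConfigurationError("empty curve")
    if n == 1:
        return 0.0
    half = 0.5
    peak = int(np.argmax(c))
    if c[peak] < half:
        return 0.0
    # walk left from the peak to the interpolated half-maximum crossing
    left = float(peak)
    for i in range(peak, 0, -1):
        if c[i - 1] < half:
            left = i - (c[i] - half) / (c[i] - c[i - 1])
            break
    else:
        left = 0.0
    right = float(peak)
    for i in range(peak, n - 1):
        if c[i + 1] < half:
            right = i + (c[i] - half) / (c[i] - c[i + 1])
            break
    else:
        right = float(n - 1)
    return float(right - left)


@dataclass
class TuningSummary:
    """Summary of one receptive field (weight vector over inputs)."""

    peak_index: int  # 1-based
    rescaled_curve: np.ndarray
    width_at_half_max: float
    specificity: float | None
    bimodality_fraction: float


def summarize_tuning(
    weights: np.ndarray,
    w_min: float,
    w_max: float,
    training_index: int | None = None,
    initial_pref_index: int | None = None,
    margin: float | None = None,
) -> TuningSummary:
    w = np.asarray(weights, float)
    rescaled = rescale_tuning(w)
    spec = (
        input_specificity(w, training_index, initial_pref_index)
        if training_index is not None and initial_pref_index is not None
        else None
    )
    return TuningSummary(
        peak_index=int(np.argmax(w)) + 1,
        rescaled_curve=rescaled,
        width_at_half_max=width_at_half_max(rescaled),
        specificity=spec,
        bimodality_fraction=bimodality_fraction(w, w_min, w_max, margin),
    )
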