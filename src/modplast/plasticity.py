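"""STDP learning windows, exact online accumulators, and their oracles.

Four neuromodulator-gated pair-based learning windows are supported, named by
the sign of their acausal/causal branches:

* ``DP`` (Depression–Potentiation): the standard antisymmetric window —
  pre-before-post potentiates, post-before-pre depresses.
* ``PP`` (Potentiation–Potentiation): every pairing potentiates.
* ``UP`` (Unchanged–Potentiation): causal-only potentiation.
* ``DU`` (Depression–Unchanged): acausal-only depression.

The window value for a spike-time difference ``dt = t_post - t_pre`` is::

    dW(dt) = alpha * a_causal  * exp(-dt / tau_causal)    for dt > 0
    dW(dt) = alpha * a_acausal * exp(+dt / tau_acausal)   for dt < 0
    dW(0)  = 0

with ``a_acausal`` signed (negative = depression) and ``alpha`` the global
learning rate — the knob neuromodulatory gating is assumed to act on.  Pairs
interact all-to-all; the online implementation realizes the all-pairs sum
event-by-event through exponentially decaying eligibility traces and is exact
(not an approximation), which the brute-force double-loop oracle verifies.

The triplet rule adds a second, slower trace on each side (pre trace ``r2``
with ``tau_x``, post trace ``o2`` with ``tau_y``): a post spike potentiates by
``r1*(a_causal + a3_causal*o2)`` and a pre spike changes the weight by
``o1*(a_acausal + a3_acausal*r2)``, the slow traces being read just before
the current spike increments them.  With the triplet amplitudes at zero it
reduces exactly to the pair rule.

All time constants are in seconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .errors import ConfigurationError, NormalizationError

__all__ = [
    "LearningWindow",
    "TripletParams",
    "WeightTrajectory",
    "learning_window",
    "window_value",
    "brute_force_pair_sum",
    "brute_force_triplet_sum",
    "online_pair_accumulation",
    "online_triplet_accumulation",
    "apply_bounds",
    "normalize_weights",
    "expected_drift",
]

RULES = ("DP", "PP", "UP", "DU")


@dataclass(frozen=True)
class LearningWindow:
    """A pair-based STDP window (amplitudes dimensionless, times in s)."""

    rule_id: str
    a_causal: float
    a_acausal: float
    tau_causal: float = 0.020
    tau_acausal: float = 0.020
    learning_rate_alpha: float = 1.0

    def __post_init__(self) -> None:
        if self.tau_causal <= 0 or self.tau_acausal <= 0:
            raise ConfigurationError("STDP time constants must be positive")
        if self.learning_rate_alpha < 0:
            raise ConfigurationError("learning rate alpha must be >= 0")
        sign_ok = {
            "DP": self.a_causal > 0 and self.a_acausal < 0,
            "PP": self.a_causal > 0 and self.a_acausal > 0,
            "UP": self.a_causal > 0 and self.a_acausal == 0,
            "DU": self.a_causal == 0 and self.a_acausal < 0,
            "triplet": True,
        }
        if self.rule_id not in sign_ok:
            raise ConfigurationError(f"unknown rule_id {self.rule_id!r}")
        if not sign_ok[self.rule_id]:
            raise ConfigurationError(
                f"branch amplitudes ({self.a_causal}, {self.a_acausal}) "
                f"inconsistent with rule {self.rule_id}"
            )

    def with_alpha(self, alpha: float) -> "LearningWindow":
        return replace(self, learning_rate_alpha=alpha)


def learning_window(
    rule_id: str,
    alpha: float = 1.0,
    depression_excess: float = 0.0,
    tau_causal: float = 0.020,
    tau_acausal: float = 0.020,
) -> LearningWindow:
    """Build one of the four named windows with unit branch amplitudes.

    ``depression_excess`` scales the depression branch up relative to
    potentiation (``0.02`` gives the 2% excess that makes the window
    integral negative and drives symmetry breaking under DP).
    """
    amps = {
        "DP": (1.0, -(1.0 + depression_excess)),
        "PP": (1.0, 1.0),
        "UP": (1.0, 0.0),
        "DU": (0.0, -(1.0 + depression_excess)),
    }
    if rule_id not in amps:
        raise ConfigurationError(f"unknown rule_id {rule_id!r}; expected one of {RULES}")
    a_c, a_ac = amps[rule_id]
    return LearningWindow(
        rule_id=rule_id,
        a_causal=a_c,
        a_acausal=a_ac,
        tau_causal=tau_causal,
        tau_acausal=tau_acausal,
        learning_rate_alpha=alpha,
    )


@dataclass(frozen=True)
class TripletParams:
    """Triplet-rule parameters: a pair window plus slow-trace amplitudes.

    ``a3_causal`` multiplies the slow post trace (time constant ``tau_y``)
    in the potentiation update; ``a3_acausal`` (signed, negative =
    depression) multiplies the slow pre trace (``tau_x``) in the acausal
    update.  Zero triplet amplitudes recover the pair rule exactly.
    """

    window: LearningWindow
    a3_causal: float = 0.0
    a3_acausal: float = 0.0
    tau_x: float = 0.101
    tau_y: float = 0.125

    def __post_init__(self) -> None:
        if self.tau_x <= 0 or self.tau_y <= 0:
            raise ConfigurationError("triplet time constants must be positive")


@dataclass
class WeightTrajectory:
    """Time-indexed synaptic weight matrix with hard bounds."""

    times: np.ndarray  # (T,) seconds
    weights: np.ndarray  # (T, n_inputs)
    w_min: float
    w_max: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.weights = np.atleast_2d(np.asarray(self.weights, float))
        if self.w_min >= self.w_max:
            raise ConfigurationError("w_min must be < w_max")
        lo, hi = self.weights.min(initial=self.w_min), self.weights.max(initial=self.w_max)
        if lo < self.w_min - 1e-9 or hi > self.w_max + 1e-9:
            raise ConfigurationError("stored weights exceed [w_min, w_max]")

    @property
    def final(self) -> np.ndarray:
        return self.weights[-1]


def window_value(window: LearningWindow, delta_t: float) -> float:
    """Weight change for a single pre/post pairing with ``delta_t = t_post - t_pre``.

    Exactly zero at ``delta_t == 0`` (a measure-zero convention that also
    avoids double counting simultaneous events in the online updater).
    """
    a = window.learning_rate_alpha
    if delta_t > 0:
        return a * window.a_causal * math.exp(-delta_t / window.tau_causal)
    if delta_t < 0:
        return a * window.a_acausal * math.exp(delta_t / window.tau_acausal)
    return 0.0


def brute_force_pair_sum(
    pre_spikes: np.ndarray, post_spikes: np.ndarray, window: LearningWindow
) -> float:
    """All-to-all pair sum by explicit double loop (oracle for the online path)."""
    total = 0.0
    for tp in np.asarray(pre_spikes, float):
        for tq in np.asarray(post_spikes, float):
            total += window_value(window, tq - tp)
    return total


def brute_force_triplet_sum(
    pre_spikes: np.ndarray, post_spikes: np.ndarray, params: TripletParams
) -> float:
    """Exhaustive pair + triplet enumeration (oracle for the triplet updater)."""
    pre = np.asarray(pre_spikes, float)
    post = np.asarray(post_spikes, float)
    w = params.window
    alpha = w.learning_rate_alpha
    total = brute_force_pair_sum(pre, post, w)
    # potentiation triplets: (post t0) ... (pre t1) ... (post t2), t1 < t2
    for t2 in post:
        for t1 in pre:
            if not (t1 < t2):
                continue
            for t0 in post:
                if t0 < t2:
                    total += (
                        alpha
                        * params.a3_causal
                        * math.exp(-(t2 - t1) / w.tau_causal)
                        * math.exp(-(t2 - t0) / params.tau_y)
                    )
    # acausal triplets: (pre t0) ... (post t1) ... (pre t2), t1 < t2
    for t2 in pre:
        for t1 in post:
            if not (t1 < t2):
                continue
            for t0 in pre:
                if t0 < t2:
                    total += (
                        alpha
                        * params.a3_acausal
                        * math.exp(-(t2 - t1) / w.tau_acausal)
                        * math.exp(-(t2 - t0) / params.tau_x)
                    )
    return total


def online_triplet_accumulation(
    pre_spikes: np.ndarray, post_spikes: np.ndarray, params: TripletParams
) -> float:
    """Event-driven trace implementation of the (pair or triplet) rule.

    Processes the merged, time-sorted event list once; traces are decayed
    between events with a single ``exp`` per event, so the result matches the
    brute-force enumeration to floating-point precision.  Simultaneous
    pre/post events see each other's traces *before* the coincident spike is
    added, realizing the ``dW(0) = 0`` convention.
    """
    w = params.window
    alpha = w.learning_rate_alpha
    pre = np.asarray(pre_spikes, float)
    post = np.asarray(post_spikes, float)
    events = np.concatenate([pre, post])
    is_pre = np.concatenate([np.ones(len(pre), bool), np.zeros(len(post), bool)])
    order = np.argsort(events, kind="stable")
    events, is_pre = events[order], is_pre[order]

    r1 = r2 = o1 = o2 = 0.0
    t_last = -np.inf  # time traces were last decayed to
    total = 0.0
    i, m = 0, len(events)
    while i < m:
        t = events[i]
        j = i
        while j < m and events[j] == t:
            j += 1
        has_pre = bool(np.any(is_pre[i:j]))
        has_post = bool(np.any(~is_pre[i:j]))
        if np.isfinite(t_last):
            d = t - t_last
            r1 *= math.exp(-d / w.tau_causal)
            r2 *= math.exp(-d / params.tau_x)
            o1 *= math.exp(-d / w.tau_acausal)
            o2 *= math.exp(-d / params.tau_y)
        t_last = t
        if has_pre:
            total += alpha * o1 * (w.a_acausal + params.a3_acausal * r2)
        if has_post:
            total += alpha * r1 * (w.a_causal + params.a3_causal * o2)
        if has_pre:
            r1 += 1.0
            r2 += 1.0
        if has_post:
            o1 += 1.0
            o2 += 1.0
        i = j
    return total


def online_pair_accumulation(
    pre_spikes: np.ndarray, post_spikes: np.ndarray, window: LearningWindow
) -> float:
    """Pair rule as the zero-triplet-amplitude special case of the triplet path."""
    return online_triplet_accumulation(pre_spikes, post_spikes, TripletParams(window))


def apply_bounds(weights: np.ndarray, w_min: float, w_max: float) -> np.ndarray:
    """Hard-clip weights into ``[w_min, w_max]`` (idempotent)."""
    if w_min >= w_max:
        raise ConfigurationError(f"w_min ({w_min}) must be < w_max ({w_max})")
    return np.clip(np.asarray(weights, float), w_min, w_max)


def normalize_weights(
    weights: np.ndarray,
    target_sum: float,
    w_min: float | None = None,
    w_max: float | None = None,
) -> np.ndarray:
    """Multiplicatively rescale the weight vector to sum to ``target_sum``.

    Optionally clips to bounds afterwards (in which case the sum constraint
    holds only up to clipping).  Raises :class:`NormalizationError` on an
    all-zero vector.
    """
    w = np.asarray(weights, float)
    s = w.sum()
    if s <= 0:
        raise NormalizationError("cannot normalize a weight vector with sum <= 0")
    out = w * (target_sum / s)
    if w_min is not None and w_max is not None:
        out = apply_bounds(out, w_min, w_max)
    return out


def expected_drift(nu_pre: float, nu_post: float, window: LearningWindow) -> float:
    """Mean weight-change rate (1/s) for independent Poisson pre/post trains.

    Under the all-to-all pair rule with statistically independent trains, the
    expected change per unit time is the product of the coincidence rate and
    the window integral::

        nu_pre * nu_post * alpha * (a_causal*tau_causal + a_acausal*tau_acausal)

    A balanced DP window therefore drifts at zero; any depression excess makes
    the drift negative — the symmetry-breaking force acting on weakly
    correlated synapses.
    """
    return (
        nu_pre
        * nu_post
        * window.learning_rate_alpha
        * (
            window.a_causal * window.tau_causal
            + window.a_acausal * window.tau_acausal
        )
    )
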