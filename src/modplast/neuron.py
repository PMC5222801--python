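"""Postsynaptic leaky integrate-and-fire neuron with background noise.

The single readout neuron integrates current-based synaptic input (one
exponential kernel per presynaptic spike, scaled by the synaptic weight) plus
a Gaussian background noise current.  The noise is calibrated so that with all
feedforward weights at zero the neuron still fires at ~10 Hz — the baseline
activity against which STDP correlations are expressed.

Membrane potential is in arbitrary units (rest 0, threshold 20); all times
are in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ._core import run_lif_stdp
from .errors import CalibrationError, ConfigurationError
from .inputs import SpikeTrainSet

__all__ = ["NeuronParams", "SimulationTrace", "simulate_postsynaptic", "calibrate_noise"]


@dataclass(frozen=True)
class NeuronParams:
    """Leaky integrate-and-fire parameters (times in s, potentials in a.u.).

    ``noise_mean`` (current units) and ``noise_sd`` (current * sqrt(s); white
    noise spectral amplitude) define the background current.  The shipped
    defaults are the output of :func:`calibrate_noise` targeting 10 Hz at zero
    feedforward weight.  ``psc_scale`` converts one unit of synaptic weight
    into postsynaptic current amplitude per spike.
    """

    membrane_time_constant: float = 0.020
    resting_potential: float = 0.0
    threshold: float = 20.0
    reset: float = 0.0
    refractory_period: float = 0.002
    synaptic_kernel_time_constant: float = 0.002
    psc_scale: float = 8.0
    noise_mean: float = 15.46875
    noise_sd: float = 0.8
    dt: float = 1e-4

    def __post_init__(self) -> None:
        if self.threshold <= self.resting_potential:
            raise ConfigurationError("threshold must exceed resting potential")
        if self.reset >= self.threshold:
            raise ConfigurationError("reset must be below threshold")
        if self.refractory_period < 0:
            raise ConfigurationError("refractory_period must be >= 0")
        if self.membrane_time_constant <= 0 or self.synaptic_kernel_time_constant <= 0:
            raise ConfigurationError("time constants must be positive")
        if self.dt <= 0:
            raise ConfigurationError("dt must be positive")

    @property
    def refractory_bins(self) -> int:
        return int(round(self.refractory_period / self.dt))


@dataclass
class SimulationTrace:
    """Postsynaptic spike times (s) from one simulation."""

    post_spikes: np.ndarray
    duration: float
    membrane_trace: np.ndarray | None = None

    @property
    def rate(self) -> float:
        return len(self.post_spikes) / self.duration if self.duration > 0 else 0.0


_NO_EVENTS = (np.empty(0, np.int64), np.empty(0, np.int64))


def simulate_postsynaptic(
    inputs: SpikeTrainSet | None,
    weights: np.ndarray,
    params: NeuronParams,
    seed: int,
    duration: float | None = None,
) -> SimulationTrace:
    """Simulate the neuron with frozen weights (no plasticity).

    ``inputs`` may be ``None`` together with an explicit ``duration`` for the
    noise-only (zero-weight) condition.
    """
    weights = np.asarray(weights, float)
    if inputs is not None:
        if len(weights) != inputs.n_inputs:
            raise ConfigurationError(
                f"{len(weights)} weights for {inputs.n_inputs} input trains"
            )
        if abs(inputs.dt - params.dt) > 1e-12:
            raise ConfigurationError("input and neuron dt differ")
        bins, ids = inputs.merged_events()
        duration = inputs.duration
    else:
        if duration is None:
            raise ConfigurationError("duration required when inputs is None")
        bins, ids = _NO_EVENTS
        weights = np.zeros(max(len(weights), 1))
    n_bins = int(round(duration / params.dt))
    post_bins, _, _, _, _ = run_lif_stdp(
        bins,
        ids,
        len(weights),
        n_bins,
        params.dt,
        weights.astype(np.float64),
        -np.inf,
        np.inf,
        params.membrane_time_constant,
        params.resting_potential,
        params.threshold,
        params.reset,
        params.refractory_bins,
        params.synaptic_kernel_time_constant,
        params.psc_scale,
        params.noise_mean,
        params.noise_sd,
        0.0,  # alpha = 0: plasticity off
        0.0,
        0.0,
        0.020,
        0.020,
        0.0,
        0.0,
        0.101,
        0.125,
        True,
        0,
        0.0,
        True,
        0,
        seed,
    )
    return SimulationTrace(post_spikes=post_bins * params.dt, duration=duration)


def zero_weight_rate(
    params: NeuronParams, duration: float = 100.0, seed: int = 0, n_trials: int = 1
) -> float:
    """Mean noise-driven firing rate (Hz) with all feedforward weights at zero."""
    rates = [
        simulate_postsynaptic(None, np.zeros(1), params, seed + k, duration=duration).rate
        for k in range(n_trials)
    ]
    return float(np.mean(rates))


def calibrate_noise(
    params: NeuronParams,
    target_rate: float = 10.0,
    tolerance: float = 1.0,
    seed: int = 0,
    duration: float = 100.0,
    max_iter: int = 40,
) -> NeuronParams:
    """Bisection on ``noise_mean`` so the zero-weight rate hits ``target_rate``.

    The zero-weight firing rate is monotonically non-decreasing in the mean
    noise current, so bisection converges; each evaluation uses the same
    ``duration`` and a seed derived deterministically from ``seed``.  Raises
    :class:`CalibrationError` when the target lies outside the searchable
    range.
    """
    if target_rate <= 0:
        raise ConfigurationError("target_rate must be positive")
    lo = 0.0
    hi = 3.0 * (params.threshold - params.resting_potential)

    def rate_at(mu: float) -> float:
        return zero_weight_rate(replace(params, noise_mean=mu), duration, seed)

    r_lo, r_hi = rate_at(lo), rate_at(hi)
    if not (r_lo <= target_rate <= r_hi):
        raise CalibrationError(
            f"target {target_rate} Hz outside achievable range "
            f"[{r_lo:.3f}, {r_hi:.3f}] Hz for noise_mean in [{lo}, {hi}]"
        )
    mu, rate = hi, r_hi
    for _ in range(max_iter):
        mu = 0.5 * (lo + hi)
        rate = rate_at(mu)
        if abs(rate - target_rate) <= 0.5 * tolerance:
            break
        if rate < target_rate:
            lo = mu
        else:
            hi = mu
    else:
        if abs(rate - target_rate) > tolerance:
            raise CalibrationError(
                f"bisection did not reach {target_rate}±{tolerance} Hz "
                f"(best {rate:.3f} Hz at noise_mean={mu:.6f})"
            )
    return replace(params, noise_mean=mu)
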