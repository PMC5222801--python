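"""High-level driver for one plastic simulation trial.

Couples a :class:`~modplast.inputs.SpikeTrainSet` to the LIF/STDP kernel and
returns the postsynaptic trace, the recorded weight trajectory and (for
frozen-weight probe trials) the accumulated weight change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._core import run_lif_stdp
from .errors import ConfigurationError
from .inputs import SpikeTrainSet
from .neuron import NeuronParams, SimulationTrace
from .plasticity import LearningWindow, TripletParams, WeightTrajectory

__all__ = ["PlasticityRun", "run_plastic_trial"]


@dataclass
class PlasticityRun:
    """Result of one plastic trial."""

    trace: SimulationTrace
    trajectory: WeightTrajectory
    final_weights: np.ndarray
    dw_accumulated: np.ndarray  # populated when freeze_weights=True


def run_plastic_trial(
    inputs: SpikeTrainSet,
    initial_weights: np.ndarray,
    neuron: NeuronParams,
    rule: LearningWindow | TripletParams,
    seed: int,
    w_min: float = 0.0,
    w_max: float = 10.0,
    freeze_weights: bool = False,
    normalize_every: float | None = None,
    norm_target: float | None = None,
    normalization_scheme: str = "subtractive",
    record_every: float | None = None,
) -> PlasticityRun:
    """Simulate the postsynaptic neuron with online plasticity.

    Parameters
    ----------
    rule
        A :class:`LearningWindow` (pair rule) or :class:`TripletParams`.
    freeze_weights
        Hold the weights at their initial values for the neuron dynamics and
        accumulate the would-be change separately (the probe protocol used to
        measure dw/w at a fixed weight).
    normalize_every
        Interval (s) of weight normalization; ``None`` (the default)
        disables it.  ``norm_target`` defaults to the initial sum.
    normalization_scheme
        ``"subtractive"`` (default) distributes the correction equally over
        synapses — the competitive scheme under which Hebbian growth
        sharpens tuning; ``"multiplicative"`` rescales the vector instead.
    record_every
        Interval (s) at which the weight vector is recorded; ``None`` records
        only the initial and final vectors.
    """
    if isinstance(rule, TripletParams):
        window, trip = rule.window, rule
    else:
        window, trip = rule, TripletParams(rule)
    w0 = np.asarray(initial_weights, float)
    if len(w0) != inputs.n_inputs:
        raise ConfigurationError(
            f"{len(w0)} weights for {inputs.n_inputs} input trains"
        )
    if np.any(w0 < w_min - 1e-12) or np.any(w0 > w_max + 1e-12):
        raise ConfigurationError("initial weights outside [w_min, w_max]")
    if abs(inputs.dt - neuron.dt) > 1e-12:
        raise ConfigurationError("input and neuron dt differ")
    dt = neuron.dt
    n_bins = int(round(inputs.duration / dt))
    bins, ids = inputs.merged_events()
    norm_bins = 0
    target = 0.0
    if normalization_scheme not in ("subtractive", "multiplicative"):
        raise ConfigurationError(
            f"unknown normalization_scheme {normalization_scheme!r}"
        )
    if normalize_every is not None:
        norm_bins = max(1, int(round(normalize_every / dt)))
        target = float(w0.sum()) if norm_target is None else float(norm_target)
    rec_bins = 0 if record_every is None else max(1, int(round(record_every / dt)))

    post_bins, t_rec, w_rec, w_final, dw = run_lif_stdp(
        bins,
        ids,
        inputs.n_inputs,
        n_bins,
        dt,
        w0.astype(np.float64),
        w_min,
        w_max,
        neuron.membrane_time_constant,
        neuron.resting_potential,
        neuron.threshold,
        neuron.reset,
        neuron.refractory_bins,
        neuron.synaptic_kernel_time_constant,
        neuron.psc_scale,
        neuron.noise_mean,
        neuron.noise_sd,
        window.learning_rate_alpha,
        window.a_causal,
        window.a_acausal,
        window.tau_causal,
        window.tau_acausal,
        trip.a3_causal,
        trip.a3_acausal,
        trip.tau_x,
        trip.tau_y,
        freeze_weights,
        norm_bins,
        target,
        normalization_scheme == "subtractive",
        rec_bins,
        seed,
    )
    trace = SimulationTrace(post_spikes=post_bins * dt, duration=inputs.duration)
    traj = WeightTrajectory(times=t_rec, weights=w_rec, w_min=w_min, w_max=w_max)
    return PlasticityRun(
        trace=trace, trajectory=traj, final_weights=w_final, dw_accumulated=dw
    )
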