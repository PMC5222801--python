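"""Correlated time-varying Poisson input ensembles.

Each input neuron stands for an afferent tuned to one sensory feature (a tone
frequency, an orientation).  Independent rate "signals" fluctuate around a
common base rate; each neuron's instantaneous firing rate is a kernel-weighted
sum of the signals centred on its own index, so that neighbouring inputs have
correlated activity.  One input (the "training input") and its neighbours can
be fired at an elevated rate to model paired sensory/neuromodulatory
stimulation.

Rates are represented on a coarse grid (``signal_dt``, default 1 ms) and
spikes are drawn per fine time bin (``dt``, default 0.1 ms) as Bernoulli
events with probability ``rate * dt``, i.e. an inhomogeneous Poisson process
with piecewise-constant rate.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "InputEnsembleConfig",
    "SpikeTrainSet",
    "generate_signals",
    "mix_signals",
    "apply_training_boost",
    "sample_poisson_spikes",
    "generate_ensemble",
]


@dataclass(frozen=True)
class InputEnsembleConfig:
    """Configuration of the correlated Poisson input ensemble.

    Parameters
    ----------
    n_inputs
        Number of input neurons (feature channels), numbered ``1..n_inputs``.
    base_rate
        Mean firing rate of every input in Hz (untrained condition).
    signal_timescale
        Relaxation time (s) of the Ornstein–Uhlenbeck rate signals.
    signal_relative_sd
        Stationary standard deviation of each signal as a fraction of
        ``base_rate``.  ``0`` gives constant-rate (homogeneous) inputs.
    mixing_width
        Width (in units of input index) of the Gaussian kernel mixing the
        independent signals into per-neuron rates.  ``0`` disables mixing.
    boundary_mode
        ``"clip"`` truncates the kernel at the edges and renormalizes each
        row (feature axes such as tone frequency are not circular);
        ``"wrap"`` uses circular index distance.
    training_index
        1-based index of the over-represented ("training") input, or ``None``
        for the untrained condition.
    training_gain
        Multiplicative rate boost of the training input.  ``2.0`` makes the
        training stimulus 100% stronger than the others.
    training_neighbor_profile
        Interpolation factors ``lam_k`` for neighbours at offset ``±k``
        (k = 1, 2, ...): the neighbour gain is ``1 + lam_k*(training_gain-1)``,
        so a unit training gain leaves the whole ensemble untouched.
    signal_dt
        Time resolution (s) of the rate traces.
    dt
        Time resolution (s) of spike sampling; must divide ``signal_dt``.
    """

    n_inputs: int
    base_rate: float
    signal_timescale: float = 0.05
    signal_relative_sd: float = 0.5
    mixing_width: float = 1.0
    boundary_mode: str = "clip"
    training_index: int | None = None
    training_gain: float = 2.0
    training_neighbor_profile: tuple[float, ...] = (0.5,)
    signal_dt: float = 1e-3
    dt: float = 1e-4

    def __post_init__(self) -> None:
        if self.n_inputs < 1:
            raise ConfigurationError(f"n_inputs must be >= 1, got {self.n_inputs}")
        if self.base_rate < 0:
            raise ConfigurationError(f"base_rate must be >= 0, got {self.base_rate}")
        if self.training_gain < 0:
            raise ConfigurationError("training_gain must be >= 0")
        if self.boundary_mode not in ("clip", "wrap"):
            raise ConfigurationError(f"unknown boundary_mode {self.boundary_mode!r}")
        if self.dt <= 0 or self.signal_dt <= 0:
            raise ConfigurationError("dt and signal_dt must be positive")
        if self.training_index is not None and not (
            1 <= self.training_index <= self.n_inputs
        ):
            raise ConfigurationError(
                f"training_index {self.training_index} outside 1..{self.n_inputs}"
            )
        ratio = self.signal_dt / self.dt
        if abs(ratio - round(ratio)) > 1e-9:
            raise ConfigurationError("signal_dt must be an integer multiple of dt")

    @property
    def upsample(self) -> int:
        return int(round(self.signal_dt / self.dt))

    def untrained(self) -> "InputEnsembleConfig":
        return replace(self, training_index=None)


@dataclass
class SpikeTrainSet:
    """A set of sampled spike trains plus the rate traces that produced them.

    ``spikes`` holds, per neuron, the spike times in seconds (strictly
    increasing, in ``[0, duration)``, at most one per bin of width ``dt``);
    ``bins`` holds the same spikes as integer bin indices.  ``rate_traces``
    is the (n_inputs, n_steps) matrix of instantaneous rates in Hz on the
    ``signal_dt`` grid.
    """

    duration: float
    dt: float
    spikes: list[np.ndarray]
    bins: list[np.ndarray]
    rate_traces: np.ndarray
    signal_dt: float

    @property
    def n_inputs(self) -> int:
        return len(self.spikes)

    def counts(self) -> np.ndarray:
        return np.array([len(s) for s in self.spikes])

    def merged_events(self) -> tuple[np.ndarray, np.ndarray]:
        """All spikes merged across neurons, sorted by time bin.

        Returns ``(bins, neuron_indices)`` with neuron indices 0-based; this
        is the event-list representation consumed by the simulation core.
        """
        if self.n_inputs == 0:
            return np.empty(0, np.int64), np.empty(0, np.int64)
        all_bins = np.concatenate(self.bins).astype(np.int64)
        ids = np.concatenate(
            [np.full(len(b), i, np.int64) for i, b in enumerate(self.bins)]
        )
        order = np.argsort(all_bins, kind="stable")
        return all_bins[order], ids[order]


def _n_steps(duration: float, step: float) -> int:
    n = int(round(duration / step))
    if n <= 0:
        raise ConfigurationError(f"duration {duration} too short for step {step}")
    return n


def generate_signals(
    config: InputEnsembleConfig,
    duration: float,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Generate one independent non-negative rate signal per input channel.

    Each signal is a clipped Ornstein–Uhlenbeck process with relaxation time
    ``signal_timescale`` and stationary standard deviation
    ``signal_relative_sd * base_rate``, fluctuating around ``base_rate`` and
    clipped at zero.  Returns an (n_inputs, n_steps) array in Hz on the
    ``signal_dt`` grid.
    """
    if duration <= 0:
        raise ConfigurationError(f"duration must be positive, got {duration}")
    rng = np.random.default_rng(seed)
    n_steps = _n_steps(duration, config.signal_dt)
    n = config.n_inputs
    mu = config.base_rate
    sigma = config.signal_relative_sd * config.base_rate
    if mu == 0.0:
        return np.zeros((n, n_steps))
    if sigma == 0.0:
        return np.full((n, n_steps), mu)

    tau = config.signal_timescale
    a = np.exp(-config.signal_dt / tau)
    # exact OU transition: stationary sd sigma regardless of signal_dt
    b = sigma * np.sqrt(1.0 - a * a)
    out = np.empty((n, n_steps))
    x = mu + sigma * rng.standard_normal(n)  # start from stationarity
    np.clip(x, 0.0, None, out=x)
    noise = rng.standard_normal((n_steps, n))
    for t in range(n_steps):
        x = mu + a * (x - mu) + b * noise[t]
        np.clip(x, 0.0, None, out=x)
        out[:, t] = x
    return out


def _mixing_kernel(config: InputEnsembleConfig) -> np.ndarray:
    """Row-normalized Gaussian mixing matrix over index distance."""
    n = config.n_inputs
    w = config.mixing_width
    if w <= 0:
        return np.eye(n)
    idx = np.arange(n)
    d = np.abs(idx[None, :] - idx[:, None]).astype(float)
    if config.boundary_mode == "wrap":
        d = np.minimum(d, n - d)
    kern = np.exp(-0.5 * (d / w) ** 2)
    kern /= kern.sum(axis=1, keepdims=True)
    return kern


def mix_signals(signals: np.ndarray, config: InputEnsembleConfig) -> np.ndarray:
    """Mix independent signals into correlated per-neuron rate traces.

    The rate trace of neuron *i* is the Gaussian-kernel-weighted sum of the
    signals centred on *i*.  Kernel rows are non-negative and sum to one, so
    the mean rate of every neuron equals ``base_rate`` in the untrained
    condition, and rate-trace correlation decays with index distance.
    """
    signals = np.asarray(signals, float)
    if signals.shape[0] != config.n_inputs:
        raise ConfigurationError(
            f"signals has {signals.shape[0]} channels, expected {config.n_inputs}"
        )
    if np.any(signals < 0):
        raise ConfigurationError("signals must be non-negative")
    kern = _mixing_kernel(config)
    if not np.allclose(kern.sum(axis=1), 1.0, atol=1e-10):
        raise AssertionError("internal error: mixing kernel rows not normalized")
    return kern @ signals


def training_gain_vector(config: InputEnsembleConfig) -> np.ndarray:
    """Per-neuron multiplicative gains implementing the training boost."""
    g = np.ones(config.n_inputs)
    if config.training_index is None:
        return g
    c = config.training_index - 1  # to 0-based
    g[c] = config.training_gain
    for k, lam in enumerate(config.training_neighbor_profile, start=1):
        gain = 1.0 + lam * (config.training_gain - 1.0)
        for j in (c - k, c + k):
            if 0 <= j < config.n_inputs:
                g[j] = gain
    return g


def apply_training_boost(
    rate_traces: np.ndarray, config: InputEnsembleConfig
) -> np.ndarray:
    """Scale the training input's rate trace (and its neighbours') up.

    With ``training_gain = 2.0`` the training stimulus is 100% stronger than
    the others.  Traces outside the boosted neighbourhood are returned
    unchanged (bit-identical).
    """
    rate_traces = np.asarray(rate_traces, float)
    if rate_traces.shape[0] != config.n_inputs:
        raise ConfigurationError("rate_traces/config size mismatch")
    if config.training_index is None:
        return rate_traces
    gains = training_gain_vector(config)
    out = rate_traces.copy()
    boosted = np.nonzero(gains != 1.0)[0]
    out[boosted] = rate_traces[boosted] * gains[boosted, None]
    return out


def sample_poisson_spikes(
    rate_traces: np.ndarray,
    dt: float,
    seed: int | np.random.Generator,
    signal_dt: float | None = None,
    duration: float | None = None,
) -> SpikeTrainSet:
    """Draw Poisson spikes from piecewise-constant rate traces.

    Each fine bin of width ``dt`` emits at most one spike, with probability
    ``rate * dt`` (Bernoulli thinning of the Poisson process).  ``signal_dt``
    defaults to ``dt`` (rate traces already on the fine grid).
    """
    if dt <= 0:
        raise ConfigurationError("dt must be positive")
    rate_traces = np.atleast_2d(np.asarray(rate_traces, float))
    signal_dt = dt if signal_dt is None else signal_dt
    upsample = int(round(signal_dt / dt))
    if abs(signal_dt / dt - upsample) > 1e-9 or upsample < 1:
        raise ConfigurationError("signal_dt must be an integer multiple of dt")
    max_rate = rate_traces.max() if rate_traces.size else 0.0
    if max_rate * dt >= 1.0:
        raise ConfigurationError(
            f"rate*dt reaches {max_rate * dt:.3f} >= 1; decrease dt below "
            f"{1.0 / max_rate:.2e} s"
        )
    rng = np.random.default_rng(seed)
    n, n_coarse = rate_traces.shape
    n_bins = n_coarse * upsample
    if duration is None:
        duration = n_bins * dt
    spikes: list[np.ndarray] = []
    bins: list[np.ndarray] = []
    for i in range(n):
        p = np.repeat(rate_traces[i] * dt, upsample)
        b = np.nonzero(rng.random(n_bins) < p)[0].astype(np.int64)
        bins.append(b)
        spikes.append(b * dt)
    return SpikeTrainSet(
        duration=duration,
        dt=dt,
        spikes=spikes,
        bins=bins,
        rate_traces=rate_traces,
        signal_dt=signal_dt,
    )


def _ou_chunk(
    config: InputEnsembleConfig,
    n_steps: int,
    rng: np.random.Generator,
    x: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Advance the clipped OU signals by ``n_steps``, drawing noise per step.

    Keeps memory proportional to the chunk (no pre-drawn noise matrix);
    returns the signal block and the carried end state.
    """
    mu = config.base_rate
    sigma = config.signal_relative_sd * config.base_rate
    out = np.empty((config.n_inputs, n_steps))
    if sigma == 0.0:
        out[:] = mu
        return out, x
    tau = config.signal_timescale
    a = np.exp(-config.signal_dt / tau)
    b = sigma * np.sqrt(1.0 - a * a)
    for t in range(n_steps):
        x = mu + a * (x - mu) + b * rng.standard_normal(config.n_inputs)
        np.clip(x, 0.0, None, out=x)
        out[:, t] = x
    return out, x


def generate_ensemble(
    config: InputEnsembleConfig,
    duration: float,
    seed: int | np.random.Generator,
    chunk_duration: float = 500.0,
) -> SpikeTrainSet:
    """Full pipeline: signals -> mixing -> training boost -> Poisson spikes.

    A single generator seeded once drives both the signals and the spike
    sampling, so the whole ensemble is reproducible from one seed.  Because
    the boost only rescales rate traces after the signal draw, traces outside
    the boosted neighbourhood (and their spike draws) match the untrained
    condition bit-for-bit under the same seed.

    Runs longer than ``chunk_duration`` are generated in chunks with the
    signal state carried across chunk boundaries, keeping memory bounded;
    such spike-train sets do not retain their rate traces.
    """
    rng = np.random.default_rng(seed)
    if duration <= chunk_duration:
        signals = generate_signals(config, duration, rng)
        rates = mix_signals(signals, config)
        rates = apply_training_boost(rates, config)
        return sample_poisson_spikes(
            rates, config.dt, rng, signal_dt=config.signal_dt, duration=duration
        )

    if config.base_rate == 0.0:
        empty = [np.empty(0) for _ in range(config.n_inputs)]
        return SpikeTrainSet(
            duration=duration,
            dt=config.dt,
            spikes=[e.copy() for e in empty],
            bins=[e.astype(np.int64) for e in empty],
            rate_traces=np.zeros((config.n_inputs, 0)),
            signal_dt=config.signal_dt,
        )

    total_steps = _n_steps(duration, config.signal_dt)
    chunk_steps = max(1, int(round(chunk_duration / config.signal_dt)))
    sigma = config.signal_relative_sd * config.base_rate
    x = np.clip(
        config.base_rate + sigma * rng.standard_normal(config.n_inputs), 0.0, None
    )
    bins: list[list[np.ndarray]] = [[] for _ in range(config.n_inputs)]
    done = 0
    while done < total_steps:
        n_c = min(chunk_steps, total_steps - done)
        signals, x = _ou_chunk(config, n_c, rng, x)
        rates = mix_signals(signals, config)
        rates = apply_training_boost(rates, config)
        chunk = sample_poisson_spikes(
            rates, config.dt, rng, signal_dt=config.signal_dt
        )
        offset = done * config.upsample
        for i in range(config.n_inputs):
            bins[i].append(chunk.bins[i] + offset)
        done += n_c
    all_bins = [
        np.concatenate(b) if b else np.empty(0, np.int64) for b in bins
    ]
    return SpikeTrainSet(
        duration=duration,
        dt=config.dt,
        spikes=[b * config.dt for b in all_bins],
        bins=all_bins,
        rate_traces=np.empty((config.n_inputs, 0)),
        signal_dt=config.signal_dt,
    )
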