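"""The in-silico experiments: symmetry breaking, receptive-field adaptation,
and the learning-rate vs. activity modulation sweeps.

Each experiment orchestrates the input, neuron and plasticity modules over
trials.  One master seed expands deterministically into per-trial seeds, so a
trial gives identical results whether run singly or as part of a batch.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .inputs import InputEnsembleConfig, generate_ensemble
from .metrics import (
    bimodality_fraction,
    rescale_tuning,
    summarize_tuning,
    width_at_half_max,
    TuningSummary,
)
from .neuron import NeuronParams
from .plasticity import (
    LearningWindow,
    TripletParams,
    WeightTrajectory,
    learning_window,
)
from .simulate import run_plastic_trial

__all__ = [
    "W_MIN",
    "W_MAX",
    "trial_seeds",
    "tuned_profile",
    "SymmetryBreakingConfig",
    "SymmetryBreakingResult",
    "run_symmetry_breaking",
    "RFAdaptationConfig",
    "RFAdaptationResult",
    "run_rf_adaptation",
    "run_rf_adaptation_normalized",
    "PairSweepConfig",
    "ModulationSweepResult",
    "run_modulation_pair_sweep",
    "NetworkModulationConfig",
    "NetworkModulationResult",
    "run_modulation_network",
]

#: default hard weight bounds (arbitrary units); the probe weights 3.0 and
#: 7.0 of the modulation sweep sit inside this range.
W_MIN = 0.0
W_MAX = 10.0


def trial_seeds(master_seed: int, n_trials: int) -> np.ndarray:
    """Expand one master seed into ``(n_trials, 2)`` independent seeds.

    Column 0 seeds the input generator, column 1 the neuron/noise stream;
    values stay below 2**31.
    """
    state = np.random.SeedSequence(master_seed).generate_state(2 * n_trials)
    return (state % np.uint32(2**31)).astype(np.int64).reshape(n_trials, 2)


def tuned_profile(
    n_inputs: int,
    peak_index: int = 7,
    peak: float = 0.5 * W_MAX,
    baseline: float = 0.2 * W_MAX,
    width: float = 1.5,
) -> np.ndarray:
    """Gaussian-bump initial receptive field peaked at ``peak_index`` (1-based)."""
    idx = np.arange(1, n_inputs + 1, dtype=float)
    return baseline + (peak - baseline) * np.exp(
        -0.5 * ((idx - peak_index) / width) ** 2
    )


def _resolve_rule(
    rule_id: str,
    alpha: float,
    depression_excess: float = 0.0,
    triplet: bool = False,
    a3_causal: float = 0.002,
    a3_acausal: float = -0.002,
) -> LearningWindow | TripletParams:
    window = learning_window(rule_id, alpha=alpha, depression_excess=depression_excess)
    if triplet:
        return TripletParams(window, a3_causal=a3_causal, a3_acausal=a3_acausal)
    return window


# ---------------------------------------------------------------------------
# Experiment 1: symmetry breaking with 100 equal synapses
# ---------------------------------------------------------------------------


@dataclass
class SymmetryBreakingConfig:
    """All synapses start equal; competitive STDP splits them to the bounds."""

    n_inputs: int = 100
    base_rate: float = 10.0
    duration: float = 3600.0
    rule_id: str = "DP"
    depression_excess: float = 0.02
    alpha: float = 0.03
    w_init: float = 2.0
    record_every: float = 10.0
    # per-synapse efficacy reduced for the large ensemble so the neuron stays
    # in the fluctuation-driven regime where STDP competition operates
    neuron: NeuronParams = field(default_factory=lambda: NeuronParams(psc_scale=4.0))
    input_kwargs: dict = field(default_factory=dict)

    def input_config(self) -> InputEnsembleConfig:
        return InputEnsembleConfig(
            n_inputs=self.n_inputs, base_rate=self.base_rate, **self.input_kwargs
        )


@dataclass
class SymmetryBreakingResult:
    trajectory: WeightTrajectory
    final_weights: np.ndarray
    bimodality: float
    hist_counts: np.ndarray
    hist_edges: np.ndarray


def run_symmetry_breaking(
    config: SymmetryBreakingConfig, seed: int
) -> SymmetryBreakingResult:
    """Run one symmetry-breaking simulation and histogram the final weights.

    Under DP with a small depression excess the weights split bimodally to
    the bounds; PP/UP send every weight to the upper bound and DU to the
    lower bound within seconds.
    """
    seeds = trial_seeds(seed, 1)[0]
    spikes = generate_ensemble(config.input_config(), config.duration, int(seeds[0]))
    rule = _resolve_rule(config.rule_id, config.alpha, config.depression_excess)
    run = run_plastic_trial(
        spikes,
        np.full(config.n_inputs, config.w_init),
        config.neuron,
        rule,
        int(seeds[1]),
        w_min=W_MIN,
        w_max=W_MAX,
        record_every=config.record_every,
    )
    counts, edges = np.histogram(run.final_weights, bins=20, range=(W_MIN, W_MAX))
    return SymmetryBreakingResult(
        trajectory=run.trajectory,
        final_weights=run.final_weights,
        bimodality=bimodality_fraction(run.final_weights, W_MIN, W_MAX),
        hist_counts=counts,
        hist_edges=edges,
    )


# ---------------------------------------------------------------------------
# Experiment 2: receptive-field adaptation with a training input
# ---------------------------------------------------------------------------


@dataclass
class RFAdaptationConfig:
    """A 10-input network initially tuned to input 7, optionally trained at 4."""

    n_inputs: int = 10
    base_rate: float = 10.0
    duration: float = 40.0
    n_trials: int = 100
    rule_id: str = "DP"
    alpha: float = 0.009
    training: bool = False
    training_index: int = 4
    training_gain: float = 2.0
    initial_pref_index: int = 7
    peak: float = 4.5
    baseline: float = 2.2
    profile_width: float = 1.5
    normalize: bool = False
    normalize_every: float = 0.1
    normalization_scheme: str = "subtractive"
    record_every: float = 0.5
    triplet: bool = False
    neuron: NeuronParams = field(default_factory=NeuronParams)
    input_kwargs: dict = field(default_factory=dict)

    def input_config(self) -> InputEnsembleConfig:
        return InputEnsembleConfig(
            n_inputs=self.n_inputs,
            base_rate=self.base_rate,
            training_index=self.training_index if self.training else None,
            training_gain=self.training_gain,
            **self.input_kwargs,
        )

    def initial_weights(self) -> np.ndarray:
        return tuned_profile(
            self.n_inputs,
            self.initial_pref_index,
            self.peak,
            self.baseline,
            self.profile_width,
        )


@dataclass
class RFAdaptationResult:
    times: np.ndarray  # (R,)
    mean_weights: np.ndarray  # (R, n_inputs)
    sd_weights: np.ndarray  # (R, n_inputs)
    specificity_mean: np.ndarray  # (R,)
    specificity_sd: np.ndarray  # (R,)
    weight_sums: np.ndarray  # (n_trials, R): total weight at each record time
    final_summary: TuningSummary

    @property
    def peak_index(self) -> int:
        return self.final_summary.peak_index


def run_rf_adaptation(config: RFAdaptationConfig, seed: int) -> RFAdaptationResult:
    """Trial-averaged weight trajectories and input-specificity time series.

    Specificity is ``w[training] - w[initial preferred]`` per trial; the mean
    and per-time-point standard deviation over trials are returned.
    """
    if config.n_trials < 1:
        raise ConfigurationError("n_trials must be >= 1")
    seeds = trial_seeds(seed, config.n_trials)
    in_cfg = config.input_config()
    w0 = config.initial_weights()
    rule = _resolve_rule(config.rule_id, config.alpha, triplet=config.triplet)
    all_w = []
    times = None
    for k in range(config.n_trials):
        spikes = generate_ensemble(in_cfg, config.duration, int(seeds[k, 0]))
        run = run_plastic_trial(
            spikes,
            w0,
            config.neuron,
            rule,
            int(seeds[k, 1]),
            w_min=W_MIN,
            w_max=W_MAX,
            normalize_every=config.normalize_every if config.normalize else None,
            normalization_scheme=config.normalization_scheme,
            record_every=config.record_every,
        )
        all_w.append(run.trajectory.weights)
        times = run.trajectory.times
    stack = np.stack(all_w)  # (n_trials, R, n)
    spec = (
        stack[:, :, config.training_index - 1]
        - stack[:, :, config.initial_pref_index - 1]
    )
    mean_w = stack.mean(axis=0)
    sd_w = stack.std(axis=0)
    return RFAdaptationResult(
        times=times,
        mean_weights=mean_w,
        sd_weights=sd_w,
        specificity_mean=spec.mean(axis=0),
        specificity_sd=spec.std(axis=0),
        weight_sums=stack.sum(axis=2),
        final_summary=summarize_tuning(
            mean_w[-1],
            W_MIN,
            W_MAX,
            training_index=config.training_index,
            initial_pref_index=config.initial_pref_index,
        ),
    )


def run_rf_adaptation_normalized(
    config: RFAdaptationConfig, seed: int
) -> RFAdaptationResult:
    """Receptive-field adaptation with the multiplicative normalization rule on."""
    return run_rf_adaptation(replace(config, normalize=True), seed)


# ---------------------------------------------------------------------------
# Experiment 3a: dw/w sweeps over learning rate and presynaptic rate
# ---------------------------------------------------------------------------


@dataclass
class PairSweepConfig:
    """One plastic synapse probed at fixed weight under the DP rule.

    The weight is clamped at its probe value for the neuron dynamics while
    the would-be STDP change accumulates, giving dw/w per trial over a fixed
    measurement window.
    """

    alpha0: float = 0.0005
    nu0: float = 10.0
    alpha_grid: tuple[float, ...] = (0.0005, 0.001, 0.002, 0.004, 0.008)
    nu_grid: tuple[float, ...] = (1.0, 2.0, 5.0, 10.0, 20.0, 50.0, 100.0)
    w_grid: tuple[float, ...] = (3.0, 7.0)
    trial_duration: float = 10.0
    n_trials: int = 200
    triplet: bool = False
    neuron: NeuronParams = field(default_factory=NeuronParams)

    def __post_init__(self) -> None:
        if not (self.alpha_grid and self.nu_grid and self.w_grid):
            raise ConfigurationError("sweep grids must be non-empty")
        if any(w <= 0 for w in self.w_grid):
            raise ConfigurationError("dw/w is undefined at w = 0; probe weights must be > 0")


@dataclass
class ModulationSweepResult:
    """dw/w statistics over the (w, alpha, nu) grid plus fitted slopes k."""

    table: pd.DataFrame  # columns: w, alpha, nu, mean_dwow, sd_dwow, sem_dwow, n_trials
    slopes: pd.DataFrame  # columns: w, nu, k, residual_frac

    def dwow(self, w: float, alpha: float, nu: float) -> float:
        t = self.table
        row = t[(t.w == w) & (t.alpha == alpha) & (t.nu == nu)]
        return float(row.mean_dwow.iloc[0])

    def slope(self, w: float, nu: float) -> float:
        s = self.slopes
        return float(s[(s.w == w) & (s.nu == nu)].k.iloc[0])


def _probe_dwow(
    w: float,
    alpha: float,
    nu: float,
    config: PairSweepConfig,
    seeds: np.ndarray,
) -> np.ndarray:
    """Per-trial dw/w for one (w, alpha, nu) grid point."""
    rule = _resolve_rule("DP", alpha, triplet=config.triplet)
    in_cfg = InputEnsembleConfig(
        n_inputs=1, base_rate=nu, signal_relative_sd=0.0, mixing_width=0.0
    )
    out = np.empty(len(seeds))
    for k, (s_in, s_core) in enumerate(seeds):
        spikes = generate_ensemble(in_cfg, config.trial_duration, int(s_in))
        run = run_plastic_trial(
            spikes,
            np.array([w]),
            config.neuron,
            rule,
            int(s_core),
            w_min=W_MIN,
            w_max=W_MAX,
            freeze_weights=True,
        )
        out[k] = run.dw_accumulated[0] / w
    return out


def run_modulation_pair_sweep(
    config: PairSweepConfig, seed: int
) -> ModulationSweepResult:
    """Sweep dw/w over the learning-rate grid (at nu0) and the rate grid (at alpha0).

    For each (w, nu) the slope ``k`` of the through-origin law ``dw/w = k*alpha``
    is fitted across the alpha grid, along with the largest relative residual
    of the linear fit.
    """
    seeds = trial_seeds(seed, config.n_trials)
    rows = []
    grid = [(w, a, config.nu0) for w in config.w_grid for a in config.alpha_grid]
    grid += [
        (w, config.alpha0, nu)
        for w in config.w_grid
        for nu in config.nu_grid
        if not (nu == config.nu0 and config.alpha0 in config.alpha_grid)
    ]
    seen = set()
    for w, a, nu in grid:
        if (w, a, nu) in seen:
            continue
        seen.add((w, a, nu))
        vals = _probe_dwow(w, a, nu, config, seeds)
        rows.append(
            dict(
                w=w,
                alpha=a,
                nu=nu,
                mean_dwow=vals.mean(),
                sd_dwow=vals.std(ddof=1),
                sem_dwow=vals.std(ddof=1) / np.sqrt(len(vals)),
                n_trials=len(vals),
            )
        )
    table = pd.DataFrame(rows)

    slope_rows = []
    for w in config.w_grid:
        sub = table[(table.w == w) & (table.nu == config.nu0)].sort_values("alpha")
        if len(sub) >= 2:
            a = sub.alpha.to_numpy()
            y = sub.mean_dwow.to_numpy()
            coef = np.polyfit(a, y, 1)
            fit = np.polyval(coef, a)
            rng_y = y.max() - y.min()
            resid = np.abs(y - fit).max() / rng_y if rng_y > 0 else 0.0
            slope_rows.append(dict(w=w, nu=config.nu0, k=coef[0], residual_frac=resid))
    slopes = pd.DataFrame(slope_rows)
    return ModulationSweepResult(table=table, slopes=slopes)


# ---------------------------------------------------------------------------
# Experiment 3b: network-level modulation (tuning sharpening vs broadening)
# ---------------------------------------------------------------------------


@dataclass
class NetworkModulationConfig:
    """10-input tuned network run at combinations of alpha and presynaptic rate."""

    n_inputs: int = 10
    conditions: tuple[tuple[float, float], ...] = (
        (0.01, 1.0),
        (0.02, 1.0),
        (0.02, 10.0),
    )  # (alpha, nu) pairs
    duration: float = 200.0
    n_trials: int = 50
    initial_pref_index: int = 7
    peak: float = 0.5 * W_MAX
    baseline: float = 0.2 * W_MAX
    profile_width: float = 1.5
    triplet: bool = False
    neuron: NeuronParams = field(default_factory=NeuronParams)
    input_kwargs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.conditions:
            raise ConfigurationError("conditions grid must be non-empty")


@dataclass
class NetworkModulationResult:
    initial_rescaled: np.ndarray
    initial_width: float
    table: pd.DataFrame  # columns: alpha, nu, final_width, sharpened
    final_rescaled: dict  # (alpha, nu) -> mean rescaled final curve

    def width(self, alpha: float, nu: float) -> float:
        t = self.table
        return float(t[(t.alpha == alpha) & (t.nu == nu)].final_width.iloc[0])


def run_modulation_network(
    config: NetworkModulationConfig, seed: int
) -> NetworkModulationResult:
    """Initial vs final rescaled tuning curves under each (alpha, nu) condition.

    Curves are rescaled by their maximum weight before comparison; the
    tuning-width statistic is the linearly interpolated width at half
    maximum of the trial-mean rescaled curve.
    """
    w0 = tuned_profile(
        config.n_inputs,
        config.initial_pref_index,
        config.peak,
        config.baseline,
        config.profile_width,
    )
    init_rescaled = rescale_tuning(w0)
    init_width = width_at_half_max(init_rescaled)
    seeds = trial_seeds(seed, config.n_trials)
    rows = []
    curves = {}
    for alpha, nu in config.conditions:
        rule = _resolve_rule("DP", alpha, triplet=config.triplet)
        in_cfg = InputEnsembleConfig(
            n_inputs=config.n_inputs, base_rate=nu, **config.input_kwargs
        )
        finals = np.empty((config.n_trials, config.n_inputs))
        for k in range(config.n_trials):
            spikes = generate_ensemble(in_cfg, config.duration, int(seeds[k, 0]))
            run = run_plastic_trial(
                spikes,
                w0,
                config.neuron,
                rule,
                int(seeds[k, 1]),
                w_min=W_MIN,
                w_max=W_MAX,
            )
            finals[k] = run.final_weights
        mean_final = finals.mean(axis=0)
        resc = rescale_tuning(mean_final)
        width = width_at_half_max(resc)
        curves[(alpha, nu)] = resc
        rows.append(
            dict(alpha=alpha, nu=nu, final_width=width, sharpened=width < init_width)
        )
    return NetworkModulationResult(
        initial_rescaled=init_rescaled,
        initial_width=init_width,
        table=pd.DataFrame(rows),
        final_rescaled=curves,
    )
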