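# Methods

`modplast` simulates how neuromodulatory state shapes receptive-field
plasticity in a minimal feedforward circuit: N feature-tuned Poisson input
neurons project onto a single leaky integrate-and-fire (LIF) neuron whose
synaptic weights evolve under one of four spike-timing-dependent plasticity
(STDP) learning windows.  Each window stands for a different neuromodulatory
state; two further "modulation" knobs — the global learning rate α and the
presynaptic firing rate ν — stand for plasticity gating and
disinhibition-mediated activity upregulation respectively.

## Input model

Each input channel *i* carries an instantaneous rate r_i(t) built in three
stages:

1. **Signals.** One independent Ornstein–Uhlenbeck process per channel,
   relaxation time 50 ms (`signal_timescale`), stationary SD equal to half
   the base rate (`signal_relative_sd = 0.5`), clipped at zero.  Each signal
   models one sensory feature (a tone, an orientation).
2. **Mixing.** A row-normalized Gaussian kernel over index distance (width
   1 index) mixes the signals into per-neuron rates, so neighbouring inputs
   are correlated, with correlation decaying over ~2 indices.  Feature axes
   are treated as non-circular: the kernel is clipped at the edges and each
   row renormalized (`boundary_mode="wrap"` is available).
3. **Training boost.** In the trained condition one input (index 4 by
   default) is fired at gain 2.0 — 100% stronger — and its immediate
   neighbours at gain 1.5 (offset profile `1 + 0.5·(gain−1)`), so a unit
   gain is exactly neutral.

Spikes are Bernoulli draws per 0.1 ms bin with probability r_i(t)·dt
(piecewise-constant rates on a 1 ms grid); the generator refuses
configurations with r·dt ≥ 1.  The mixing rows summing to one guarantees
every untrained channel averages exactly the base rate, making trained and
untrained ensembles differ only inside the boosted neighbourhood
(bit-identical elsewhere under a shared seed).

What this generator does **not** emulate: refractoriness or burstiness of
real afferents, tonotopic map geometry, stimulus-locked transients, and any
top-down feedback.  Passing tests therefore show that the *plasticity
mechanisms* behave as described for rate-correlated Poisson drive, not that
the specific numbers would transfer to recorded spike trains.

## Postsynaptic neuron

Current-based LIF in arbitrary voltage units: rest 0, threshold 20, reset
0, τ_m = 20 ms, absolute refractory period 2 ms, forward Euler at the shared
0.1 ms clock.  Each presynaptic spike adds `psc_scale · w` to an exponential
synaptic current (τ_syn = 2 ms); `psc_scale = 8` maps one weight unit to a
peak EPSP of ≈0.13 voltage units.  A Gaussian background current
(mean `noise_mean`, white-noise amplitude `noise_sd = 0.8` in
current·√s, giving a stationary membrane SD of ≈4) keeps the neuron
spontaneously active.  `calibrate_noise` bisects on the mean current until
the zero-weight firing rate matches a target; the shipped default
(`noise_mean = 15.46875`) is the output of that calibration for 10 Hz and
is validated by the test suite at 10 ± 1 Hz.

## Plasticity

Pair-based windows, Δt = t_post − t_pre:

    ΔW(Δt) = α · a_causal  · exp(−Δt/τ₊)   (Δt > 0)
    ΔW(Δt) = α · a_acausal · exp(+Δt/τ₋)   (Δt < 0),  ΔW(0) = 0

with τ₊ = τ₋ = 20 ms and unit amplitudes on active branches: DP (+1, −1),
PP (+1, +1), UP (+1, 0), DU (0, −1).  The learning rate α carries the whole
magnitude scale, so the α values of the modulation sweeps (α₀ = 0.0005
upward) are meaningful as window amplitudes.  Pairs interact all-to-all;
the online implementation keeps one pre trace per synapse and one post
trace, decayed lazily with a single `exp` per event, and therefore
reproduces the brute-force all-pairs sum to floating-point precision (the
suite checks 1e−12 relative on random fixtures).  Simultaneous (same-bin)
pre/post spikes contribute nothing — each side's update reads the other
side's trace *before* the coincident spike increments it.

Weights are additive with hard bounds [0, 10] — the combination whose
signature is the bimodal endpoint distribution under competition.  The
closed-form drift for independent Poisson pre/post trains,
ν_pre·ν_post·α·(a₊τ₊ + a₋τ₋), is exposed as `expected_drift` and verified
by frozen-weight simulation; a balanced DP window drifts at zero and a 2%
depression excess gives a significantly negative drift.

**Triplet rule.** The standard two-traces-per-side extension: a slow pre
trace (τ_x = 101 ms) and slow post trace (τ_y = 125 ms); a post spike adds
α·r₁·(a_causal + a3_causal·o₂), a pre spike adds
α·o₁·(a_acausal + a3_acausal·r₂), slow traces read just before the current
spike is added.  With triplet amplitudes zero the code path is literally
the pair rule (bit-identical trajectories).  Default triplet amplitudes are
±0.002 — a small nonlinear correction; larger values make the ν²-scaling
triplet terms dominate at high rates and change which weights grow fastest,
so the size of this correction is an explicit assumption, not a fitted
value.

**Normalization.** Two schemes run on a 100 ms schedule, both conserving
the initial summed weight up to bound clipping:

* *subtractive* (default): add (target − Σw)/N to every weight;
* *multiplicative*: rescale the vector to the target sum (this is also the
  behaviour of the standalone `normalize_weights`).

The subtractive scheme is the default because it is the competitive one:
under it, any rule whose raw drift grows with w (DP, PP, UP) sharpens the
tuning curve, while DU's weight-tracking depression relaxes the curve
toward uniform (flattening).  Multiplicative normalization does the
opposite for PP/UP/DU (the rate-driven, weight-independent part of the
drift then favours relatively faster growth of weak weights) and is kept
available for exactly that comparison.

## Experiments and their parameters

All randomness flows from one master seed through `SeedSequence`; trial k
uses the same two derived seeds (input stream, neuron noise) whether run
alone or in a batch.

**Symmetry breaking** (`01_symmetry_breaking.py`): 100 inputs (50 in the
scaled test), all weights at 2.0, base rate 10 Hz.  DP with 2% depression
excess, α = 0.03, 3600 s (2400 s scaled): weights split to the bounds with
roughly 85–90% potentiated and 10–15% depressed; the bimodality fraction
(weights within 5% of a bound) reaches ≥0.9.  The per-synapse efficacy is
reduced to `psc_scale = 4` here so that the many-input neuron stays in the
fluctuation-driven regime where spike-trigger correlations are steeply
weight-dependent — the competition that separates winners from losers.
The fast saturation runs (PP, UP → upper bound, DU → lower bound within
10 s) use α = 0.2, large enough that one-signed drift traverses the full
weight range in seconds.

**Receptive-field adaptation** (`02_…`, `03_…`): 10 inputs, initial
Gaussian profile peaked at input 7 (peak 4.5, baseline 2.2, width 1.5
indices), α = 0.009, 40 s horizon, 100 trials (10–20 in tests).  The
profile height matters: the trained input can only overtake the preferred
input before everything saturates if the initial peak-to-baseline gap is
smaller than the peak's remaining headroom to w_max; 45%/22% of w_max
satisfies this with margin, and α = 0.009 is large enough that the UP rule
crosses zero specificity by ~30 s yet small enough that PP stays below
saturation without training.  Normalized runs extend to 400 s because the
competitive shift under the antisymmetric DP window is roughly an order of
magnitude slower than under PP.

**Modulation sweeps** (`04_…`, `05_…`): the probe protocol holds the
weight fixed (the accumulated change is recorded but not applied) for 10 s
per trial, 200 trials, at w ∈ {3, 7}; α ∈ {1,2,4,8,16}·α₀ at ν₀ = 10 Hz
and ν ∈ {1…150} Hz at α₀.  Because the weight is frozen, the accumulated
change is exactly proportional to α — the linearity Δw/w = kα is a property
of the protocol — and all stochastic content sits in k's dependence on w
and ν.  k(w=7) > k(w=3) at low ν (threshold nonlinearity: a larger EPSP
recruits disproportionately many extra postsynaptic spikes), while above a
crossover near 40–100 Hz the strongly driven neuron saturates and the weak
weight gains relatively faster.  The network runs (10 inputs, 200 s, 50
trials; 15–20 in tests) translate this into tuning width: at ν = 1 Hz both
α = 0.01 and 0.02 sharpen the rescaled curve, at ν = 10 Hz and α = 0.02 the
curve broadens (the peak saturates at w_max while the flanks keep growing).

## Numerical choices and edge cases

* Euler step 0.1 ms everywhere; rate grids at 1 ms; r·dt and window time
  constants comfortably resolved.
* Ensembles longer than 500 s are generated in chunks with the OU state
  carried across boundaries, so memory stays bounded for the hour-long
  100-input runs; chunked spike-train sets do not retain rate traces.
* Trace decays use one `exp` per event (no per-step multiplication), so
  online/oracle agreement is limited only by rounding (~1e−13).
* `width_at_half_max` linearly interpolates the crossings of 0.5 on the
  rescaled curve; a curve at or above 0.5 everywhere returns the full index
  extent N−1 (the "flat" convention), a single-point peak returns ≤1.
* Normalization on an all-zero vector is a no-op in the simulation loop
  (and an error in the standalone op); Δt = 0 pairings contribute zero.
* Ties in `argmax` of a saturated mean weight vector resolve to the lowest
  index; experiment parameters were chosen so the relevant peaks are
  strict.

## Limitations

* Every quantitative parameter of the original study's methods (neuron
  model, window amplitudes, signal statistics, normalization scheme and
  schedule, run lengths) is unpublished in the main text; the values here
  are this package's own choices, selected once so that each documented
  qualitative regime is realized, and all are exposed in the configs.
* The ν crossover location depends on the synaptic efficacy scale and the
  noise operating point; only its existence, not its value, should be read
  as a model prediction.
* Single postsynaptic neuron, no inhibitory plasticity, no explicit
  disinhibitory circuit: activity upregulation is modelled directly as a
  presynaptic rate change.
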