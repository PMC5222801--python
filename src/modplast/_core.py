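"""Numba kernel: leaky integrate-and-fire neuron with online STDP.

One time-stepped forward-Euler loop (shared clock with the input module)
integrates the membrane, injects presynaptic current, applies the
triplet-general STDP update event-by-event (pair rules are the special case
with zero triplet amplitudes, so pair and triplet runs share one code path
bit-for-bit), enforces hard weight bounds, and optionally applies
multiplicative normalization on a fixed schedule.

Eligibility traces are decayed lazily (one ``exp`` per access, from the
trace's last event), so per-step cost is dominated by the membrane update.

Plasticity sign/ordering conventions match :mod:`modplast.plasticity`:
simultaneous (same-bin) pre and post spikes contribute nothing, because each
update reads the opposite side's traces before the coincident spike is added.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["run_lif_stdp"]


@njit(cache=True)
def run_lif_stdp(
    spike_bins,  # int64 (E,), sorted
    spike_ids,  # int64 (E,), 0-based synapse index
    n_inputs,
    n_bins,
    dt,
    w_init,  # float64 (n,)
    w_min,
    w_max,
    tau_m,
    v_rest,
    v_thresh,
    v_reset,
    ref_bins,
    tau_syn,
    j_psc,
    noise_mean,
    noise_sd,
    alpha,
    a_causal,
    a_acausal,
    tau_causal,
    tau_acausal,
    a3_causal,
    a3_acausal,
    tau_x,
    tau_y,
    freeze_weights,
    norm_every_bins,  # 0 disables normalization
    norm_target,
    norm_subtractive,  # True: equal additive correction; False: multiplicative
    record_every_bins,  # 0 -> record only initial and final
    seed,
):
    np.random.seed(seed)
    w = w_init.copy()
    dw_accum = np.zeros(n_inputs)

    # traces, decayed lazily from their last event bin
    r1 = np.zeros(n_inputs)
    r2 = np.zeros(n_inputs)
    last_pre = np.zeros(n_inputs, np.int64)
    o1 = 0.0
    o2 = 0.0
    last_post = np.int64(0)

    if record_every_bins > 0:
        n_rec = n_bins // record_every_bins + 2
    else:
        n_rec = 2
    w_rec = np.zeros((n_rec, n_inputs))
    t_rec = np.zeros(n_rec)
    w_rec[0] = w
    i_rec = 1

    max_post = n_bins // (ref_bins + 1) + 1
    post_bins = np.empty(max_post, np.int64)
    n_post = 0

    v = v_rest
    i_syn = 0.0
    ref_count = 0
    syn_decay = np.exp(-dt / tau_syn)
    ev = 0
    n_events = spike_bins.shape[0]
    bin_pre = np.empty(64, np.int64)  # pre spikes arriving in the current bin

    alpha_eff = alpha  # frozen runs still accumulate with full alpha
    noise_scale = noise_sd * np.sqrt(dt) / tau_m

    for t in range(n_bins):
        # --- collect this bin's presynaptic spikes, inject current,
        #     apply acausal updates (post traces exclude any same-bin post)
        n_bin_pre = 0
        while ev < n_events and spike_bins[ev] == t:
            i = spike_ids[ev]
            ev += 1
            i_syn += j_psc * w[i]
            if alpha_eff != 0.0:
                # decay traces for synapse i and the post traces to bin t
                d_pre = (t - last_pre[i]) * dt
                r1[i] *= np.exp(-d_pre / tau_causal)
                r2[i] *= np.exp(-d_pre / tau_x)
                last_pre[i] = t
                d_post = (t - last_post) * dt
                o1 *= np.exp(-d_post / tau_acausal)
                o2 *= np.exp(-d_post / tau_y)
                last_post = t
                dw = alpha_eff * o1 * (a_acausal + a3_acausal * r2[i])
                if freeze_weights:
                    dw_accum[i] += dw
                else:
                    w[i] += dw
                    if w[i] < w_min:
                        w[i] = w_min
                    elif w[i] > w_max:
                        w[i] = w_max
            if n_bin_pre < 64:
                bin_pre[n_bin_pre] = i
                n_bin_pre += 1

        # --- membrane update
        noise = noise_mean + 0.0
        xi = np.random.normal(0.0, 1.0)  # drawn every bin to keep streams aligned
        spiked = False
        if ref_count > 0:
            ref_count -= 1
        else:
            v += (dt / tau_m) * (-(v - v_rest) + i_syn + noise) + noise_scale * xi
            if v >= v_thresh:
                spiked = True
                v = v_reset
                ref_count = ref_bins
        i_syn *= syn_decay

        # --- causal updates on a postsynaptic spike
        #     (pre traces exclude same-bin pre spikes: not yet incremented)
        if spiked:
            post_bins[n_post] = t
            n_post += 1
            if alpha_eff != 0.0:
                d_post = (t - last_post) * dt
                o1 *= np.exp(-d_post / tau_acausal)
                o2 *= np.exp(-d_post / tau_y)
                last_post = t
                for i in range(n_inputs):
                    d_pre = (t - last_pre[i]) * dt
                    r1[i] *= np.exp(-d_pre / tau_causal)
                    r2[i] *= np.exp(-d_pre / tau_x)
                    last_pre[i] = t
                    dw = alpha_eff * r1[i] * (a_causal + a3_causal * o2)
                    if freeze_weights:
                        dw_accum[i] += dw
                    else:
                        w[i] += dw
                        if w[i] < w_min:
                            w[i] = w_min
                        elif w[i] > w_max:
                            w[i] = w_max
                o1 += 1.0
                o2 += 1.0

        # --- increment pre traces for this bin's spikes (after any post update)
        if alpha_eff != 0.0:
            for k in range(n_bin_pre):
                i = bin_pre[k]
                r1[i] += 1.0
                r2[i] += 1.0

        # --- scheduled multiplicative normalization
        if (
            norm_every_bins > 0
            and not freeze_weights
            and t > 0
            and (t + 1) % norm_every_bins == 0
        ):
            s = 0.0
            for i in range(n_inputs):
                s += w[i]
            if norm_subtractive:
                delta = (norm_target - s) / n_inputs
                for i in range(n_inputs):
                    w[i] += delta
                    if w[i] < w_min:
                        w[i] = w_min
                    elif w[i] > w_max:
                        w[i] = w_max
            elif s > 0.0:
                scale = norm_target / s
                for i in range(n_inputs):
                    w[i] *= scale
                    if w[i] < w_min:
                        w[i] = w_min
                    elif w[i] > w_max:
                        w[i] = w_max

        # --- record
        if record_every_bins > 0 and (t + 1) % record_every_bins == 0:
            w_rec[i_rec] = w
            t_rec[i_rec] = (t + 1) * dt
            i_rec += 1

    # final state always recorded as the last row
    t_end = n_bins * dt
    if t_rec[i_rec - 1] != t_end:
        w_rec[i_rec] = w
        t_rec[i_rec] = t_end
        i_rec += 1

    return post_bins[:n_post].copy(), t_rec[:i_rec].copy(), w_rec[:i_rec].copy(), w, dw_accum
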