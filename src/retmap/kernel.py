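"""Millisecond-resolution spike-processing kernel.

The engine advances neurons and synaptic trophic state in 500 ms windows.
Within a window everything happens at the 1 ms simulation timestep:
presynaptic spikes update their synapses' cleft bookkeeping and feed the
postsynaptic input traces; neurons integrate, fire and reset; postsynaptic
spikes convert cleft pro-factor to growth factor on every synapse of the
firing cell.  The kernel maintains an active set (neurons with non-negligible
state or in-flight input), so silent stretches between retinal waves cost
nothing — state decays below 1e-12 are flushed to exactly zero, which makes
skipping silent windows bit-identical to stepping through them.

The numerics mirror ``NeuronPopulation.integrate_step`` and the scalar
``on_pre_spike`` / ``on_post_spike`` functions exactly; the test suite checks
the kernel against those reference implementations event-for-event.
"""

from __future__ import annotations

import numpy as np
from numba import njit

EPS = 1e-12


@njit(cache=True)
def step_window(  # noqa: C901 - hot loop, deliberately monolithic
    t0_ms,
    n_ms,
    ev_ms,          # int64[:] event times (sorted), absolute ms
    ev_rgc,         # int32[:] presynaptic cell per event
    pre_indptr,     # CSR rgc -> synapse ids
    pre_syn,
    post_indptr,    # CSR post cell -> synapse ids
    post_syn,
    syn_post,       # int32[:] postsynaptic cell per synapse
    syn_aff,        # float64[:] chemoaffinity per synapse
    syn_t,          # float64[:] trophic state (updated in place)
    syn_cleft,      # float64[:] cleft pro-factor (updated in place)
    syn_last,       # float64[:] last event time, ms (updated in place)
    exc,            # float64[:] neuron excitation E (in place)
    syn_in,         # float64[:] neuron input trace I (in place)
    size,           # float64[:] neuron size S
    h,              # float64[:] homeostatic scale
    refr,           # int32[:] refractory countdown (in place)
    release_mod,    # float64[:] trophic-release modifier per neuron
    threshold,
    alpha_m,
    alpha_ampa,
    att0,
    att1,
    refractory_ms,
    destab_rate,
    stab_rate,
    inv_tau_coinc,
    trophic_on,     # bool: post-spike trophic conversion enabled
    sec_counts,     # int64[:] per-neuron spike counts (accumulated in place)
    fired_cell,     # int32[:] output buffer of firing neurons
    fired_ms,       # int64[:] output buffer of firing times
):
    n_neurons = exc.shape[0]
    in_count = np.zeros(n_neurons, dtype=np.int64)
    active = np.empty(n_neurons, dtype=np.int64)
    is_active = np.zeros(n_neurons, dtype=np.uint8)
    n_active = 0
    for i in range(n_neurons):
        if exc[i] > EPS or syn_in[i] > EPS or refr[i] > 0:
            active[n_active] = i
            is_active[i] = 1
            n_active += 1
    n_fired = 0
    cap = fired_cell.shape[0]
    ev_i = 0
    n_ev = ev_ms.shape[0]
    for step in range(n_ms):
        t = t0_ms + step
        # deliver presynaptic spikes scheduled for this millisecond
        while ev_i < n_ev and ev_ms[ev_i] == t:
            rgc = ev_rgc[ev_i]
            for k in range(pre_indptr[rgc], pre_indptr[rgc + 1]):
                s = pre_syn[k]
                dt = t - syn_last[s]
                bound = syn_cleft[s] * (1.0 - np.exp(-dt * inv_tau_coinc))
                tval = syn_t[s] - destab_rate * syn_aff[s] * bound
                syn_t[s] = tval if tval > 0.0 else 0.0
                syn_cleft[s] = syn_cleft[s] - bound + 1.0
                syn_last[s] = t
                post = syn_post[s]
                in_count[post] += 1
                if is_active[post] == 0:
                    active[n_active] = post
                    is_active[post] = 1
                    n_active += 1
            ev_i += 1
        # integrate the active set
        w = 0
        for a in range(n_active):
            i = active[a]
            ii = syn_in[i] * alpha_ampa + h[i] * in_count[i]
            in_count[i] = 0
            drive = ii / (att0 + att1 * size[i])
            ee = exc[i] * alpha_m + (1.0 - alpha_m) * drive
            fired = False
            if refr[i] <= 0 and ee >= threshold:
                fired = True
                ee = 0.0
                refr[i] = refractory_ms
            if refr[i] > 0:
                refr[i] -= 1
            if fired:
                sec_counts[i] += 1
                if n_fired < cap:
                    fired_cell[n_fired] = i
                    fired_ms[n_fired] = t
                n_fired += 1
                if trophic_on:
                    for k in range(post_indptr[i], post_indptr[i + 1]):
                        s = post_syn[k]
                        dt = t - syn_last[s]
                        bound = syn_cleft[s] * (1.0 - np.exp(-dt * inv_tau_coinc))
                        nt = syn_cleft[s] - bound
                        tval = syn_t[s] - destab_rate * syn_aff[s] * bound
                        if tval < 0.0:
                            tval = 0.0
                        tval = tval + stab_rate * syn_aff[s] * release_mod[i] * nt
                        syn_t[s] = tval if tval < 1.0 else 1.0
                        syn_cleft[s] = 0.0
                        syn_last[s] = t
            if ee <= EPS and ii <= EPS and refr[i] == 0:
                is_active[i] = 0  # flush to exact zero; neuron leaves the set
                exc[i] = 0.0
                syn_in[i] = 0.0
            else:
                exc[i] = ee
                syn_in[i] = ii
                active[w] = i
                w += 1
        n_active = w
    return n_fired
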