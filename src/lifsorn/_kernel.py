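"""Numba-compiled inner loop advancing the network one chunk of fixed steps.

The kernel mirrors, step for step, the pure-Python reference in
:mod:`lifsorn.dynamics` (``_step_chunk_python``); both consume the same
pre-drawn noise array so their outputs agree to floating tolerance and
can be cross-checked in tests.  Per-step order of operations:

1. membrane integration with the Ornstein-Uhlenbeck noise increment
2. spike detection and reset
3. nearest-neighbour STDP for every excitatory spike (partner times
   taken *before* this step's spikes are registered, so simultaneous
   pre/post spikes pair with the partner's previous spike; spikers are
   processed in ascending neuron id)
4. short-term-plasticity update and delayed delivery scheduling
5. spike registration (last-spike memory, counters, record)
6. delivery of all events due this step
7. intrinsic-plasticity threshold update

Once-per-second mechanisms (normalization, growth, pruning, snapshots)
run between chunks in :class:`lifsorn.dynamics.Network`.
"""

import numpy as np
from numba import njit

__all__ = ["step_chunk"]


@njit(cache=True)
def step_chunk(
    step0,
    n_steps,
    dt,
    e_l,
    tau_m,
    noise_coef,
    noise,
    V,
    V_T,
    v_reset,
    n_exc,
    W,
    adj,
    creation_step,
    last_spike,
    mod_ee,
    mod_ei,
    mod_ie,
    mod_ii,
    stp_x,
    stp_u,
    stp_U,
    tau_d,
    tau_f,
    stdp_on,
    a_plus,
    a_minus,
    tau_plus,
    tau_minus,
    w_max,
    ip_on,
    ip_mask,
    eta_ip,
    h_ip,
    ei_ptr,
    ei_tgt,
    w_ei,
    ie_ptr,
    ie_tgt,
    w_ie,
    ii_ptr,
    ii_tgt,
    w_ii,
    d_ee,
    d_ei,
    d_ie,
    d_ii,
    buf,
    rec_id,
    rec_step,
    spike_counts,
):
    N = V.shape[0]
    D = buf.shape[0]
    cap = rec_id.shape[0]
    n_rec = 0
    overflow = False
    spikers = np.empty(N, np.int64)
    spiked = np.zeros(N, np.bool_)
    for s in range(n_steps):
        g = step0 + s
        # 1. membrane + noise (Euler-Maruyama, stationary sd = sigma)
        for n in range(N):
            V[n] += dt * (e_l - V[n]) / tau_m + noise_coef * noise[s, n]
        # 2. threshold / reset
        n_spk = 0
        for n in range(N):
            if spiked[n]:
                spiked[n] = False
            if V[n] >= V_T[n]:
                spikers[n_spk] = n
                n_spk += 1
                spiked[n] = True
                V[n] = v_reset[n]
        # 3. STDP, ascending spiker id, pre-step spike memory
        if stdp_on:
            for k in range(n_spk):
                i = spikers[k]
                if i < n_exc:
                    for p in range(n_exc):
                        if (
                            adj[p, i]
                            and last_spike[p] >= 0
                            and last_spike[p] >= creation_step[p, i]
                        ):
                            w = W[p, i] + a_plus * np.exp(
                                -((g - last_spike[p]) * dt) / tau_plus
                            )
                            W[p, i] = w if w < w_max else w_max
                    for q in range(n_exc):
                        if (
                            adj[i, q]
                            and last_spike[q] >= 0
                            and last_spike[q] >= creation_step[i, q]
                        ):
                            w = W[i, q] - a_minus * np.exp(
                                -((g - last_spike[q]) * dt) / tau_minus
                            )
                            W[i, q] = w if w > 0.0 else 0.0
        # 4. STP + schedule deliveries
        for k in range(n_spk):
            i = spikers[k]
            is_exc = i < n_exc
            update_stp = (mod_ee or mod_ei) if is_exc else (mod_ie or mod_ii)
            factor = 1.0
            if update_stp:
                x = stp_x[i]
                u = stp_u[i]
                if last_spike[i] >= 0:
                    dtms = (g - last_spike[i]) * dt
                    x = 1.0 - (1.0 - x) * np.exp(-dtms / tau_d)
                    u = stp_U + (u - stp_U) * np.exp(-dtms / tau_f)
                x = x * (1.0 - u)
                u = u + stp_U * (1.0 - u)
                stp_x[i] = x
                stp_u[i] = u
                factor = u * x
            if is_exc:
                f_ee = factor if mod_ee else 1.0
                slot = (g + d_ee) % D
                for q in range(n_exc):
                    if adj[i, q]:
                        buf[slot, q] += f_ee * W[i, q]
                f_ei = factor * w_ei if mod_ei else w_ei
                slot = (g + d_ei) % D
                for e in range(ei_ptr[i], ei_ptr[i + 1]):
                    buf[slot, ei_tgt[e]] += f_ei
            else:
                j = i - n_exc
                f_ie = factor * w_ie if mod_ie else w_ie
                slot = (g + d_ie) % D
                for e in range(ie_ptr[j], ie_ptr[j + 1]):
                    buf[slot, ie_tgt[e]] += f_ie
                f_ii = factor * w_ii if mod_ii else w_ii
                slot = (g + d_ii) % D
                for e in range(ii_ptr[j], ii_ptr[j + 1]):
                    buf[slot, ii_tgt[e]] += f_ii
        # 5. register spikes
        for k in range(n_spk):
            i = spikers[k]
            last_spike[i] = g
            spike_counts[i] += 1
            if n_rec < cap:
                rec_id[n_rec] = i
                rec_step[n_rec] = g
                n_rec += 1
            else:
                overflow = True
        # 6. deliver events due now
        slot = g % D
        for n in range(N):
            V[n] += buf[slot, n]
            buf[slot, n] = 0.0
        # 7. intrinsic plasticity
        if ip_on:
            for n in range(N):
                if ip_mask[n]:
                    ind = 1.0 if spiked[n] else 0.0
                    V_T[n] += eta_ip * (ind - h_ip[n])
    return n_rec, overflow
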