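"""Clock-driven integration kernel.

A single jitted loop advances all Hodgkin-Huxley cells with a fixed
step, delivers delayed synaptic events through a ring buffer and records
threshold crossings.  The per-cell update order matches
:func:`chromanet.membrane.advance_neuron` exactly (deliver, decay,
exponential-Euler gating at the pre-step voltage, forward voltage
update), so the scalar path serves as its reference implementation.

Edges are stored CSR-sorted by global source id; targets are local
indices into the Hodgkin-Huxley state arrays.  Spike-generator cells
(photoreceptors) appear only as edge sources via the pre-scheduled
``in_steps``/``in_cells`` event list.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = ["simulate"]


@njit(cache=True, fastmath=True)
def simulate(
    n_steps,
    dt,
    c_total,
    g_leak,
    e_leak,
    g_na,
    e_na,
    g_k,
    e_k,
    tau_ampa,
    e_ampa,
    tau_gaba,
    e_gaba,
    v_thresh,
    refrac_ms,
    v,
    m,
    h,
    n,
    g_a,
    g_g,
    refrac_until,
    buf_a,
    buf_g,
    indptr,
    e_tgt,
    e_w,
    e_delay_steps,
    e_is_gaba,
    in_steps,
    in_cells,
    n_input,
    rec_cell,
    rec_step,
):
    """Advance ``n_steps``; returns (n_recorded, err_cell, err_step).

    ``err_cell`` is -1 on success; otherwise the local index of the cell
    whose voltage left the finite range (integration divergence).
    State arrays and ring buffers are modified in place.
    """
    buf_len = buf_a.shape[0]
    n_hh = v.shape[0]
    decay_a = math.exp(-dt / tau_ampa)
    decay_g = math.exp(-dt / tau_gaba)
    cap = rec_cell.shape[0]
    ip = 0
    n_in = in_steps.shape[0]
    n_rec = 0

    for t in range(n_steps):
        # scatter generator spikes scheduled for this step
        while ip < n_in and in_steps[ip] == t:
            c = in_cells[ip]
            for e in range(indptr[c], indptr[c + 1]):
                slot = (t + e_delay_steps[e]) % buf_len
                if e_is_gaba[e]:
                    buf_g[slot, e_tgt[e]] += e_w[e]
                else:
                    buf_a[slot, e_tgt[e]] += e_w[e]
            ip += 1

        slot_now = t % buf_len
        t_end = (t + 1) * dt
        for i in range(n_hh):
            v0 = v[i]
            ga = (g_a[i] + buf_a[slot_now, i]) * decay_a
            gg = (g_g[i] + buf_g[slot_now, i]) * decay_g
            buf_a[slot_now, i] = 0.0
            buf_g[slot_now, i] = 0.0

            # gating rates at the pre-step voltage
            x = v0 + 40.0
            if abs(x) < 1e-7:
                am = 1.0
            else:
                am = 0.1 * x / (1.0 - math.exp(-x / 10.0))
            bm = 4.0 * math.exp(-(v0 + 65.0) / 18.0)
            ah = 0.07 * math.exp(-(v0 + 65.0) / 20.0)
            bh = 1.0 / (1.0 + math.exp(-(v0 + 35.0) / 10.0))
            x = v0 + 55.0
            if abs(x) < 1e-7:
                an = 0.1
            else:
                an = 0.01 * x / (1.0 - math.exp(-x / 10.0))
            bn = 0.125 * math.exp(-(v0 + 65.0) / 80.0)

            s = am + bm
            m[i] = am / s + (m[i] - am / s) * math.exp(-dt * s)
            s = ah + bh
            h[i] = ah / s + (h[i] - ah / s) * math.exp(-dt * s)
            s = an + bn
            n[i] = an / s + (n[i] - an / s) * math.exp(-dt * s)

            i_leak = g_leak * (v0 - e_leak)
            i_na = g_na * m[i] * m[i] * m[i] * h[i] * (v0 - e_na)
            i_k = g_k * n[i] * n[i] * n[i] * n[i] * (v0 - e_k)
            i_syn = ga * (v0 - e_ampa) + gg * (v0 - e_gaba)
            v1 = v0 + dt * (-(i_leak + i_na + i_k + i_syn)) / c_total
            if not math.isfinite(v1):
                return n_rec, i, t
            v[i] = v1
            g_a[i] = ga
            g_g[i] = gg

            if v0 < v_thresh <= v1 and t_end >= refrac_until[i]:
                refrac_until[i] = t_end + refrac_ms
                if n_rec < cap:
                    rec_cell[n_rec] = i
                    rec_step[n_rec] = t + 1
                    n_rec += 1
                # scatter outgoing events of this cortical cell
                gid = n_input + i
                for e in range(indptr[gid], indptr[gid + 1]):
                    slot = (t + 1 + e_delay_steps[e]) % buf_len
                    if e_is_gaba[e]:
                        buf_g[slot, e_tgt[e]] += e_w[e]
                    else:
                        buf_a[slot, e_tgt[e]] += e_w[e]
    return n_rec, -1, -1
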