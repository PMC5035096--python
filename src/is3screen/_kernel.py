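"""Numba core of the branched-cable integrator.

One fused routine advances membrane voltage and channel gating states.
Gating uses exponential (Rush-Larsen) updates at the previous voltage;
the voltage step is implicit (backward Euler, or Crank-Nicolson via the
theta parameter) and solves the tree-structured linear system directly
with a leaf-to-root Hines elimination -- compartments are ordered so
``parent[i] < i``.

Channels are stored sparsely as (channel, compartment) pairs restricted
to compartments with nonzero maximal conductance, so somatic-only
scenarios do no gating work in the dendrites.

Units: mV, ms, nF, uS, nA.
"""

import math

import numpy as np
from numba import njit

TAU_CONSTANT = 0
TAU_BELL = 1
TAU_SIGMOID = 2


@njit(cache=True, inline="always")
def _gate_inf_tau(v, vhalf, k, form, p):
    inf = 1.0 / (1.0 + math.exp(-(v - vhalf) / k))
    if form == TAU_CONSTANT:
        tau = p[0]
    elif form == TAU_BELL:
        tau = p[0] + p[1] / (math.exp((v - p[2]) / p[3]) + math.exp(-(v - p[2]) / p[4]))
    else:
        tau = p[0] + p[1] / (1.0 + math.exp((v - p[2]) / p[3]))
    return inf, tau


@njit(cache=True)
def integrate(
    v, gates, dt, n_steps, theta,
    parent, g_ax, cap, g_leak, e_leak,
    gate_vhalf, gate_k, gate_exp, gate_tau_form, gate_tau_p,
    chan_gate_ptr, chan_erev,
    pair_ptr, pair_comp, pair_gbar,
    inj_comp, inj_nA,
    syn_comp, syn_g, syn_e,
    rec_idx, v_out,
):
    """Advance ``n_steps`` of length ``dt``; mutates v, gates, v_out.

    Returns -1 on success, else the 1-based step at which the state became
    non-finite (the caller raises with this diagnostic).

    Sparse channel layout: channel c owns gates
    ``chan_gate_ptr[c]:chan_gate_ptr[c+1]`` and compartment pairs
    ``pair_ptr[c]:pair_ptr[c+1]``; ``gates`` has one row per (gate, pair)
    slot, aligned so gate g of channel c at pair j uses row ``g`` column
    ``pair_comp[j]`` -- gates are stored per compartment, but only active
    columns are ever touched.
    """
    n_comp = v.shape[0]
    n_chan = chan_gate_ptr.shape[0] - 1

    d = np.empty(n_comp)
    rhs = np.empty(n_comp)
    gm = np.empty(n_comp)
    be = np.empty(n_comp)

    for r in range(rec_idx.shape[0]):
        v_out[r, 0] = v[rec_idx[r]]

    for step in range(n_steps):
        # --- gating update (exponential Euler) on active compartments only
        for c in range(n_chan):
            for g in range(chan_gate_ptr[c], chan_gate_ptr[c + 1]):
                form = gate_tau_form[g]
                vhalf = gate_vhalf[g]
                k = gate_k[g]
                p = gate_tau_p[g]
                for j in range(pair_ptr[c], pair_ptr[c + 1]):
                    i = pair_comp[j]
                    inf, tau = _gate_inf_tau(v[i], vhalf, k, form, p)
                    gates[g, i] = inf + (gates[g, i] - inf) * math.exp(-dt / tau)

        # --- membrane conductance and reversal-weighted source terms
        for i in range(n_comp):
            gm[i] = g_leak[i]
            be[i] = g_leak[i] * e_leak[i]
        for c in range(n_chan):
            erev = chan_erev[c]
            for j in range(pair_ptr[c], pair_ptr[c + 1]):
                i = pair_comp[j]
                o = 1.0
                for g in range(chan_gate_ptr[c], chan_gate_ptr[c + 1]):
                    x = gates[g, i]
                    xe = x
                    for _ in range(gate_exp[g] - 1):
                        xe *= x
                    o *= xe
                gc = pair_gbar[j] * o
                gm[i] += gc
                be[i] += gc * erev

        # --- assemble (C/dt + theta*G) V_new = C/dt V + theta*b + (1-theta)(b - G V)
        for i in range(n_comp):
            d[i] = cap[i] / dt + theta * gm[i]
            rhs[i] = cap[i] / dt * v[i] + theta * be[i] \
                + (1.0 - theta) * (be[i] - gm[i] * v[i])

        # axial coupling (implicit on the matrix, explicit residue on rhs)
        for i in range(1, n_comp):
            ga = g_ax[i]
            if ga <= 0.0:
                continue
            pidx = parent[i]
            d[i] += theta * ga
            d[pidx] += theta * ga
            if theta < 1.0:
                flow = ga * (v[pidx] - v[i])
                rhs[i] += (1.0 - theta) * flow
                rhs[pidx] -= (1.0 - theta) * flow

        # injected currents
        for j in range(inj_comp.shape[0]):
            rhs[inj_comp[j]] += inj_nA[j, step]

        # synapses: i_syn = g(t) * (v - e), conductance part implicit
        for s in range(syn_comp.shape[0]):
            gs = syn_g[s, step]
            if gs <= 0.0:
                continue
            i = syn_comp[s]
            d[i] += theta * gs
            rhs[i] += theta * gs * syn_e[s] + (1.0 - theta) * gs * (syn_e[s] - v[i])

        # --- Hines solve (off-diagonal between i and parent is -theta*g_ax[i])
        for i in range(n_comp - 1, 0, -1):
            off = -theta * g_ax[i]
            if off == 0.0:
                continue
            pidx = parent[i]
            f = off / d[i]
            d[pidx] -= off * f
            rhs[pidx] -= f * rhs[i]
        v[0] = rhs[0] / d[0]
        for i in range(1, n_comp):
            off = -theta * g_ax[i]
            v[i] = (rhs[i] - off * v[parent[i]]) / d[i]

        for r in range(rec_idx.shape[0]):
            v_out[r, step + 1] = v[rec_idx[r]]

        if step % 64 == 0:
            ok = True
            for i in range(n_comp):
                if not np.isfinite(v[i]) or v[i] > 1000.0 or v[i] < -1000.0:
                    ok = False
            if not ok:
                return step + 1
    for i in range(v.shape[0]):
        if not np.isfinite(v[i]):
            return n_steps
    return -1
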