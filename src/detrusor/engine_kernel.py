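"""Compiled inner loop of the fixed-step integrator.

This is a numba translation of :meth:`detrusor.engine.CompartmentModel.step`
for protocol runs: identical arithmetic, specialized to a fixed reversal
potential for the Ca2+ channels (the Nernst-updated variant falls back to
the numpy path).  A consistency test in the suite holds the two paths to
float agreement.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    HAVE_NUMBA = False

    def njit(*a, **k):
        def wrap(f):
            return f

        return wrap if not (len(a) == 1 and callable(a[0])) else a[0]


@njit(cache=True)
def run_kernel(
    n_steps,
    dt,
    record_every,
    # gates
    g_vhalf, g_slope, g_tau0, g_tauamp, g_tauvmid, g_tausigma,
    g_ca_kd, g_ca_n,
    # channels
    ch_gmax, ch_erev, ch_act, ch_actexp, ch_inact, ch_inactexp, ch_isca,
    # bk (template arrays, see engine._compile_bk_rate_templates)
    bind_mult, unbind_vals, alpha_base, beta_base,
    bk_src, bk_dst, za, zb, vslope, kc4, bk_gmax, bk_erev, bk_o0,
    tadj,
    # leak, calcium
    leak_g, leak_e,
    depth_cm, ca_base, ca_taur, ca_floor,
    # membrane
    area_cm2, c_uf,
    # stimulation: per-step injected current (nA) at one compartment,
    # per-step clamp command (nan = unclamped), synapses
    stim_amp, stim_comp, clamp_cmd,
    syn_comp, syn_g, syn_e,
    # coupling
    cp_i, cp_j, cp_g,
    # state (modified in place)
    v, gates, bk, ca,
    # recording
    rec_comps, rec_t, rec_v, rec_ca, rec_i, record_currents,
):
    n_comp = v.shape[0]
    n_gates = g_vhalf.shape[0]
    n_ch = ch_gmax.shape[0]
    n_sites = rec_comps.shape[0]
    i_chan = np.zeros((n_ch + 2, n_comp))
    q = np.zeros((10, 10, n_comp))
    rates = np.zeros((26, n_comp))
    i_total = np.zeros(n_comp)
    max_dv = 5.0
    t = 0.0
    k_rec = 1  # slot 0 is written by the caller

    for step_i in range(n_steps):
        # ionic currents from the current state
        for c in range(n_ch):
            m = gates[ch_act[c]]
            x = ch_actexp[c]
            h = gates[ch_inact[c]]
            y = ch_inactexp[c]
            for j in range(n_comp):
                po = m[j] ** x if x > 0 else 1.0
                if y > 0:
                    po *= h[j] ** y
                i_chan[c, j] = ch_gmax[c] * po * (v[j] - ch_erev[c])
        for j in range(n_comp):
            o_sum = bk[6, j] + bk[7, j] + bk[8, j] + bk[9, j]
            if bk_o0:
                o_sum += bk[5, j]
            i_chan[n_ch, j] = bk_gmax * o_sum * (v[j] - bk_erev)
            i_chan[n_ch + 1, j] = leak_g * (v[j] - leak_e)

        # HH gating
        for g in range(n_gates):
            for j in range(n_comp):
                minf = 1.0 / (1.0 + np.exp((v[j] + g_vhalf[g]) / g_slope[g]))
                if g_ca_kd[g] == g_ca_kd[g]:  # not nan
                    cn = ca[j] ** g_ca_n[g]
                    minf *= cn / (cn + g_ca_kd[g] ** g_ca_n[g])
                tau = (
                    g_tau0[g]
                    + g_tauamp[g] / np.cosh((v[j] + g_tauvmid[g]) / g_tausigma[g])
                ) / tadj
                mg = gates[g, j] + dt * (minf - gates[g, j]) / tau
                if mg < 0.0:
                    mg = 0.0
                elif mg > 1.0:
                    mg = 1.0
                gates[g, j] = mg

        # BK Markov occupancies
        max_exit = 0.0
        for j in range(n_comp):
            # bind rows 0,2,4,6,8,10,12,14 ; unbind 1,3,..,15
            for r in range(8):
                rates[2 * r, j] = bind_mult[r] * ca[j] * tadj
                rates[2 * r + 1, j] = unbind_vals[r] * tadj
            ea = np.exp(za * v[j] / vslope)
            eb = np.exp(-zb * v[j] / vslope)
            f4 = 0.5 + 0.5 * ca[j] / (ca[j] + kc4)
            for r in range(5):
                a = alpha_base[r] * ea * tadj
                b = beta_base[r] * eb * tadj
                if r == 4:
                    a *= f4
                    b *= f4
                rates[16 + 2 * r, j] = a
                rates[17 + 2 * r, j] = b
        for j in range(n_comp):
            for a in range(10):
                for b in range(10):
                    q[a, b, j] = 0.0
            for e in range(26):
                q[bk_dst[e], bk_src[e], j] += rates[e, j]
            for b in range(10):
                s = 0.0
                for a in range(10):
                    s += q[a, b, j]
                q[b, b, j] -= s
                if s > max_exit:
                    max_exit = s
        n_sub = int(np.ceil(max_exit * dt / 0.1))
        if n_sub < 1:
            n_sub = 1
        h = dt / n_sub
        for _ in range(n_sub):
            for j in range(n_comp):
                dnew = np.zeros(10)
                for a in range(10):
                    acc = 0.0
                    for b in range(10):
                        acc += q[a, b, j] * bk[b, j]
                    dnew[a] = acc
                for a in range(10):
                    bk[a, j] += h * dnew[a]

        # calcium shell
        for j in range(n_comp):
            i_ca = 0.0
            for c in range(n_ch):
                if ch_isca[c]:
                    i_ca += i_chan[c, j]
            dca = -i_ca / (2.0 * 96485.332 * depth_cm) - (ca[j] - ca_base) / ca_taur
            ca[j] += dt * dca
            if ca[j] < ca_floor:
                ca[j] = ca_floor

        # membrane potential
        if clamp_cmd[step_i] == clamp_cmd[step_i]:  # clamped
            for j in range(n_comp):
                v[j] = clamp_cmd[step_i]
        else:
            for j in range(n_comp):
                acc = 0.0
                for c in range(n_ch + 2):
                    acc += i_chan[c, j]
                i_total[j] = -acc * area_cm2 * 1e6
            if stim_comp >= 0:
                i_total[stim_comp] += stim_amp[step_i]
            for s in range(syn_comp.shape[0]):
                g_now = syn_g[s, step_i]
                if g_now > 0.0:
                    i_total[syn_comp[s]] -= g_now * (v[syn_comp[s]] - syn_e[s])
            for p in range(cp_i.shape[0]):
                flow = cp_g[p] * (v[cp_j[p]] - v[cp_i[p]])
                i_total[cp_i[p]] += flow
                i_total[cp_j[p]] -= flow
            for j in range(n_comp):
                dv = dt * 1e-3 * i_total[j] / c_uf
                if dv > max_dv or dv < -max_dv:
                    return -1, t
                v[j] += dv
        t += dt

        if (step_i + 1) % record_every == 0:
            rec_t[k_rec] = t
            for s in range(n_sites):
                rec_v[k_rec, s] = v[rec_comps[s]]
                rec_ca[k_rec, s] = ca[rec_comps[s]]
            if record_currents:
                for c in range(n_ch + 2):
                    rec_i[c, k_rec] = i_chan[c, rec_comps[0]]
            k_rec += 1

    return k_rec, t
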