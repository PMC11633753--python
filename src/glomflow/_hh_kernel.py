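"""Fixed-step cable/Hodgkin-Huxley integration kernel (numba).

One neuron is a chain of cylindrical nodes (distal axon ... soma ... dendrite
... end bulb).  Each step advances the three HH gating variables with the
exponential rule evaluated at the current voltage (staggered update), then
solves the voltage update with a Crank-Nicolson step of the cable equation
(tridiagonal Thomas solve).  The scheme is the fixed-step analogue of
NEURON's ``secondorder=2``: second-order accurate, unconditionally stable,
and it handles the stiff low-capacitance end-bulb node implicitly, which
matters because the spontaneous-firing regime is driven by per-step noise
charge injected exactly there.

Gating rates use the canonical squid-axon parameterization (6.3 degrees C,
voltages in absolute mV).  Rates are tabulated on a 0.05 mV grid and linearly
interpolated, which keeps the per-node cost free of exponentials.

Units inside the kernel: mV, ms, S, and S*mV for currents (1 S*mV = 1 mA);
injected currents are converted from pA at the boundary (1 pA = 1e-12 A =
1e-9 S*mV).
"""

from __future__ import annotations

import numpy as np
from numba import njit

V_TABLE_MIN = -120.0
V_TABLE_MAX = 80.0
V_TABLE_STEP = 0.05

PA = 1e-9  # pA -> S*mV
NS = 1e-9  # nS -> S


def hh_rates(v):
    """Squid-axon HH rate constants (1/ms) at 6.3 C; v in mV (absolute).

    Uses the singularity-free 'vtrap' form of the linear/exponential rates.
    """
    v = np.asarray(v, dtype=float)

    def vtrap(x, y):
        x = np.asarray(x, dtype=float)
        small = np.abs(x / y) < 1e-6
        with np.errstate(over="ignore", invalid="ignore"):
            out = x / (np.exp(x / y) - 1.0)
        return np.where(small, y * (1.0 - x / y / 2.0), out)

    am = 0.1 * vtrap(-(v + 40.0), 10.0)
    bm = 4.0 * np.exp(-(v + 65.0) / 18.0)
    ah = 0.07 * np.exp(-(v + 65.0) / 20.0)
    bh = 1.0 / (1.0 + np.exp(-(v + 35.0) / 10.0))
    an = 0.01 * vtrap(-(v + 55.0), 10.0)
    bn = 0.125 * np.exp(-(v + 65.0) / 80.0)
    return am, bm, ah, bh, an, bn


def gating_tables(dt: float) -> np.ndarray:
    """(n_grid, 6) table of [m_inf, exp(-dt/tau_m), h_inf, ..., n_inf, ...]."""
    v = np.arange(V_TABLE_MIN, V_TABLE_MAX + V_TABLE_STEP / 2, V_TABLE_STEP)
    am, bm, ah, bh, an, bn = hh_rates(v)
    tab = np.empty((v.size, 6))
    for j, (a, b) in enumerate(((am, bm), (ah, bh), (an, bn))):
        tau = 1.0 / (a + b)
        tab[:, 2 * j] = a * tau
        tab[:, 2 * j + 1] = np.exp(-dt / tau)
    return np.ascontiguousarray(tab)


def steady_gates(v):
    am, bm, ah, bh, an, bn = hh_rates(v)
    return am / (am + bm), ah / (ah + bh), an / (an + bn)


@njit(cache=True, inline="always")
def _g_raw(t, wp, t0, td, tx):
    """Raw receptor waveform a+b-c (floored at 0). wp: 11 piecewise constants."""
    t_off = t0 + td * tx
    g = 0.0
    if t0 < t < t_off:
        g += wp[0] / (1.0 + np.exp((wp[1] + t0 - t) / wp[2]))          # a
        if t > t0 + wp[10]:                                            # c window
            g -= wp[7] - (wp[8] + wp[9] * np.exp(-(t - t0 - wp[10]) / wp[6]))
    elif t_off < t < t_off + wp[5]:
        g += wp[3] / (1.0 + np.exp((t - t_off - wp[4]) / wp[11]))      # b
    return g if g > 0.0 else 0.0


@njit(cache=True)
def run_population(
    n_steps,
    dt,
    v0,
    area,          # (n_nodes,) cm^2
    gax,           # (n_nodes-1,) S, coupling between node i and i+1
    cm,            # F/cm^2
    gna_bar,       # S/cm^2
    gk_bar,
    gpas,
    ena,
    ek,
    epas,
    tab,           # gating tables for this dt
    syn_node,      # receptor conductance injection node
    wp,            # (12,) waveform constants (unused if m_scale == 0)
    stim_t0,
    stim_td,
    tx,            # (n_neurons,) per-neuron duration multiplier
    m_scale,       # nS per raw waveform unit; 0 disables the stimulus
    esyn,
    noise_node,
    noise_mean_pa,
    noise_sd_pa,
    inj_node,
    inj_pa,        # (n_steps,) or (1,) injected current trace, pA
    seeds,         # (n_neurons,) rng seeds
    thresh,
    refrac_ms,
    spike_node,
    max_spikes,
    rec_nodes,     # (n_rec_sites,) int64, may be empty
    rec_every,
):
    n_neurons = tx.shape[0]
    n_nodes = area.shape[0]
    spikes = np.full((n_neurons, max_spikes), np.nan)
    n_spk = np.zeros(n_neurons, dtype=np.int64)
    n_rec = rec_nodes.shape[0]
    n_rec_t = (n_steps + rec_every - 1) // rec_every if n_rec > 0 else 0
    vrec = np.zeros((n_neurons, n_rec, n_rec_t))
    grec = np.zeros((n_neurons, n_rec_t)) if n_rec > 0 else np.zeros((n_neurons, 0))
    ok = True

    inv_dv = 1.0 / V_TABLE_STEP
    n_tab = tab.shape[0]
    refrac_steps = int(refrac_ms / dt)
    c_dt = np.empty(n_nodes)
    for i in range(n_nodes):
        c_dt[i] = cm * area[i] / 1e-3 / dt  # S (C*[mV/ms] = S*mV)

    lo = np.empty(n_nodes)  # sum of couplings at node (diag of Laplacian)
    for i in range(n_nodes):
        s = 0.0
        if i > 0:
            s += gax[i - 1]
        if i < n_nodes - 1:
            s += gax[i]
        lo[i] = s

    V = np.empty(n_nodes)
    gm = np.empty(n_nodes)
    gh = np.empty(n_nodes)
    gn = np.empty(n_nodes)
    d = np.empty(n_nodes)
    rhs = np.empty(n_nodes)
    cp = np.empty(n_nodes)
    dp = np.empty(n_nodes)

    for nr in range(n_neurons):
        np.random.seed(seeds[nr])
        for i in range(n_nodes):
            V[i] = v0
        # steady-state gates at v0 (from table, no interpolation needed at init)
        x = (v0 - V_TABLE_MIN) * inv_dv
        ix = int(x)
        if ix < 0:
            ix = 0
        if ix > n_tab - 2:
            ix = n_tab - 2
        w = x - ix
        m0 = tab[ix, 0] * (1 - w) + tab[ix + 1, 0] * w
        h0 = tab[ix, 2] * (1 - w) + tab[ix + 1, 2] * w
        nn0 = tab[ix, 4] * (1 - w) + tab[ix + 1, 4] * w
        for i in range(n_nodes):
            gm[i] = m0
            gh[i] = h0
            gn[i] = nn0

        last_spike = -10 ** 9
        above = V[spike_node] >= thresh
        tx_i = tx[nr]

        for step in range(n_steps):
            t = step * dt
            # --- gating advance (staggered, exponential rule) ---
            for i in range(n_nodes):
                x = (V[i] - V_TABLE_MIN) * inv_dv
                ix = int(x)
                if ix < 0:
                    ix = 0
                elif ix > n_tab - 2:
                    ix = n_tab - 2
                w = x - ix
                w1 = 1.0 - w
                minf = tab[ix, 0] * w1 + tab[ix + 1, 0] * w
                em = tab[ix, 1] * w1 + tab[ix + 1, 1] * w
                hinf = tab[ix, 2] * w1 + tab[ix + 1, 2] * w
                eh = tab[ix, 3] * w1 + tab[ix + 1, 3] * w
                ninf = tab[ix, 4] * w1 + tab[ix + 1, 4] * w
                en = tab[ix, 5] * w1 + tab[ix + 1, 5] * w
                gm[i] = minf + (gm[i] - minf) * em
                gh[i] = hinf + (gh[i] - hinf) * eh
                gn[i] = ninf + (gn[i] - ninf) * en

            # --- assemble ionic conductances and sources ---
            for i in range(n_nodes):
                a_ = area[i]
                m3h = gm[i] * gm[i] * gm[i] * gh[i]
                n4 = gn[i] * gn[i]
                n4 *= n4
                gna = gna_bar * m3h * a_
                gk = gk_bar * n4 * a_
                gl = gpas * a_
                d[i] = gna + gk + gl
                rhs[i] = gna * ena + gk * ek + gl * epas

            # receptor conductance (point process)
            if m_scale > 0.0:
                gs = m_scale * NS * _g_raw(t, wp, stim_t0, stim_td, tx_i)
                d[syn_node] += gs
                rhs[syn_node] += gs * esyn
                if n_rec > 0 and step % rec_every == 0:
                    grec[nr, step // rec_every] = gs
            # noise current
            if noise_sd_pa > 0.0 or noise_mean_pa != 0.0:
                i_n = noise_mean_pa + noise_sd_pa * np.random.standard_normal()
                rhs[noise_node] += i_n * PA
            # injected current trace
            if inj_pa.shape[0] > 1:
                rhs[inj_node] += inj_pa[step] * PA
            elif inj_pa[0] != 0.0:
                rhs[inj_node] += inj_pa[0] * PA

            # --- Crank-Nicolson voltage update, Thomas solve ---
            # (c_dt + (L+G)/2) Vn = (c_dt - (L+G)/2) V + rhs
            # where L is the axial Laplacian and G=diag(d).
            for i in range(n_nodes):
                av = lo[i] * V[i]
                if i > 0:
                    av -= gax[i - 1] * V[i - 1]
                if i < n_nodes - 1:
                    av -= gax[i] * V[i + 1]
                rhs[i] += c_dt[i] * V[i] - 0.5 * (av + d[i] * V[i])
                d[i] = c_dt[i] + 0.5 * (lo[i] + d[i])

            if n_nodes == 1:
                V[0] = rhs[0] / d[0]
                cp[0] = 0.0
            else:
                cp[0] = -0.5 * gax[0] / d[0]
            dp[0] = rhs[0] / d[0]
            for i in range(1, n_nodes):
                den = d[i] - (-0.5 * gax[i - 1]) * cp[i - 1]
                if i < n_nodes - 1:
                    cp[i] = -0.5 * gax[i] / den
                dp[i] = (rhs[i] - (-0.5 * gax[i - 1]) * dp[i - 1]) / den
            V[n_nodes - 1] = dp[n_nodes - 1]
            for i in range(n_nodes - 2, -1, -1):
                V[i] = dp[i] - cp[i] * V[i + 1]

            if not (-200.0 < V[syn_node] < 200.0):
                ok = False
                break

            # --- spike detection (upward crossing with refractory lockout) ---
            v_sp = V[spike_node]
            if v_sp >= thresh:
                if not above and step - last_spike >= refrac_steps:
                    if n_spk[nr] < max_spikes:
                        spikes[nr, n_spk[nr]] = t
                        n_spk[nr] += 1
                    last_spike = step
                above = True
            else:
                above = False

            if n_rec > 0 and step % rec_every == 0:
                for j in range(n_rec):
                    vrec[nr, j, step // rec_every] = V[rec_nodes[j]]

        if not ok:
            break

    return spikes, n_spk, vrec, grec, ok
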