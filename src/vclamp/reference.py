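"""Independent reference integrator for validating the production scheme.

A classic fixed-step 4th-order Runge-Kutta integrator that evaluates the
gating equations directly (tanh sigmoids and bell-shaped time constants, no
lookup tables, no exponential-Euler splitting).  It shares nothing with the
production kernel beyond the model definition, so agreement of spike counts
and spike times between the two is a meaningful check of both.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from ._kernel import flatten_model, KIND_CA_GATED, KIND_CA_SOURCE
from .biophys import NeuronModel, steady_state

__all__ = ["rk4_spike_counts"]


def _gate_params(flat):
    n = max(1, len(flat.gates))
    P = np.zeros((n, 6))
    for i, g in enumerate(flat.gates):
        P[i] = [g.V_half, g.V_slope, g.tau_max, g.tau_min, g.V_tau_half, g.V_tau_slope]
    return P


def rk4_spike_counts(
    model: NeuronModel,
    amplitudes,
    *,
    sweep_duration: float,
    stim_on: float,
    stim_off: float,
    dt: float = 0.00625,
    spike_threshold: float = -10.0,
    spike_guard: float = 2.0,
    settle_time: float = 2000.0,
):
    """Spike counts and times per sweep under a current-step protocol.

    State carries across sweeps; the run starts from a ``settle_time``
    zero-input integration of the steady-state-initialized model.
    """
    amplitudes = np.asarray(amplitudes, dtype=np.float64)
    flat = flatten_model(model)
    P = _gate_params(flat)
    V = np.array(model.E_leak, dtype=np.float64)
    m = np.zeros(flat.n_inst)
    h = np.ones(flat.n_inst)
    ca0 = flat.ca_rest if flat.ca_on else 0.0
    for i in range(flat.n_inst):
        cur = model.currents[flat.cur_index[i]]
        v = V[flat.comp[i]]
        if cur.activation is not None:
            m[i] = float(steady_state(v, cur.activation))
        else:
            m[i] = ca0 / (ca0 + flat.kca_half)
        if cur.inactivation is not None:
            h[i] = float(steady_state(v, cur.inactivation))
    y = np.concatenate([V, m, h, [ca0]])
    n_settle = int(round(settle_time / dt))
    n_step = int(round(sweep_duration / dt))
    counts, times = _rk4_loop(
        flat.C, flat.g_leak, flat.E_leak, flat.g_sx, flat.g_sd,
        flat.comp, flat.g, flat.E, flat.p, flat.kind, flat.gate_a, flat.gate_h,
        P, flat.ca_on, flat.ca_phi, flat.ca_rest, flat.ca_tau, flat.kca_half,
        dt, amplitudes, int(round(stim_on / dt)), int(round(stim_off / dt)),
        n_step, n_settle, y, spike_threshold, spike_guard,
    )
    return counts, times


@njit(cache=True)
def _deriv(y, I_inj,
           C, gL, EL, gsx, gsd, comp, g, E, p, kind, ga, gh, P,
           ca_on, ca_phi, ca_rest, ca_tau, kca_half):
    ninst = comp.shape[0]
    dy = np.zeros_like(y)
    V0, V1, V2 = y[0], y[1], y[2]
    Ca = y[3 + 2 * ninst]
    I = np.zeros(3)
    Ica = 0.0
    for i in range(ninst):
        c = comp[i]
        Vc = y[c]
        mi = y[3 + i]
        hi = y[3 + ninst + i]
        if kind[i] == 2:
            act = Ca / (Ca + kca_half)
            cur = g[i] * act * (E[i] - Vc)
        else:
            gp = P[ga[i]]
            minf = 0.5 + 0.5 * np.tanh((Vc - gp[0]) / gp[1])
            t = np.tanh((Vc - gp[4]) / gp[5])
            tau = (gp[2] - gp[3]) * (1.0 - t * t) + gp[3]
            dy[3 + i] = (minf - mi) / tau
            mp = mi
            for _ in range(p[i] - 1):
                mp *= mi
            hv = 1.0
            if gh[i] >= 0:
                hp = P[gh[i]]
                hinf = 0.5 + 0.5 * np.tanh((Vc - hp[0]) / hp[1])
                th = np.tanh((Vc - hp[4]) / hp[5])
                tauh = (hp[2] - hp[3]) * (1.0 - th * th) + hp[3]
                dy[3 + ninst + i] = (hinf - hi) / tauh
                hv = hi
            cur = g[i] * mp * hv * (E[i] - Vc)
        if kind[i] == 1:
            Ica += cur
        I[c] += cur
    I[0] += gL[0] * (EL[0] - V0) + gsx * (V1 - V0) + gsd * (V2 - V0) + I_inj
    I[1] += gL[1] * (EL[1] - V1) + gsx * (V0 - V1)
    I[2] += gL[2] * (EL[2] - V2) + gsd * (V0 - V2)
    dy[0] = I[0] / C[0]
    dy[1] = I[1] / C[1]
    dy[2] = I[2] / C[2]
    if ca_on:
        dy[3 + 2 * ninst] = ca_phi * Ica - (Ca - ca_rest) / ca_tau
    return dy


@njit(cache=True)
def _rk4_loop(C, gL, EL, gsx, gsd, comp, g, E, p, kind, ga, gh, P,
              ca_on, ca_phi, ca_rest, ca_tau, kca_half,
              dt, amps, i_on, i_off, n_step, n_settle, y,
              sp_thresh, guard):
    n_sweep = amps.shape[0]
    counts = np.zeros(n_sweep, np.int64)
    times = np.full((n_sweep, 512), np.nan)

    def step(y, I_inj):
        k1 = _deriv(y, I_inj, C, gL, EL, gsx, gsd, comp, g, E, p, kind, ga, gh, P,
                    ca_on, ca_phi, ca_rest, ca_tau, kca_half)
        k2 = _deriv(y + 0.5 * dt * k1, I_inj, C, gL, EL, gsx, gsd, comp, g, E, p,
                    kind, ga, gh, P, ca_on, ca_phi, ca_rest, ca_tau, kca_half)
        k3 = _deriv(y + 0.5 * dt * k2, I_inj, C, gL, EL, gsx, gsd, comp, g, E, p,
                    kind, ga, gh, P, ca_on, ca_phi, ca_rest, ca_tau, kca_half)
        k4 = _deriv(y + dt * k3, I_inj, C, gL, EL, gsx, gsd, comp, g, E, p,
                    kind, ga, gh, P, ca_on, ca_phi, ca_rest, ca_tau, kca_half)
        return y + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)

    for _ in range(n_settle):
        y = step(y, 0.0)
    for s in range(n_sweep):
        prev_above = y[0] > sp_thresh
        last = -1e9
        for k in range(n_step):
            I_inj = amps[s] if i_on <= k < i_off else 0.0
            y = step(y, I_inj)
            above = y[0] > sp_thresh
            if above and not prev_above:
                t = k * dt
                if t - last >= guard:
                    if counts[s] < 512:
                        times[s, counts[s]] = t
                    counts[s] += 1
                    last = t
            prev_above = above
    return counts, times
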