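"""Compiled integration core.

The model is flattened into plain arrays and each gate's steady state and
per-step exponential-Euler decay factor are tabulated on a fine voltage grid
(0.05 mV over [-150, 100] mV, linear interpolation).  The table values are
exact evaluations of the tanh expressions; interpolation error at this
resolution is far below the integration error.  Voltages advance by forward
Euler, gates by exact exponential relaxation toward the tabulated steady
state — the classic exponential-Euler scheme for stiff HH kinetics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

V_GRID_MIN = -150.0
V_GRID_MAX = 100.0
V_GRID_STEP = 0.05
NV = int(round((V_GRID_MAX - V_GRID_MIN) / V_GRID_STEP)) + 1

SPIKE_THRESHOLD = -10.0  # mV, upward crossing at the soma
SPIKE_GUARD = 2.0  # ms between counted crossings
MAX_SPIKES_PER_SWEEP = 512
DIVERGENCE_LIMIT = 200.0  # mV

KIND_PLAIN = 0
KIND_CA_SOURCE = 1
KIND_CA_GATED = 2


@dataclass
class FlatModel:
    """Array view of a NeuronModel: one row per (current, compartment)."""

    C: np.ndarray
    g_leak: np.ndarray
    E_leak: np.ndarray
    g_sx: float
    g_sd: float
    comp: np.ndarray  # int, compartment of each instance
    g: np.ndarray  # allocated conductance (nS)
    E: np.ndarray
    p: np.ndarray  # activation exponent
    kind: np.ndarray
    gate_a: np.ndarray  # index into gate-spec list, -1 for Ca-gated
    gate_h: np.ndarray  # -1 when no inactivation
    cur_index: np.ndarray  # back-reference into model.currents
    gates: list  # GatingSpec per gate slot
    ca_on: bool
    ca_phi: float
    ca_rest: float
    ca_tau: float
    kca_half: float

    @property
    def n_inst(self) -> int:
        return self.comp.shape[0]


def flatten_model(model) -> FlatModel:
    comp, g, E, p, kind, ga, gh, ci = [], [], [], [], [], [], [], []
    gates = []
    for idx, cur in enumerate(model.currents):
        a_slot = h_slot = -1
        if cur.activation is not None:
            a_slot = len(gates)
            gates.append(cur.activation)
        if cur.inactivation is not None:
            h_slot = len(gates)
            gates.append(cur.inactivation)
        if cur.is_calcium_gated:
            k = KIND_CA_GATED
        elif cur.is_calcium_source:
            k = KIND_CA_SOURCE
        else:
            k = KIND_PLAIN
        for c in range(3):
            gc = cur.g_total * cur.split[c]
            if gc > 0.0:
                comp.append(c)
                g.append(gc)
                E.append(cur.E_rev)
                p.append(cur.activation.p if cur.activation is not None else 1)
                kind.append(k)
                ga.append(a_slot)
                gh.append(h_slot)
                ci.append(idx)
    ca = model.calcium
    return FlatModel(
        C=np.asarray(model.C, dtype=np.float64),
        g_leak=np.asarray(model.g_leak, dtype=np.float64),
        E_leak=np.asarray(model.E_leak, dtype=np.float64),
        g_sx=float(model.g_sx),
        g_sd=float(model.g_sd),
        comp=np.asarray(comp, dtype=np.int64),
        g=np.asarray(g, dtype=np.float64),
        E=np.asarray(E, dtype=np.float64),
        p=np.asarray(p, dtype=np.int64),
        kind=np.asarray(kind, dtype=np.int64),
        gate_a=np.asarray(ga, dtype=np.int64),
        gate_h=np.asarray(gh, dtype=np.int64),
        cur_index=np.asarray(ci, dtype=np.int64),
        gates=gates,
        ca_on=ca is not None,
        ca_phi=ca.influx_gain if ca else 0.0,
        ca_rest=ca.rest if ca else 0.0,
        ca_tau=ca.tau if ca else 1.0,
        kca_half=ca.kca_half if ca else 1.0,
    )


def build_tables(flat: FlatModel, dt: float):
    """Tabulate x_inf and exp(-dt/tau) for every gate on the voltage grid."""
    vgrid = V_GRID_MIN + V_GRID_STEP * np.arange(NV)
    ngate = max(1, len(flat.gates))
    xinf = np.zeros((ngate, NV))
    fdec = np.ones((ngate, NV))
    for i, gs in enumerate(flat.gates):
        xinf[i] = 0.5 + 0.5 * np.tanh((vgrid - gs.V_half) / gs.V_slope)
        t = np.tanh((vgrid - gs.V_tau_half) / gs.V_tau_slope)
        tau = (gs.tau_max - gs.tau_min) * (1.0 - t * t) + gs.tau_min
        fdec[i] = np.exp(-dt / tau)
    return xinf, fdec


@dataclass
class SweepOutput:
    traces: np.ndarray
    spike_times: list
    spike_counts: np.ndarray
    baseline: np.ndarray
    steady: np.ndarray
    v_min: np.ndarray
    state: object
    diverged_sweep: int


def integrate_sweeps(
    flat: FlatModel,
    tables,
    *,
    dt: float,
    amplitudes: np.ndarray,
    i_on: int,
    i_off: int,
    n_step: int,
    state,
    record_stride: int = 0,
    S_exc=None,
    S_inh=None,
    E_exc: float = 0.0,
    E_inh: float = 0.0,
    g_exc=None,
    g_inh=None,
    spike_threshold: float = SPIKE_THRESHOLD,
    spike_guard: float = SPIKE_GUARD,
):
    """Drive the compiled sweep loop; mutates ``state`` in place."""
    xinf, fdec = tables
    n_sweep = amplitudes.shape[0]
    use_syn = S_exc is not None
    if not use_syn:
        S_exc = np.zeros(1)
        S_inh = np.zeros(1)
        g_exc = np.zeros(n_sweep)
        g_inh = np.zeros(n_sweep)
    elif S_inh is None:
        S_inh = np.zeros_like(S_exc)
        g_inh = np.zeros(n_sweep)
    ca = np.array([state.Ca], dtype=np.float64)
    traces, spikes, counts, base, steady, vmin, diverged = _sweep_loop(
        flat.C,
        flat.g_leak,
        flat.E_leak,
        flat.g_sx,
        flat.g_sd,
        flat.comp,
        flat.g,
        flat.E,
        flat.p,
        flat.kind,
        flat.gate_a,
        flat.gate_h,
        xinf,
        fdec,
        flat.ca_on,
        flat.ca_phi,
        flat.ca_rest,
        flat.ca_tau,
        flat.kca_half,
        dt,
        n_sweep,
        n_step,
        np.ascontiguousarray(amplitudes),
        i_on,
        i_off,
        use_syn,
        np.ascontiguousarray(S_exc),
        np.ascontiguousarray(S_inh),
        np.ascontiguousarray(g_exc),
        np.ascontiguousarray(g_inh),
        E_exc,
        E_inh,
        state.V,
        state.m,
        state.h,
        ca,
        record_stride,
        spike_threshold,
        spike_guard,
    )
    state.Ca = float(ca[0])
    spike_times = [
        spikes[s, : counts[s]].copy() if counts[s] <= MAX_SPIKES_PER_SWEEP else spikes[s].copy()
        for s in range(n_sweep)
    ]
    return SweepOutput(
        traces=traces,
        spike_times=spike_times,
        spike_counts=counts,
        baseline=base,
        steady=steady,
        v_min=vmin,
        state=state,
        diverged_sweep=int(diverged),
    )


@njit(cache=True, fastmath=True)
def _sweep_loop(
    C,
    gL,
    EL,
    gsx,
    gsd,
    comp,
    g,
    E,
    p,
    kind,
    gate_a,
    gate_h,
    xinf,
    fdec,
    ca_on,
    ca_phi,
    ca_rest,
    ca_tau,
    kca_half,
    dt,
    n_sweep,
    n_step,
    amps,
    i_on,
    i_off,
    use_syn,
    Se,
    Si,
    gA,
    gG,
    Ee,
    Ei,
    V,
    m,
    h,
    ca,
    rec_stride,
    sp_thresh,
    guard,
):
    ninst = comp.shape[0]
    record = rec_stride > 0
    nrec = n_step // rec_stride if record else 1
    traces = np.empty((n_sweep if record else 1, nrec))
    spikes = np.zeros((n_sweep, MAX_SPIKES_PER_SWEEP))
    counts = np.zeros(n_sweep, np.int64)
    base = np.full(n_sweep, np.nan)
    steady = np.full(n_sweep, np.nan)
    vmin = np.full(n_sweep, np.nan)
    inv_dv = 1.0 / V_GRID_STEP
    nv1 = NV - 1
    n50 = int(50.0 / dt)
    Ca = ca[0]
    diverged = -1
    for s in range(n_sweep):
        amp = amps[s]
        gAs = gA[s]
        gGs = gG[s]
        acc_b = 0.0
        acc_s = 0.0
        vlow = 1e30
        last_spike = -1e9
        prev_above = V[0] > sp_thresh
        n_over = 0
        for k in range(n_step):
            I0 = 0.0
            I1 = 0.0
            I2 = 0.0
            Ica = 0.0
            for i in range(ninst):
                c = comp[i]
                Vc = V[c]
                if kind[i] == 2:
                    mi = Ca / (Ca + kca_half)
                else:
                    u = (Vc - V_GRID_MIN) * inv_dv
                    if u < 0.0:
                        u = 0.0
                    elif u > nv1 - 1e-9:
                        u = nv1 - 1e-9
                    j = int(u)
                    fr = u - j
                    gi = gate_a[i]
                    mss = xinf[gi, j] + fr * (xinf[gi, j + 1] - xinf[gi, j])
                    fd = fdec[gi, j] + fr * (fdec[gi, j + 1] - fdec[gi, j])
                    mi = mss + (m[i] - mss) * fd
                    m[i] = mi
                mp = mi
                for _ in range(p[i] - 1):
                    mp *= mi
                hi = 1.0
                if gate_h[i] >= 0:
                    u = (Vc - V_GRID_MIN) * inv_dv
                    if u < 0.0:
                        u = 0.0
                    elif u > nv1 - 1e-9:
                        u = nv1 - 1e-9
                    j = int(u)
                    fr = u - j
                    gi = gate_h[i]
                    hss = xinf[gi, j] + fr * (xinf[gi, j + 1] - xinf[gi, j])
                    fd = fdec[gi, j] + fr * (fdec[gi, j + 1] - fdec[gi, j])
                    hi = hss + (h[i] - hss) * fd
                    h[i] = hi
                cur = g[i] * mp * hi * (E[i] - Vc)
                if kind[i] == 1:
                    Ica += cur
                if c == 0:
                    I0 += cur
                elif c == 1:
                    I1 += cur
                else:
                    I2 += cur
            if i_on <= k < i_off:
                I0 += amp
            if use_syn and k < i_off:
                I0 += gAs * Se[k] * (Ee - V[0]) + gGs * Si[k] * (Ei - V[0])
            I0 += gL[0] * (EL[0] - V[0]) + gsx * (V[1] - V[0]) + gsd * (V[2] - V[0])
            I1 += gL[1] * (EL[1] - V[1]) + gsx * (V[0] - V[1])
            I2 += gL[2] * (EL[2] - V[2]) + gsd * (V[0] - V[2])
            V[0] += dt * I0 / C[0]
            V[1] += dt * I1 / C[1]
            V[2] += dt * I2 / C[2]
            if ca_on:
                Ca += dt * (ca_phi * Ica - (Ca - ca_rest) / ca_tau)
                if Ca < 0.0:
                    Ca = 0.0
            if record and k % rec_stride == 0 and k // rec_stride < nrec:
                traces[s, k // rec_stride] = V[0]
            above = V[0] > sp_thresh
            if above and not prev_above:
                t = k * dt
                if t - last_spike >= guard:
                    if counts[s] < MAX_SPIKES_PER_SWEEP:
                        spikes[s, counts[s]] = t
                    counts[s] += 1
                    last_spike = t
            prev_above = above
            if i_on - n50 <= k < i_on:
                acc_b += V[0]
            if i_off - n50 <= k < i_off:
                acc_s += V[0]
            if i_on <= k < i_off and V[0] < vlow:
                vlow = V[0]
            if V[0] > DIVERGENCE_LIMIT or V[0] < -DIVERGENCE_LIMIT:
                n_over += 1
                if n_over * dt > 1.0:
                    ca[0] = Ca
                    return traces, spikes, counts, base, steady, vmin, s
            else:
                n_over = 0
        if i_on >= n50:
            base[s] = acc_b / n50
        if i_off - i_on >= n50:
            steady[s] = acc_s / n50
            vmin[s] = vlow
    ca[0] = Ca
    return traces, spikes, counts, base, steady, vmin, diverged


@njit(cache=True)
def synapse_series(sinf, tau_syn, dt, S0):
    """Integrate dS/dt = (S_inf - S)/(tau (1 - S_inf)) along a waveform."""
    n = sinf.shape[0]
    out = np.empty(n)
    S = S0
    for k in range(n):
        si = sinf[k]
        f = np.exp(-dt / (tau_syn * (1.0 - si)))
        S = si + (S - si) * f
        out[k] = S
    return out
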