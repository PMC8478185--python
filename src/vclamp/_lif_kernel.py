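"""Compiled sweep loop for the leaky integrate-and-fire control model."""

from __future__ import annotations

import numpy as np
from numba import njit

MAX_SPIKES = 4096


@njit(cache=True)
def lif_sweeps(
    C,
    gL,
    EL,
    Vth,
    Vreset,
    t_ref,
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
    rec_stride,
):
    nrec = n_step // rec_stride
    traces = np.empty((n_sweep, nrec))
    spikes = np.zeros((n_sweep, MAX_SPIKES))
    counts = np.zeros(n_sweep, np.int64)
    V = EL
    ref_until = -1.0
    for s in range(n_sweep):
        amp = amps[s]
        gAs = gA[s]
        gGs = gG[s]
        for k in range(n_step):
            t = k * dt
            if t < ref_until:
                V = Vreset
            else:
                I = gL * (EL - V)
                if i_on <= k < i_off:
                    I += amp
                if use_syn and k < i_off:
                    I += gAs * Se[k] * (Ee - V) + gGs * Si[k] * (Ei - V)
                V += dt * I / C
                if V >= Vth:
                    if counts[s] < MAX_SPIKES:
                        spikes[s, counts[s]] = t
                    counts[s] += 1
                    V = Vreset
                    ref_until = t + t_ref
            if k % rec_stride == 0 and k // rec_stride < nrec:
                traces[s, k // rec_stride] = V
        ref_until -= n_step * dt
    return traces, spikes, counts
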