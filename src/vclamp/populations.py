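"""Phenotype populations, presynaptic waveforms and the LIF control.

Three canonical cell models — regular firing, delayed firing and stuttering
— capture the phenotypes seen in cultured hippocampal neurons:

* ``regular``: low rheobase, continuous monotone f-I curve, voltage sag
  carried by the h-current.
* ``delayed``: inward rectification and a slow pre-spike voltage ramp from
  an inward-rectifier K-current (Kir) that deactivates with depolarization;
  high input resistance, long first-spike latency, no h-current.
* ``stuttering``: a potent slowly-inactivating D-type K-current (Kv1)
  enforces a single short-latency spike near rheobase and a discontinuous
  jump to repetitive firing at depolarized steps; low input resistance,
  sag (h-current present), strong afterhyperpolarization (KCa).

Biophysically diverse populations are drawn by Gaussian variation of the
maximal conductances, membrane capacitance, leak reversal potential and
compartment coupling conductances around the canonical values; all kinetic
parameters are shared across instances.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Sequence

import numpy as np

from .biophys import (
    CalciumDynamicsSpec,
    GatingSpec,
    IonicCurrentSpec,
    NeuronModel,
    Recording,
    SynapseSpec,
)

__all__ = [
    "PHENOTYPES",
    "PhenotypeDistribution",
    "PresynapticWaveform",
    "LIFModel",
    "canonical_model",
    "default_distribution",
    "sample_population",
    "population_manifest",
    "generate_presynaptic_waveform",
    "read_waveform_ascii",
    "write_waveform_ascii",
    "sample_lif_population",
    "lif_simulate",
    "child_seed",
]

PHENOTYPES = ("regular", "delayed", "stuttering")


def child_seed(master_seed: int, *tags) -> int:
    """Derive a reproducible child seed (< 2**31) from a master seed."""
    import zlib

    ents = [zlib.crc32(str(t).encode()) for t in tags]
    ss = np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, *ents])
    return int(ss.generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# canonical phenotype models
# ---------------------------------------------------------------------------

# Shared spike-generating machinery.  tanh slopes are twice the equivalent
# Boltzmann slope factor.
_NA_ACT = GatingSpec(V_half=-28.0, V_slope=12.0, tau_max=0.30, tau_min=0.05,
                     V_tau_half=-30.0, V_tau_slope=30.0, p=3)
_NA_INACT = GatingSpec(V_half=-50.0, V_slope=-10.0, tau_max=6.0, tau_min=0.25,
                       V_tau_half=-45.0, V_tau_slope=25.0)
_KD_ACT = GatingSpec(V_half=-30.0, V_slope=18.0, tau_max=6.0, tau_min=0.8,
                     V_tau_half=-30.0, V_tau_slope=30.0, p=4)
_H_ACT = GatingSpec(V_half=-82.0, V_slope=-14.0, tau_max=400.0, tau_min=100.0,
                    V_tau_half=-85.0, V_tau_slope=30.0)
# Kir: the kinetic sweep experiments start from these canonical values
# (activation midpoint -91 mV, peak activation time constant 10 ms).
_KIR_ACT = GatingSpec(V_half=-91.0, V_slope=-20.0, tau_max=10.0, tau_min=1.0,
                      V_tau_half=-91.0, V_tau_slope=20.0)
# D-type (Kv1): depolarization-activated, slowly inactivating.  The kinetic
# sweeps rescale tau_max over 2..18 ms around the canonical 14 ms.
_D_ACT = GatingSpec(V_half=-45.0, V_slope=14.0, tau_max=14.0, tau_min=5.0,
                    V_tau_half=-50.0, V_tau_slope=40.0)
_D_INACT = GatingSpec(V_half=-65.0, V_slope=-12.0, tau_max=200.0, tau_min=50.0,
                      V_tau_half=-65.0, V_tau_slope=40.0)
_CAT_ACT = GatingSpec(V_half=-48.0, V_slope=14.0, tau_max=4.0, tau_min=1.0,
                      V_tau_half=-55.0, V_tau_slope=25.0)
_CAT_INACT = GatingSpec(V_half=-75.0, V_slope=-8.0, tau_max=80.0, tau_min=20.0,
                        V_tau_half=-70.0, V_tau_slope=25.0)

E_NA = 50.0
E_K = -90.0
E_H = -30.0
E_CA = 120.0

_CA_DYNAMICS = CalciumDynamicsSpec(influx_gain=0.0005, rest=0.05, tau=60.0, kca_half=2.0)


def _na(g):
    return IonicCurrentSpec("Na", g, E_NA, _NA_ACT, _NA_INACT, split=(0.3, 0.7, 0.0))


def _kd(g):
    return IonicCurrentSpec("Kd", g, E_K, _KD_ACT, split=(0.4, 0.6, 0.0))


def _h(g):
    return IonicCurrentSpec("h", g, E_H, _H_ACT, split=(0.8, 0.0, 0.2))


def _kir(g):
    return IonicCurrentSpec("Kir", g, E_K, _KIR_ACT, split=(0.6, 0.0, 0.4))


def _d(g):
    return IonicCurrentSpec("D", g, E_K, _D_ACT, _D_INACT, split=(0.7, 0.3, 0.0))


def _cat(g):
    return IonicCurrentSpec("CaT", g, E_CA, _CAT_ACT, _CAT_INACT,
                            split=(1.0, 0.0, 0.0), is_calcium_source=True)


def _kca(g):
    return IonicCurrentSpec("KCa", g, E_K, None, split=(1.0, 0.0, 0.0))


def canonical_model(phenotype: str) -> NeuronModel:
    """The mean-parameter model of one phenotype (deterministic)."""
    if phenotype == "regular":
        return NeuronModel(
            C=(26.0, 1.5, 13.0),
            g_leak=(1.2, 0.15, 0.6),
            E_leak=(-66.0, -66.0, -66.0),
            g_sx=20.0,
            g_sd=4.0,
            currents=(_na(600.0), _kd(180.0), _h(1.5), _cat(2.0), _kca(4.0)),
            calcium=_CA_DYNAMICS,
            phenotype="regular",
        )
    if phenotype == "delayed":
        return NeuronModel(
            C=(32.0, 1.5, 16.0),
            g_leak=(2.5, 0.15, 0.5),
            E_leak=(-56.0, -56.0, -56.0),
            g_sx=25.0,
            g_sd=4.0,
            currents=(_na(600.0), _kd(180.0), _kir(24.0), _cat(1.0), _kca(2.0)),
            calcium=_CA_DYNAMICS,
            phenotype="delayed",
        )
    if phenotype == "stuttering":
        return NeuronModel(
            C=(10.0, 1.5, 5.0),
            g_leak=(3.2, 0.2, 1.0),
            E_leak=(-60.0, -60.0, -60.0),
            g_sx=15.0,
            g_sd=4.0,
            currents=(_na(600.0), _kd(300.0), _d(8.5), _h(2.0), _cat(2.0), _kca(6.0)),
            calcium=_CA_DYNAMICS,
            phenotype="stuttering",
        )
    raise ValueError(f"unknown phenotype {phenotype!r}; expected one of {PHENOTYPES}")


# ---------------------------------------------------------------------------
# Gaussian population sampling
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhenotypeDistribution:
    """Gaussian variation around a canonical phenotype.

    ``conductance_sd`` maps current name -> SD in nS of its total maximal
    conductance.  Capacitance varies by a common factor on all compartments;
    the leak reversal shift applies to all compartments.
    """

    phenotype: str
    conductance_sd: Dict[str, float]
    C_rel_sd: float = 0.15
    E_leak_sd: float = 2.0
    coupling_rel_sd: float = 0.25

    def __post_init__(self) -> None:
        if any(sd < 0 for sd in self.conductance_sd.values()):
            raise ValueError("SDs must be >= 0")
        if min(self.C_rel_sd, self.E_leak_sd, self.coupling_rel_sd) < 0:
            raise ValueError("SDs must be >= 0")


#: Relative SD applied to every varied maximal conductance by default.
CONDUCTANCE_REL_SD = 0.25


def default_distribution(phenotype: str) -> PhenotypeDistribution:
    base = canonical_model(phenotype)
    sds = {c.name: CONDUCTANCE_REL_SD * c.g_total for c in base.currents}
    return PhenotypeDistribution(phenotype=phenotype, conductance_sd=sds)


def _truncated_normal(rng, mean, sd, floor=0.0):
    """Gaussian draw truncated below ``floor`` by resampling."""
    if sd == 0:
        return mean
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x >= floor:
            return x
    return max(mean, floor)


def population_manifest(models, seed: Optional[int] = None):
    """One row per instance with every sampled parameter value.

    Returns a pandas DataFrame suitable for writing as delimited text."""
    import pandas as pd

    rows = []
    for i, m in enumerate(models):
        row = {"instance": i, "phenotype": m.phenotype, "seed": seed,
               "C_soma_pF": m.C[0], "C_axon_pF": m.C[1], "C_dend_pF": m.C[2],
               "E_leak_mV": m.E_leak[0], "g_sx_nS": m.g_sx, "g_sd_nS": m.g_sd}
        for cur in m.currents:
            row[f"g_{cur.name}_nS"] = cur.g_total
        rows.append(row)
    return pd.DataFrame(rows)


def sample_population(
    dist: PhenotypeDistribution, n: int, seed: int
) -> list[NeuronModel]:
    """Draw ``n`` independent model instances around the canonical model."""
    if n < 1:
        raise ValueError("n must be >= 1")
    base = canonical_model(dist.phenotype)
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        currents = []
        for cur in base.currents:
            sd = dist.conductance_sd.get(cur.name, 0.0)
            g = _truncated_normal(rng, cur.g_total, sd)
            currents.append(replace(cur, g_total=g))
        cf = _truncated_normal(rng, 1.0, dist.C_rel_sd, floor=0.05)
        dE = rng.normal(0.0, dist.E_leak_sd) if dist.E_leak_sd else 0.0
        gsx = _truncated_normal(rng, base.g_sx, dist.coupling_rel_sd * base.g_sx)
        gsd = _truncated_normal(rng, base.g_sd, dist.coupling_rel_sd * base.g_sd)
        out.append(
            replace(
                base,
                C=tuple(c * cf for c in base.C),
                E_leak=tuple(e + dE for e in base.E_leak),
                g_sx=gsx,
                g_sd=gsd,
                currents=tuple(currents),
            )
        )
    return out


# ---------------------------------------------------------------------------
# presynaptic Poisson waveforms
# ---------------------------------------------------------------------------


@dataclass
class PresynapticWaveform:
    """A presynaptic membrane-potential waveform (mV) sampled at ``dt`` ms."""

    dt: float
    V: np.ndarray
    rate: float
    seed: Optional[int] = None
    baseline: float = -65.0
    peak: float = 20.0
    pulse_width: float = 1.0

    @property
    def duration(self) -> float:
        return self.V.shape[0] * self.dt


def generate_presynaptic_waveform(
    rate: float,
    duration: float,
    dt: float = 0.025,
    seed: int = 0,
    *,
    baseline: float = -65.0,
    peak: float = 20.0,
    pulse_width: float = 1.0,
) -> PresynapticWaveform:
    """Homogeneous-Poisson spike events rendered as rectangular pulses.

    Events at ``rate`` Hz over ``duration`` ms; each event lifts V_pre from
    ``baseline`` to ``peak`` for ``pulse_width`` ms (pulses may overlap).
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if pulse_width < dt:
        raise ValueError("pulse width must be at least one sample")
    rng = np.random.default_rng(seed)
    n = int(round(duration / dt))
    V = np.full(n, baseline)
    n_events = rng.poisson(rate * duration / 1000.0)
    starts = np.sort(rng.uniform(0.0, duration, size=n_events))
    w = int(round(pulse_width / dt))
    for t0 in starts:
        i0 = int(t0 / dt)
        V[i0 : min(i0 + w, n)] = peak
    return PresynapticWaveform(
        dt=dt, V=V, rate=rate, seed=seed, baseline=baseline, peak=peak,
        pulse_width=pulse_width,
    )


def write_waveform_ascii(wf: PresynapticWaveform, path) -> None:
    """One V_pre sample (mV) per line, with generator metadata in headers."""
    with open(path, "w") as f:
        f.write(f"# dt {wf.dt!r}\n# rate {wf.rate!r}\n# seed {wf.seed!r}\n")
        for v in wf.V:
            f.write(f"{v:.6g}\n")


def read_waveform_ascii(path) -> PresynapticWaveform:
    meta = {"dt": 0.025, "rate": float("nan"), "seed": None}
    vals = []
    with open(path) as f:
        for line in f:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split()
                if len(parts) >= 2 and parts[0] in meta:
                    meta[parts[0]] = None if parts[1] == "None" else float(parts[1])
            else:
                vals.append(float(line))
    seed = meta["seed"]
    return PresynapticWaveform(
        dt=float(meta["dt"]),
        V=np.asarray(vals, dtype=np.float64),
        rate=float(meta["rate"]),
        seed=None if seed is None else int(seed),
    )


# ---------------------------------------------------------------------------
# leaky integrate-and-fire control
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LIFModel:
    """Single-compartment leaky integrate-and-fire neuron."""

    C: float = 60.0
    g_leak: float = 3.0
    E_leak: float = -65.0
    V_threshold: float = -45.0
    V_reset: float = -60.0
    t_refractory: float = 3.0

    def __post_init__(self) -> None:
        if self.V_threshold <= self.V_reset:
            raise ValueError("threshold must exceed reset")
        if self.C <= 0 or self.g_leak <= 0:
            raise ValueError("capacitance and conductance must be > 0")

    @property
    def tau_m(self) -> float:
        return self.C / self.g_leak


def sample_lif_population(
    n: int,
    seed: int,
    nominal: LIFModel = LIFModel(),
    C_rel_sd: float = 0.15,
    g_rel_sd: float = CONDUCTANCE_REL_SD,
    E_leak_sd: float = 2.0,
    V_th_sd: float = 2.0,
) -> list[LIFModel]:
    """Vary capacitance, leak conductance, leak reversal and spike threshold.

    The variation mirrors the biophysical population generator: relative
    SDs on capacitance and conductance, 2 mV absolute SDs on the voltages.
    Draws violating positivity or threshold > reset are resampled.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    while len(out) < n:
        C = rng.normal(nominal.C, C_rel_sd * nominal.C)
        g = rng.normal(nominal.g_leak, g_rel_sd * nominal.g_leak)
        E = rng.normal(nominal.E_leak, E_leak_sd)
        Vt = rng.normal(nominal.V_threshold, V_th_sd)
        if C <= 0 or g <= 0 or Vt <= nominal.V_reset:
            continue
        out.append(replace(nominal, C=C, g_leak=g, E_leak=E, V_threshold=Vt))
    return out


def lif_simulate(
    model: LIFModel,
    amplitudes: Sequence[float] | np.ndarray,
    *,
    sweep_duration: float,
    stim_on: float,
    stim_off: float,
    dt: float = 0.025,
    record_interval: float = 0.05,
    syn_exc: Optional[tuple[np.ndarray, SynapseSpec]] = None,
    syn_inh: Optional[tuple[np.ndarray, SynapseSpec]] = None,
    g_exc: Optional[np.ndarray] = None,
    g_inh: Optional[np.ndarray] = None,
) -> Recording:
    """Run the LIF neuron through the same protocol surface as ``simulate``.

    Subthreshold dynamics are a passive RC; a threshold crossing emits a
    spike, resets the voltage and clamps it for the refractory period.
    State carries over between sweeps.
    """
    from ._lif_kernel import lif_sweeps

    amplitudes = np.asarray(amplitudes, dtype=np.float64)
    n_sweep = amplitudes.shape[0]
    n_step = int(round(sweep_duration / dt))
    stride = int(round(record_interval / dt))
    use_syn = syn_exc is not None
    if use_syn:
        Se, espec = syn_exc
        Si, ispec = syn_inh if syn_inh is not None else (np.zeros_like(Se), SynapseSpec(0.0, 0.0))
        Ee, Ei = espec.E_syn, ispec.E_syn
        gA = np.asarray(g_exc, dtype=np.float64)
        gG = np.asarray(g_inh, dtype=np.float64) if g_inh is not None else np.zeros(n_sweep)
    else:
        Se = Si = np.zeros(1)
        Ee = Ei = 0.0
        gA = gG = np.zeros(n_sweep)
    traces, spikes, counts = lif_sweeps(
        model.C, model.g_leak, model.E_leak, model.V_threshold, model.V_reset,
        model.t_refractory, dt, n_sweep, n_step,
        amplitudes, int(round(stim_on / dt)), int(round(stim_off / dt)),
        use_syn, np.ascontiguousarray(Se), np.ascontiguousarray(Si),
        gA, gG, Ee, Ei, stride,
    )
    spike_times = [spikes[s, : counts[s]].copy() for s in range(n_sweep)]
    # paint a stereotyped spike peak into the subthreshold trace so that
    # threshold-crossing spike detection treats LIF and HH recordings alike
    nrec = traces.shape[1]
    for s in range(n_sweep):
        idx = np.minimum((spike_times[s] / record_interval).astype(int), nrec - 1)
        traces[s, idx] = 30.0
    stim = (
        np.column_stack([gA, gG]) if use_syn else amplitudes.copy()
    )
    return Recording(
        dt=record_interval,
        sweeps=traces,
        window=(stim_on, stim_off),
        stimulus=stim,
        stimulus_kind="synaptic" if use_syn else "current_step",
        meta={"spike_times": spike_times, "spike_counts": counts, "model": "lif"},
    )
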