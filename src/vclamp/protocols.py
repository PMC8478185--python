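"""Stimulation protocols, virtual pharmacology and kinetic manipulations.

Two protocols drive every cell:

* a static current-step protocol (-160 to +200 pA in 5 pA steps, 400 ms
  steps on a 1.25 s cycle), and
* simulated synaptic bombardment: mixed AMPA/GABA conductances driven by
  replayed Poissonian presynaptic waveforms, with the AMPA peak conductance
  ramped 0 to 25 nS in 0.5 nS increments (GABA 1 nS increments), 2.5 s of
  drive plus 2.5 s rest per 5 s cycle.

Virtual pharmacology removes a named current (conductance to zero); the
kinetic manipulations shift activation midpoints or rescale time constants,
optionally co-moving the inactivation gate so the activation/inactivation
overlap (or time-constant ratio) is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .biophys import (
    NeuronModel,
    Recording,
    SimulationError,
    SynapseSpec,
    simulate,
    synaptic_activation_series,
)
from .features import FeatureRecord, extract_features, io_curve
from .populations import (
    PresynapticWaveform,
    generate_presynaptic_waveform,
    child_seed,
)

__all__ = [
    "CurrentStepProtocol",
    "SynapticBombardmentProtocol",
    "KineticSweepSchedule",
    "run_static_protocol",
    "run_dynamic_protocol",
    "make_bombardment_drive",
    "block_current",
    "shift_activation_midpoint",
    "scale_time_constants",
    "repetitive_firing_transition",
    "run_population_experiment",
    "KIR_VHALF_GRID",
    "KIR_TAU_GRID",
    "D_VHALF_GRID",
    "D_TAU_GRID",
]


@dataclass(frozen=True)
class CurrentStepProtocol:
    """Step-current stimulation schedule."""

    start: float = -160.0
    increment: float = 5.0
    stop: float = 200.0
    duration: float = 400.0
    cycle: float = 1250.0
    onset: float = 100.0

    def __post_init__(self) -> None:
        if self.increment <= 0:
            raise ValueError("increment must be > 0")
        if self.duration >= self.cycle:
            raise ValueError("step duration must be shorter than the cycle")

    @property
    def amplitudes(self) -> np.ndarray:
        n = int(round((self.stop - self.start) / self.increment)) + 1
        return self.start + self.increment * np.arange(n)

    @property
    def window(self) -> tuple[float, float]:
        return (self.onset, self.onset + self.duration)


@dataclass(frozen=True)
class SynapticBombardmentProtocol:
    """Conductance-ramp schedule for the simulated synaptic bombardment."""

    g_exc_max: float = 25.0
    g_exc_step: float = 0.5
    g_inh_step: float = 1.0
    tau_syn: float = 10.0
    E_exc: float = 0.0
    E_inh: float = -72.0
    on_duration: float = 2500.0
    rest_duration: float = 2500.0
    exc_rate: float = 40.0
    inh_rate: float = 60.0
    V_th: float = -20.0
    V_slope: float = 35.0

    def __post_init__(self) -> None:
        if self.g_exc_max < 0 or self.g_exc_step <= 0 or self.g_inh_step < 0:
            raise ValueError("conductance schedule must be nonnegative")

    @property
    def n_sweeps(self) -> int:
        return int(round(self.g_exc_max / self.g_exc_step)) + 1

    @property
    def g_exc_schedule(self) -> np.ndarray:
        return self.g_exc_step * np.arange(self.n_sweeps)

    @property
    def g_inh_schedule(self) -> np.ndarray:
        return self.g_inh_step * np.arange(self.n_sweeps)

    @property
    def cycle(self) -> float:
        return self.on_duration + self.rest_duration

    def synapse_spec(self, which: str) -> SynapseSpec:
        E = self.E_exc if which == "exc" else self.E_inh
        return SynapseSpec(g_syn=1.0, E_syn=E, tau_syn=self.tau_syn,
                           V_th=self.V_th, V_slope=self.V_slope)


@dataclass(frozen=True)
class KineticSweepSchedule:
    """A grid of settings for one kinetic-manipulation experiment."""

    current: str
    kind: str  # 'vhalf' | 'tau' with optional coupled inactivation
    grid: tuple[float, ...]
    couple_inactivation: bool = False

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=float)
        if g.size < 2 or np.any(np.diff(g) <= 0):
            raise ValueError("grid needs >= 2 strictly increasing points")
        if self.kind not in ("vhalf", "tau"):
            raise ValueError("kind must be 'vhalf' or 'tau'")


# Sweep grids.  Kir activation midpoint -91..-75 mV (+2 mV) and peak
# activation time constant 10..130 ms (+15 ms) start from the canonical
# delayed-model values; the D-current tau grid 2..18 ms (+2 ms) brackets the
# canonical 14 ms, and the coupled D midpoint grid spans the same 16 mV
# depolarizing excursion from its canonical -45 mV.
KIR_VHALF_GRID = KineticSweepSchedule("Kir", "vhalf", tuple(np.arange(-91.0, -74.0, 2.0)))
KIR_TAU_GRID = KineticSweepSchedule("Kir", "tau", tuple(np.arange(10.0, 131.0, 15.0)))
D_VHALF_GRID = KineticSweepSchedule(
    "D", "vhalf", tuple(np.arange(-45.0, -28.0, 2.0)), couple_inactivation=True
)
D_TAU_GRID = KineticSweepSchedule(
    "D", "tau", tuple(np.arange(2.0, 19.0, 2.0)), couple_inactivation=True
)


# ---------------------------------------------------------------------------
# protocol execution
# ---------------------------------------------------------------------------


def run_static_protocol(
    model: NeuronModel,
    protocol: CurrentStepProtocol = CurrentStepProtocol(),
    dt: float = 0.025,
    record: bool = True,
) -> Recording:
    """One sweep per current level, state carried across the cycling sweeps."""
    return simulate(
        model,
        protocol.amplitudes,
        sweep_duration=protocol.cycle,
        stim_on=protocol.onset,
        stim_off=protocol.onset + protocol.duration,
        dt=dt,
        record=record,
    )


@dataclass
class BombardmentDrive:
    """Precomputed synaptic activation series shared by all instances."""

    protocol: SynapticBombardmentProtocol
    S_exc: np.ndarray
    S_inh: np.ndarray
    dt: float
    waveforms: tuple[PresynapticWaveform, PresynapticWaveform]


def make_bombardment_drive(
    protocol: SynapticBombardmentProtocol,
    seed: int,
    dt: float = 0.025,
    waveforms: Optional[tuple[PresynapticWaveform, PresynapticWaveform]] = None,
) -> BombardmentDrive:
    """Generate (or adopt) the two presynaptic waveforms and integrate their
    release rate law over one full stimulation cycle.

    The waveforms cover the on-phase; the rest phase continues at baseline so
    the synaptic activation decays to zero before the next sweep.
    """
    if waveforms is None:
        we = generate_presynaptic_waveform(
            protocol.exc_rate, protocol.on_duration, dt, child_seed(seed, "exc")
        )
        wi = generate_presynaptic_waveform(
            protocol.inh_rate, protocol.on_duration, dt, child_seed(seed, "inh")
        )
    else:
        we, wi = waveforms
        need = int(round(protocol.on_duration / dt))
        if we.V.size < need or wi.V.size < need:
            raise ValueError("waveform shorter than the bombardment on-phase")
    n_cycle = int(round(protocol.cycle / dt))
    s_tr = []
    for wf in (we, wi):
        vpre = np.full(n_cycle, wf.baseline)
        vpre[: wf.V.size] = wf.V[:n_cycle]
        spec = protocol.synapse_spec("exc")  # S dynamics independent of E
        s_tr.append(synaptic_activation_series(vpre, spec, dt))
    return BombardmentDrive(protocol=protocol, S_exc=s_tr[0], S_inh=s_tr[1],
                            dt=dt, waveforms=(we, wi))


def run_dynamic_protocol(
    model: NeuronModel,
    drive: BombardmentDrive,
    record: bool = True,
) -> Recording:
    """Ramped mixed bombardment; spike counting window is the on-phase."""
    p = drive.protocol
    n = p.n_sweeps
    return simulate(
        model,
        np.zeros(n),
        sweep_duration=p.cycle,
        stim_on=0.0,
        stim_off=p.on_duration,
        dt=drive.dt,
        syn_exc=(drive.S_exc, p.synapse_spec("exc")),
        syn_inh=(drive.S_inh, p.synapse_spec("inh")),
        g_exc=p.g_exc_schedule,
        g_inh=p.g_inh_schedule,
        record=record,
    )


# ---------------------------------------------------------------------------
# virtual pharmacology and kinetic manipulation
# ---------------------------------------------------------------------------


def block_current(model: NeuronModel, name: str) -> NeuronModel:
    """Copy of ``model`` with the named current's conductance set to zero."""
    cur = model.current(name)
    return model.with_current(replace(cur, g_total=0.0))


def shift_activation_midpoint(
    model: NeuronModel,
    name: str,
    new_V_half: float,
    couple_inactivation: bool = False,
) -> NeuronModel:
    """Set the activation V_half; optionally co-shift inactivation by the
    same amount so the window overlap is preserved."""
    cur = model.current(name)
    if cur.activation is None:
        raise ValueError(f"current {name!r} has no voltage-gated activation")
    dV = new_V_half - cur.activation.V_half
    act = replace(cur.activation, V_half=new_V_half,
                  V_tau_half=cur.activation.V_tau_half + dV)
    inact = cur.inactivation
    if couple_inactivation:
        if inact is None:
            raise ValueError(f"current {name!r} has no inactivation to couple")
        inact = replace(inact, V_half=inact.V_half + dV,
                        V_tau_half=inact.V_tau_half + dV)
    return model.with_current(replace(cur, activation=act, inactivation=inact))


def scale_time_constants(
    model: NeuronModel,
    name: str,
    new_tau_max: float,
    couple_inactivation: bool = False,
) -> NeuronModel:
    """Rescale the activation tau_max (tau_min co-scales proportionally);
    with coupling, the inactivation time constants scale by the same factor
    so the activation/inactivation speed ratio is fixed."""
    if new_tau_max <= 0:
        raise ValueError("new tau_max must be > 0")
    cur = model.current(name)
    if cur.activation is None:
        raise ValueError(f"current {name!r} has no voltage-gated activation")
    f = new_tau_max / cur.activation.tau_max
    act = replace(cur.activation, tau_max=cur.activation.tau_max * f,
                  tau_min=cur.activation.tau_min * f)
    inact = cur.inactivation
    if couple_inactivation:
        if inact is None:
            raise ValueError(f"current {name!r} has no inactivation to couple")
        inact = replace(inact, tau_max=inact.tau_max * f, tau_min=inact.tau_min * f)
    return model.with_current(replace(cur, activation=act, inactivation=inact))


def apply_sweep_setting(
    model: NeuronModel, schedule: KineticSweepSchedule, value: float
) -> NeuronModel:
    if schedule.kind == "vhalf":
        return shift_activation_midpoint(
            model, schedule.current, value, schedule.couple_inactivation
        )
    return scale_time_constants(
        model, schedule.current, value, schedule.couple_inactivation
    )


def repetitive_firing_transition(
    curve, max_isi: float = 200.0, min_spikes: int = 3, spike_times=None
) -> float:
    """Lowest step current whose window holds >= ``min_spikes`` spikes with
    all inter-spike intervals below ``max_isi`` — the jump from single-spike
    or stuttering responses to sustained repetitive firing."""
    if spike_times is None:
        raise ValueError("per-sweep spike times are required")
    for s, times in enumerate(spike_times):
        if len(times) >= min_spikes and np.all(np.diff(times) < max_isi):
            return float(curve.stimulus[s])
    return float("nan")


# ---------------------------------------------------------------------------
# population runs
# ---------------------------------------------------------------------------


def _instance_row(model, static_proto, drive, dt, record=False):
    srec = run_static_protocol(model, static_proto, dt=dt, record=True)
    drec = run_dynamic_protocol(model, drive, record=True) if drive else None
    feats = extract_features(srec, drec)
    return feats


def run_population_experiment(
    models: Sequence[NeuronModel],
    static_protocol: CurrentStepProtocol,
    drive: Optional[BombardmentDrive],
    manipulation=None,
    dt: float = 0.025,
    labels: Optional[Sequence] = None,
    progress: bool = False,
) -> pd.DataFrame:
    """Run every instance through both protocols and extract features.

    ``manipulation`` is an optional callable NeuronModel -> NeuronModel; when
    given, each instance is run before and after it and both rows appear in
    the output (column ``condition``).  Per-instance simulation failures are
    recorded as flagged rows; the population run never aborts.
    """
    if len(models) < 1:
        raise ValueError("need at least one model")
    rows = []
    conditions = [("baseline", None)] if manipulation is None else [
        ("baseline", None), ("manipulated", manipulation)
    ]
    for i, model in enumerate(models):
        label = labels[i] if labels is not None else i
        for cond, manip in conditions:
            m = manip(model) if manip else model
            row = {"instance": label, "phenotype": model.phenotype, "condition": cond}
            try:
                feats = _instance_row(m, static_protocol, drive, dt)
                row.update(feats.as_dict())
                row["failed"] = False
            except SimulationError as e:
                row.update({k: np.nan for k in FeatureRecord(
                    np.nan, np.nan, 0, 0, np.nan, np.nan, np.nan, np.nan
                ).as_dict()})
                row["failed"] = True
                row["error"] = str(e)
            rows.append(row)
        if progress and (i + 1) % 10 == 0:
            print(f"  {i + 1}/{len(models)} instances done", flush=True)
    return pd.DataFrame(rows)
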