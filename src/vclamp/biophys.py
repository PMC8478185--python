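"""Conductance-based model neurons and their numerical integration.

The cell model is a three-compartment (soma, axon, dendrite) Hodgkin-Huxley
type neuron.  Every voltage-gated current follows the template

    I_i = g_i * m^p * h * (E_i - V)

with first-order gating kinetics ``dx/dt = (x_inf(V) - x) / tau_x(V)``,
sigmoidal steady states and bell-shaped voltage-dependent time constants.
Synaptic conductances follow a first-order transmitter-release rate law
driven by a presynaptic voltage waveform.

Unit system (self-consistent): mV, ms, nS, pA, pF.  nS*mV = pA and
pF*mV/ms = pA, so no conversion factors appear in the equations.

Sign convention: currents are written as g*(E - V), i.e. positive values
depolarize the compartment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "GatingSpec",
    "IonicCurrentSpec",
    "CalciumDynamicsSpec",
    "SynapseSpec",
    "NeuronModel",
    "Recording",
    "SimulationError",
    "COMPARTMENTS",
    "steady_state",
    "time_constant",
    "ionic_current",
    "gating_step",
    "synaptic_state_step",
    "synaptic_current",
    "simulate",
    "settle_to_rest",
]

#: Compartment order used throughout: index 0 = soma, 1 = axon, 2 = dendrite.
COMPARTMENTS = ("soma", "axon", "dendrite")

#: Clamp on the synaptic steady state: the rate law divides by (1 - S_inf).
S_INF_MAX = 1.0 - 1e-6

#: Sustained excursions beyond this voltage abort a simulation.
DIVERGENCE_LIMIT_MV = 200.0


class SimulationError(RuntimeError):
    """Raised when an integration diverges or cannot be performed."""


# ---------------------------------------------------------------------------
# specifications
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GatingSpec:
    """Voltage dependence and kinetics of one activation/inactivation gate.

    ``x_inf(V) = 1/2 + 1/2 tanh((V - V_half)/V_slope)`` and
    ``tau(V) = (tau_max - tau_min)(1 - tanh((V - V_tau_half)/V_tau_slope)^2)
    + tau_min``.  A negative ``V_slope`` yields a gate that opens with
    hyperpolarization (inactivation gates, Kir and h activation).

    Parameters are in mV and ms.  ``p`` is the activation exponent and is
    ignored on inactivation gates.
    """

    V_half: float
    V_slope: float
    tau_max: float
    tau_min: float
    V_tau_half: float
    V_tau_slope: float
    p: int = 1

    def __post_init__(self) -> None:
        if self.V_slope == 0 or self.V_tau_slope == 0:
            raise ValueError("V_slope and V_tau_slope must be nonzero")
        if not (self.tau_max >= self.tau_min > 0):
            raise ValueError("require tau_max >= tau_min > 0")
        if self.p < 1:
            raise ValueError("activation exponent p must be >= 1")


@dataclass(frozen=True)
class IonicCurrentSpec:
    """One membrane current of the Hodgkin-Huxley template.

    ``split`` allocates the total conductance across (soma, axon, dendrite)
    and must sum to 1.  ``activation is None`` marks a purely
    calcium-gated current (KCa); ``is_calcium_source`` marks currents whose
    flux feeds the intracellular Ca pool (CaT).
    """

    name: str
    g_total: float
    E_rev: float
    activation: Optional[GatingSpec]
    inactivation: Optional[GatingSpec] = None
    split: tuple[float, float, float] = (1.0, 0.0, 0.0)
    is_calcium_source: bool = False

    def __post_init__(self) -> None:
        if self.g_total < 0:
            raise ValueError("g_total must be >= 0")
        s = float(sum(self.split))
        if any(f < 0 or f > 1 for f in self.split) or abs(s - 1.0) > 1e-9:
            raise ValueError("compartment split must lie in [0,1] and sum to 1")

    @property
    def is_calcium_gated(self) -> bool:
        return self.activation is None


@dataclass(frozen=True)
class CalciumDynamicsSpec:
    """Minimal first-order intracellular Ca pool gating the KCa current.

    ``d[Ca]/dt = influx_gain * I_Ca - ([Ca] - rest)/tau`` with the KCa
    activation saturating as ``[Ca]/([Ca] + kca_half)``.  Concentration is
    in arbitrary micromolar-like units; only ratios against ``kca_half``
    matter for the dynamics.
    """

    influx_gain: float = 0.002
    rest: float = 0.05
    tau: float = 80.0
    kca_half: float = 1.0

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("Ca removal time constant must be > 0")
        if self.rest < 0:
            raise ValueError("resting Ca level must be >= 0")


@dataclass(frozen=True)
class SynapseSpec:
    """First-order transmitter-release synapse.

    ``I_syn = g_syn * S * (E_syn - V)`` with
    ``dS/dt = (S_inf(V_pre) - S) / (tau_syn (1 - S_inf(V_pre)))`` and
    ``S_inf = tanh((V_pre - V_th)/V_slope)`` for ``V_pre > V_th`` else 0.
    """

    g_syn: float
    E_syn: float
    tau_syn: float = 10.0
    V_th: float = -20.0
    V_slope: float = 20.0

    def __post_init__(self) -> None:
        if self.tau_syn <= 0:
            raise ValueError("tau_syn must be > 0")
        if self.V_slope <= 0:
            raise ValueError("V_slope must be > 0")


@dataclass(frozen=True)
class NeuronModel:
    """A three-compartment conductance-based neuron.

    Arrays are ordered (soma, axon, dendrite).  ``g_sx`` couples soma and
    axon, ``g_sd`` couples soma and dendrite.
    """

    C: tuple[float, float, float]
    g_leak: tuple[float, float, float]
    E_leak: tuple[float, float, float]
    g_sx: float
    g_sd: float
    currents: tuple[IonicCurrentSpec, ...] = ()
    calcium: Optional[CalciumDynamicsSpec] = None
    phenotype: str = "unspecified"

    def __post_init__(self) -> None:
        for name in ("C", "g_leak", "E_leak"):
            if len(getattr(self, name)) != 3:
                raise ValueError("exactly 3 compartments required")
        if any(c < 0 for c in self.C) or any(g < 0 for g in self.g_leak):
            raise ValueError("capacitances and conductances must be >= 0")
        if self.g_sx < 0 or self.g_sd < 0:
            raise ValueError("coupling conductances must be >= 0")

    def current(self, name: str) -> IonicCurrentSpec:
        for cur in self.currents:
            if cur.name == name:
                return cur
        raise KeyError(f"model has no current named {name!r}")

    def current_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.currents)

    def with_current(self, new: IonicCurrentSpec) -> "NeuronModel":
        """Return a copy with the same-named current replaced."""
        if new.name not in self.current_names():
            raise KeyError(f"model has no current named {new.name!r}")
        cur = tuple(new if c.name == new.name else c for c in self.currents)
        return replace(self, currents=cur)


@dataclass
class Recording:
    """Per-sweep somatic voltage traces plus stimulus metadata.

    ``sweeps`` is an (n_sweep, n_sample) array of soma membrane potential in
    mV sampled every ``dt`` ms.  ``window`` bounds (ms from sweep start) mark
    the stimulation epoch used for spike counting.  ``stimulus`` holds one
    descriptor per sweep: step amplitude in pA for the static protocol, or
    (g_AMPA, g_GABA) in nS for the synaptic protocol.
    """

    dt: float
    sweeps: np.ndarray
    window: tuple[float, float]
    stimulus: np.ndarray
    stimulus_kind: str = "current_step"
    baseline: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    @property
    def n_sweeps(self) -> int:
        return self.sweeps.shape[0]

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.sweeps.shape[1]) * self.dt


# ---------------------------------------------------------------------------
# elementary operations (reference forms; the compiled kernel mirrors these)
# ---------------------------------------------------------------------------


def steady_state(V, spec: GatingSpec):
    """Sigmoidal steady-state activation x_inf(V)."""
    return 0.5 + 0.5 * np.tanh((V - spec.V_half) / spec.V_slope)


def time_constant(V, spec: GatingSpec):
    """Bell-shaped voltage-dependent time constant tau_x(V) in ms."""
    t = np.tanh((V - spec.V_tau_half) / spec.V_tau_slope)
    return (spec.tau_max - spec.tau_min) * (1.0 - t * t) + spec.tau_min


def ionic_current(V, m, h, spec: IonicCurrentSpec, compartment: int):
    """Current (pA) of the compartment's share of ``spec``.

    ``h`` should be 1 for currents without inactivation.
    """
    p = spec.activation.p if spec.activation is not None else 1
    g = spec.g_total * spec.split[compartment]
    return g * m**p * h * (spec.E_rev - V)


def gating_step(x, V, spec: GatingSpec, dt: float):
    """Exact exponential-Euler update of a gate over one time step."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    xinf = steady_state(V, spec)
    tau = time_constant(V, spec)
    return xinf + (x - xinf) * np.exp(-dt / tau)


def synaptic_steady_state(V_pre, spec: SynapseSpec):
    """S_inf(V_pre): zero at/below threshold, tanh-saturating above."""
    s = np.where(
        V_pre > spec.V_th, np.tanh((np.asarray(V_pre) - spec.V_th) / spec.V_slope), 0.0
    )
    return np.minimum(s, S_INF_MAX)


def synaptic_state_step(S, V_pre, spec: SynapseSpec, dt: float):
    """Exponential-Euler update of the synaptic activation S.

    The effective relaxation time constant is ``tau_syn (1 - S_inf)``;
    S_inf is clamped below 1 to keep it positive.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    sinf = synaptic_steady_state(V_pre, spec)
    tau_eff = spec.tau_syn * (1.0 - sinf)
    return sinf + (S - sinf) * np.exp(-dt / tau_eff)


def synaptic_current(V_post, S, spec: SynapseSpec):
    """I_syn = g_syn * S * (E_syn - V) in pA."""
    return spec.g_syn * S * (spec.E_syn - V_post)


def synaptic_activation_series(
    V_pre: np.ndarray, spec: SynapseSpec, dt: float, S0: float = 0.0
) -> np.ndarray:
    """Integrate the release rate law along a presynaptic waveform.

    Because S depends only on V_pre, the series can be computed once per
    waveform and replayed for every postsynaptic sweep and instance.
    """
    from ._kernel import synapse_series

    sinf = np.asarray(synaptic_steady_state(V_pre, spec), dtype=np.float64)
    return synapse_series(sinf, spec.tau_syn, dt, S0)


# ---------------------------------------------------------------------------
# simulation driver
# ---------------------------------------------------------------------------


@dataclass
class ModelState:
    """Snapshot of all dynamical variables of a model instance."""

    V: np.ndarray
    m: np.ndarray
    h: np.ndarray
    Ca: float
    converged: bool = True


def _resting_state_guess(model: NeuronModel) -> ModelState:
    from ._kernel import flatten_model

    flat = flatten_model(model)
    V = np.array(model.E_leak, dtype=np.float64)
    m = np.zeros(flat.n_inst)
    h = np.ones(flat.n_inst)
    ca0 = model.calcium.rest if model.calcium is not None else 0.0
    for i in range(flat.n_inst):
        cur = model.currents[flat.cur_index[i]]
        v = V[flat.comp[i]]
        if cur.activation is not None:
            m[i] = float(steady_state(v, cur.activation))
        else:
            kh = model.calcium.kca_half if model.calcium else 1.0
            m[i] = ca0 / (ca0 + kh)
        if cur.inactivation is not None:
            h[i] = float(steady_state(v, cur.inactivation))
    return ModelState(V=V, m=m, h=h, Ca=ca0)


def settle_to_rest(
    model: NeuronModel,
    max_time: float = 10_000.0,
    dt: float = 0.025,
    tol: float = 1e-4,
) -> ModelState:
    """Integrate with zero input until the soma drift falls below ``tol``
    mV/ms (checked over 200 ms blocks).

    Returns a flagged (``converged=False``) state when the instance does not
    settle within ``max_time`` — e.g. a spontaneously active instance.
    """
    if max_time <= 0:
        raise ValueError("max_time must be > 0")
    from ._kernel import integrate_sweeps, flatten_model, build_tables

    flat = flatten_model(model)
    tabs = build_tables(flat, dt)
    state = _resting_state_guess(model)
    block = 200.0
    n_blocks = max(1, int(math.ceil(max_time / block)))
    for _ in range(n_blocks):
        v_before = state.V[0]
        _run_block(flat, tabs, state, dt, block)
        drift = abs(state.V[0] - v_before) / block
        if drift < tol:
            state.converged = True
            return state
    state.converged = False
    return state


def _run_block(flat, tabs, state: ModelState, dt: float, duration: float) -> None:
    from ._kernel import integrate_sweeps

    nstep = int(round(duration / dt))
    out = integrate_sweeps(
        flat,
        tabs,
        dt=dt,
        amplitudes=np.zeros(1),
        i_on=0,
        i_off=0,
        n_step=nstep,
        state=state,
        record_stride=0,
    )
    if out.diverged_sweep >= 0:
        raise SimulationError("divergence during settling")


def simulate(
    model: NeuronModel,
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
    initial_state: Optional[ModelState] = None,
    settle: bool = True,
    record: bool = True,
) -> Recording:
    """Run a multi-sweep stimulation and return a :class:`Recording`.

    ``amplitudes`` gives the injected-current step (pA) per sweep, applied to
    the soma between ``stim_on`` and ``stim_off`` (ms from sweep start).
    Synaptic drive, when given, supplies per-sweep peak conductances
    ``g_exc``/``g_inh`` (nS) scaling precomputed activation series that must
    cover the full sweep at resolution ``dt``.  State carries over between
    sweeps, mirroring a continuously cycling protocol; the first sweep starts
    from the settled resting state unless ``initial_state`` is given.
    """
    from ._kernel import integrate_sweeps, flatten_model, build_tables

    amplitudes = np.asarray(amplitudes, dtype=np.float64)
    stride = int(round(record_interval / dt))
    if abs(stride * dt - record_interval) > 1e-9:
        raise ValueError("dt must divide record_interval")
    n_step = int(round(sweep_duration / dt))
    i_on = int(round(stim_on / dt))
    i_off = int(round(stim_off / dt))

    flat = flatten_model(model)
    tabs = build_tables(flat, dt)
    if initial_state is not None:
        state = ModelState(
            V=initial_state.V.copy(),
            m=initial_state.m.copy(),
            h=initial_state.h.copy(),
            Ca=initial_state.Ca,
        )
    elif settle:
        state = settle_to_rest(model, dt=dt)
    else:
        state = _resting_state_guess(model)

    se = si = None
    espec = ispec = None
    if syn_exc is not None:
        se, espec = syn_exc
        if se.shape[0] < n_step:
            raise ValueError("excitatory activation series shorter than the sweep")
    if syn_inh is not None:
        si, ispec = syn_inh
        if si.shape[0] < n_step:
            raise ValueError("inhibitory activation series shorter than the sweep")

    out = integrate_sweeps(
        flat,
        tabs,
        dt=dt,
        amplitudes=amplitudes,
        i_on=i_on,
        i_off=i_off,
        n_step=n_step,
        state=state,
        record_stride=stride if record else 0,
        S_exc=se,
        S_inh=si,
        E_exc=espec.E_syn if espec else 0.0,
        E_inh=ispec.E_syn if ispec else 0.0,
        g_exc=np.asarray(g_exc, dtype=np.float64) if g_exc is not None else None,
        g_inh=np.asarray(g_inh, dtype=np.float64) if g_inh is not None else None,
    )
    if out.diverged_sweep >= 0:
        raise SimulationError(
            f"simulation diverged (|V| > {DIVERGENCE_LIMIT_MV:.0f} mV) for "
            f"{model.phenotype!r} model at sweep {out.diverged_sweep}"
        )

    if g_exc is not None:
        stim = np.column_stack([np.asarray(g_exc), np.asarray(g_inh)])
        kind = "synaptic"
    else:
        stim = amplitudes.copy()
        kind = "current_step"
    rec = Recording(
        dt=record_interval,
        sweeps=out.traces if record else np.empty((0, 0)),
        window=(stim_on, stim_off),
        stimulus=stim,
        stimulus_kind=kind,
        baseline=out.baseline,
        meta={
            "phenotype": model.phenotype,
            "dt_integration": dt,
            "spike_times": out.spike_times,
            "spike_counts": out.spike_counts,
            "steady": out.steady,
            "v_min": out.v_min,
            "final_state": out.state,
        },
    )
    return rec
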