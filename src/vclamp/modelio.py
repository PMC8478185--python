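"""Reading and writing model definitions and recordings.

Model configurations are YAML documents mirroring the parameter tables
field-for-field (passive properties, per-current gating constants,
compartment splits, Ca dynamics).  Floats are serialized with ``repr`` so a
write/read round-trip reproduces the model bit-exactly.

Recordings export to multi-column delimited text (time + one column per
sweep) with sweep metadata in comment headers, and to a compact NumPy
``.npz`` container.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import yaml

from .biophys import (
    CalciumDynamicsSpec,
    GatingSpec,
    IonicCurrentSpec,
    NeuronModel,
    Recording,
)

__all__ = [
    "model_to_dict",
    "model_from_dict",
    "save_model",
    "load_model",
    "write_recording_text",
    "read_recording_text",
    "write_recording_npz",
    "read_recording_npz",
]


def _gating_to_dict(g: Optional[GatingSpec]):
    if g is None:
        return None
    return {
        "V_half": float(g.V_half),
        "V_slope": float(g.V_slope),
        "tau_max": float(g.tau_max),
        "tau_min": float(g.tau_min),
        "V_tau_half": float(g.V_tau_half),
        "V_tau_slope": float(g.V_tau_slope),
        "p": int(g.p),
    }


def _gating_from_dict(d) -> Optional[GatingSpec]:
    return None if d is None else GatingSpec(**d)


def model_to_dict(model: NeuronModel) -> dict:
    return {
        "phenotype": model.phenotype,
        "C_pF": [float(c) for c in model.C],
        "g_leak_nS": [float(g) for g in model.g_leak],
        "E_leak_mV": [float(e) for e in model.E_leak],
        "g_sx_nS": float(model.g_sx),
        "g_sd_nS": float(model.g_sd),
        "currents": [
            {
                "name": c.name,
                "g_total_nS": float(c.g_total),
                "E_rev_mV": float(c.E_rev),
                "split": [float(f) for f in c.split],
                "is_calcium_source": bool(c.is_calcium_source),
                "activation": _gating_to_dict(c.activation),
                "inactivation": _gating_to_dict(c.inactivation),
            }
            for c in model.currents
        ],
        "calcium": None
        if model.calcium is None
        else {
            "influx_gain": float(model.calcium.influx_gain),
            "rest": float(model.calcium.rest),
            "tau_ms": float(model.calcium.tau),
            "kca_half": float(model.calcium.kca_half),
        },
    }


def model_from_dict(d: dict) -> NeuronModel:
    currents = tuple(
        IonicCurrentSpec(
            name=c["name"],
            g_total=c["g_total_nS"],
            E_rev=c["E_rev_mV"],
            activation=_gating_from_dict(c["activation"]),
            inactivation=_gating_from_dict(c.get("inactivation")),
            split=tuple(c["split"]),
            is_calcium_source=c.get("is_calcium_source", False),
        )
        for c in d["currents"]
    )
    ca = d.get("calcium")
    calcium = (
        None
        if ca is None
        else CalciumDynamicsSpec(
            influx_gain=ca["influx_gain"],
            rest=ca["rest"],
            tau=ca["tau_ms"],
            kca_half=ca["kca_half"],
        )
    )
    return NeuronModel(
        C=tuple(d["C_pF"]),
        g_leak=tuple(d["g_leak_nS"]),
        E_leak=tuple(d["E_leak_mV"]),
        g_sx=d["g_sx_nS"],
        g_sd=d["g_sd_nS"],
        currents=currents,
        calcium=calcium,
        phenotype=d.get("phenotype", "unspecified"),
    )


class _ReprFloatDumper(yaml.SafeDumper):
    pass


_ReprFloatDumper.add_representer(
    float, lambda du, v: du.represent_scalar("tag:yaml.org,2002:float", repr(v))
)


def save_model(model: NeuronModel, path) -> None:
    with open(path, "w") as f:
        yaml.dump(model_to_dict(model), f, Dumper=_ReprFloatDumper, sort_keys=False)


def load_model(path) -> NeuronModel:
    with open(path) as f:
        return model_from_dict(yaml.safe_load(f))


# ---------------------------------------------------------------------------
# recordings
# ---------------------------------------------------------------------------


def write_recording_text(rec: Recording, path) -> None:
    """Time (ms) + one membrane-potential column (mV) per sweep."""
    stim = np.atleast_2d(np.asarray(rec.stimulus, dtype=float))
    if stim.shape[0] == 1 and rec.n_sweeps > 1:
        stim = stim.T if stim.shape[1] == rec.n_sweeps else stim
    with open(path, "w") as f:
        f.write(f"# kind {rec.stimulus_kind}\n")
        f.write(f"# dt_ms {rec.dt!r}\n")
        f.write(f"# window_ms {rec.window[0]!r} {rec.window[1]!r}\n")
        for s in range(rec.n_sweeps):
            desc = np.asarray(rec.stimulus)[s]
            vals = np.atleast_1d(desc)
            f.write("# sweep %d %s\n" % (s, " ".join(repr(float(v)) for v in vals)))
        data = np.column_stack([rec.time] + [rec.sweeps[s] for s in range(rec.n_sweeps)])
        np.savetxt(f, data, fmt="%.6g", delimiter="\t")


def read_recording_text(path) -> Recording:
    kind, dt, window, stim = "current_step", 0.05, (0.0, 0.0), []
    with open(path) as f:
        for line in f:
            if not line.startswith("#"):
                break
            parts = line[1:].split()
            if parts[0] == "kind":
                kind = parts[1]
            elif parts[0] == "dt_ms":
                dt = float(parts[1])
            elif parts[0] == "window_ms":
                window = (float(parts[1]), float(parts[2]))
            elif parts[0] == "sweep":
                stim.append([float(x) for x in parts[2:]])
    data = np.loadtxt(path)
    stim_arr = np.asarray(stim)
    if stim_arr.ndim == 2 and stim_arr.shape[1] == 1:
        stim_arr = stim_arr[:, 0]
    return Recording(
        dt=dt,
        sweeps=np.ascontiguousarray(data[:, 1:].T),
        window=window,
        stimulus=stim_arr,
        stimulus_kind=kind,
    )


def write_recording_npz(rec: Recording, path) -> None:
    np.savez_compressed(
        path,
        dt=rec.dt,
        sweeps=rec.sweeps,
        window=np.asarray(rec.window),
        stimulus=np.asarray(rec.stimulus, dtype=float),
        kind=rec.stimulus_kind,
    )


def read_recording_npz(path) -> Recording:
    z = np.load(path, allow_pickle=False)
    return Recording(
        dt=float(z["dt"]),
        sweeps=z["sweeps"],
        window=tuple(z["window"]),
        stimulus=z["stimulus"],
        stimulus_kind=str(z["kind"]),
    )
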