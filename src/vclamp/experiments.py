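"""End-to-end in-silico experiments over model populations.

Each experiment draws its populations and presynaptic waveforms from a
single master seed, runs the static current-step and synaptic-bombardment
protocols, extracts the excitability measures, and returns a
:class:`ResultTable` holding the per-instance rows and the population
summaries (Spearman correlations, medians, percent changes).  Outputs are
plain delimited text plus a JSON summary, with a run manifest for
auditability.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .features import relative_change, spearman
from .populations import (
    PHENOTYPES,
    LIFModel,
    child_seed,
    default_distribution,
    lif_simulate,
    population_manifest,
    sample_lif_population,
    sample_population,
    write_waveform_ascii,
)
from .protocols import (
    D_TAU_GRID,
    D_VHALF_GRID,
    KIR_TAU_GRID,
    KIR_VHALF_GRID,
    CurrentStepProtocol,
    SynapticBombardmentProtocol,
    apply_sweep_setting,
    block_current,
    make_bombardment_drive,
    run_population_experiment,
)
from .features import cumulative_spike_count, io_curve, rheobase, threshold_conductance

__all__ = [
    "ExperimentConfig",
    "ResultTable",
    "experiment_fig3",
    "experiment_blockade",
    "experiment_kinetics",
    "experiment_lif_control",
    "SWEEP_SCHEDULES",
]

SWEEP_SCHEDULES = {
    "kir_vhalf": ("delayed", KIR_VHALF_GRID),
    "kir_tau": ("delayed", KIR_TAU_GRID),
    "d_vhalf": ("stuttering", D_VHALF_GRID),
    "d_tau": ("stuttering", D_TAU_GRID),
}


@dataclass
class ExperimentConfig:
    """Serializable description of one experiment run."""

    seed: int = 1
    n_per_phenotype: int = 200
    phenotypes: tuple = PHENOTYPES
    protocol: CurrentStepProtocol = field(default_factory=CurrentStepProtocol)
    bombardment: SynapticBombardmentProtocol = field(
        default_factory=SynapticBombardmentProtocol
    )
    dt: float = 0.025
    blockade_current: Optional[str] = None
    remove_h_first: bool = False
    sweep: Optional[str] = None
    n_subset: int = 25
    out_dir: Optional[str] = None

    def as_dict(self) -> dict:
        d = asdict(self)
        d["phenotypes"] = list(self.phenotypes)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.as_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class ResultTable:
    """Per-instance rows plus derived population summaries."""

    rows: pd.DataFrame
    summary: dict
    config: ExperimentConfig

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.rows.to_csv(out / "rows.tsv", sep="\t", index=False)
        with open(out / "summary.json", "w") as f:
            json.dump(self.summary, f, indent=2, default=_jsonify)
        manifest = {
            "package_version": __version__,
            "config": self.config.as_dict(),
            "config_hash": self.config.config_hash(),
            "n_rows": int(len(self.rows)),
        }
        with open(out / "manifest.json", "w") as f:
            json.dump(manifest, f, indent=2, default=_jsonify)


def _jsonify(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    return str(x)


def _drive(config: ExperimentConfig, out_dir=None):
    drive = make_bombardment_drive(
        config.bombardment, seed=child_seed(config.seed, "waveforms"), dt=config.dt
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_waveform_ascii(drive.waveforms[0], out / "presyn_exc.txt")
        write_waveform_ascii(drive.waveforms[1], out / "presyn_inh.txt")
    return drive


def _populations(config: ExperimentConfig):
    pops = {}
    for ph in config.phenotypes:
        seed = child_seed(config.seed, "pop", ph)
        pops[ph] = sample_population(
            default_distribution(ph), config.n_per_phenotype, seed
        )
        if config.out_dir:
            out = Path(config.out_dir)
            out.mkdir(parents=True, exist_ok=True)
            population_manifest(pops[ph], seed).to_csv(
                out / f"population_{ph}.tsv", sep="\t", index=False
            )
    return pops


def _corr_or_nan(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    if keep.sum() < 3:
        return float("nan")
    try:
        return spearman(x[keep], y[keep])
    except ValueError:
        return float("nan")


def experiment_fig3(config: ExperimentConfig, progress: bool = False) -> ResultTable:
    """Population maps and the static-vs-dynamic count correlation.

    Runs ``n_per_phenotype`` instances of each phenotype through both
    protocols and summarizes the excitability maps: input resistance vs.
    resting potential, threshold conductance vs. rheobase, and the dynamic
    vs. static cumulative spike counts with their Spearman correlation.
    """
    drive = _drive(config, config.out_dir)
    frames = []
    for ph, models in _populations(config).items():
        df = run_population_experiment(
            models, config.protocol, drive, dt=config.dt, progress=progress
        )
        df["phenotype"] = ph
        frames.append(df)
        if progress:
            print(f"{ph}: {len(df)} rows", flush=True)
    rows = pd.concat(frames, ignore_index=True)
    ok = rows[~rows["failed"]]
    summary = {
        "n": int(len(ok)),
        "spearman_dynamic_vs_static_counts": _corr_or_nan(
            ok["static_count"], ok["dynamic_count"]
        ),
        "spearman_threshold_g_vs_rheobase": _corr_or_nan(
            ok["rheobase_pA"], ok["threshold_g_nS"]
        ),
        "median_by_phenotype": {
            ph: g[
                ["rheobase_pA", "threshold_g_nS", "static_count", "dynamic_count",
                 "latency13_ms", "input_resistance_MOhm", "resting_mV", "sag_ratio"]
            ].median().to_dict()
            for ph, g in ok.groupby("phenotype")
        },
        "n_failed": int(rows["failed"].sum()),
    }
    table = ResultTable(rows=rows, summary=summary, config=config)
    if config.out_dir:
        table.save(config.out_dir)
    return table


def experiment_blockade(config: ExperimentConfig, progress: bool = False) -> ResultTable:
    """Virtual pharmacology: remove one K-current and compare both I-O sets.

    ``config.blockade_current`` names the removed current (Kir on the
    delayed population, D on the stuttering one); ``remove_h_first`` first
    strips the h-current from stuttering models, reproducing the
    h-current-free control.  Percent changes exclude zero-baseline
    instances but their counts stay in the rows.
    """
    cur = config.blockade_current
    if cur is None:
        raise ValueError("blockade_current must be set")
    drive = _drive(config, config.out_dir)
    frames = []
    for ph, models in _populations(config).items():
        if config.remove_h_first:
            models = [block_current(m, "h") if "h" in m.current_names() else m
                      for m in models]
        df = run_population_experiment(
            models,
            config.protocol,
            drive,
            manipulation=lambda m: block_current(m, cur),
            dt=config.dt,
            progress=progress,
        )
        df["phenotype"] = ph
        frames.append(df)
    rows = pd.concat(frames, ignore_index=True)
    summary = {"blocked_current": cur}
    for kind in ("static", "dynamic"):
        col = f"{kind}_count"
        before = rows[rows.condition == "baseline"].set_index(["phenotype", "instance"])[col]
        after = rows[rows.condition == "manipulated"].set_index(["phenotype", "instance"])[col]
        changes, excluded = [], 0
        for key in before.index:
            b, a = before[key], after[key]
            if b > 0:
                changes.append(relative_change(b, a))
            else:
                excluded += 1
        summary[f"{kind}_pct_change_median"] = float(np.median(changes)) if changes else float("nan")
        summary[f"{kind}_pct_change_mean"] = float(np.mean(changes)) if changes else float("nan")
        summary[f"{kind}_n"] = len(changes)
        summary[f"{kind}_n_excluded_zero_baseline"] = excluded
    table = ResultTable(rows=rows, summary=summary, config=config)
    if config.out_dir:
        table.save(config.out_dir)
    return table


def _subset_indices(static_counts: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Seeded stratified subset along the cumulative static count."""
    n = len(static_counts)
    k = min(k, n)
    order = np.argsort(static_counts, kind="stable")
    rng = np.random.default_rng(seed)
    # one draw per stratum of the sorted order
    edges = np.linspace(0, n, k + 1).astype(int)
    picks = [order[rng.integers(lo, hi)] if hi > lo else order[lo]
             for lo, hi in zip(edges[:-1], edges[1:])]
    return np.array(sorted(set(int(p) for p in picks)))


def experiment_kinetics(config: ExperimentConfig, progress: bool = False) -> ResultTable:
    """Kinetic-parameter sweep over a representative instance subset.

    ``config.sweep`` picks one of ``kir_vhalf``/``kir_tau``/``d_vhalf``/
    ``d_tau``.  A fixed ``n_subset``-instance subset (seeded, stratified on
    cumulative static count) of the phenotype's population is re-simulated
    at every grid setting; rows come back in grid order per instance.
    """
    if config.sweep not in SWEEP_SCHEDULES:
        raise ValueError(f"unknown sweep {config.sweep!r}")
    ph, sched = SWEEP_SCHEDULES[config.sweep]
    drive = _drive(config, config.out_dir)
    models = sample_population(
        default_distribution(ph),
        config.n_per_phenotype,
        child_seed(config.seed, "pop", ph),
    )
    # baseline static counts for the stratified subset choice
    base = run_population_experiment(models, config.protocol, drive=None, dt=config.dt)
    idx = _subset_indices(
        base["static_count"].to_numpy(), config.n_subset, child_seed(config.seed, "subset", ph)
    )
    rows = []
    for j, i in enumerate(idx):
        for val in sched.grid:
            m = apply_sweep_setting(models[i], sched, float(val))
            sc = io_curve(
                _run_static(m, config)
            )
            dc = io_curve(_run_dynamic(m, drive))
            rows.append(
                dict(
                    phenotype=ph,
                    instance=int(i),
                    sweep=config.sweep,
                    setting=float(val),
                    static_count=cumulative_spike_count(sc),
                    dynamic_count=cumulative_spike_count(dc),
                    rheobase_pA=rheobase(sc),
                    threshold_g_nS=threshold_conductance(dc),
                )
            )
        if progress:
            print(f"instance {j + 1}/{len(idx)} done", flush=True)
    rows = pd.DataFrame(rows)
    net = rows.groupby("instance").agg(
        static_net=("static_count", lambda s: s.iloc[-1] - s.iloc[0]),
        dynamic_net=("dynamic_count", lambda s: s.iloc[-1] - s.iloc[0]),
    )
    summary = {
        "sweep": config.sweep,
        "grid": list(sched.grid),
        "n_instances": int(len(idx)),
        "static_net_change_median": float(net["static_net"].median()),
        "dynamic_net_change_median": float(net["dynamic_net"].median()),
        "fraction_opposite_direction": float(
            np.mean((net["static_net"] * net["dynamic_net"]) < 0)
        ),
    }
    table = ResultTable(rows=rows, summary=summary, config=config)
    if config.out_dir:
        table.save(config.out_dir)
    return table


def _run_static(m, config):
    from .protocols import run_static_protocol

    return run_static_protocol(m, config.protocol, dt=config.dt)


def _run_dynamic(m, drive):
    from .protocols import run_dynamic_protocol

    return run_dynamic_protocol(m, drive)


def experiment_lif_control(config: ExperimentConfig, progress: bool = False) -> ResultTable:
    """Passive-variation control: LIF population through both protocols.

    Checks how tightly static and dynamic excitability stay coupled when
    only passive parameters (and the threshold) vary.
    """
    drive = _drive(config, config.out_dir)
    bp = config.bombardment
    proto = config.protocol
    pop = sample_lif_population(
        config.n_per_phenotype, child_seed(config.seed, "lif")
    )
    rows = []
    for i, m in enumerate(pop):
        sr = lif_simulate(
            m, proto.amplitudes, sweep_duration=proto.cycle,
            stim_on=proto.onset, stim_off=proto.onset + proto.duration, dt=config.dt,
        )
        dr = lif_simulate(
            m, np.zeros(bp.n_sweeps), sweep_duration=bp.cycle,
            stim_on=0.0, stim_off=bp.on_duration, dt=config.dt,
            syn_exc=(drive.S_exc, bp.synapse_spec("exc")),
            syn_inh=(drive.S_inh, bp.synapse_spec("inh")),
            g_exc=bp.g_exc_schedule, g_inh=bp.g_inh_schedule,
        )
        sc, dc = io_curve(sr), io_curve(dr)
        rows.append(
            dict(
                instance=i,
                C_pF=m.C,
                g_leak_nS=m.g_leak,
                E_leak_mV=m.E_leak,
                V_threshold_mV=m.V_threshold,
                static_count=cumulative_spike_count(sc),
                dynamic_count=cumulative_spike_count(dc),
                rheobase_pA=rheobase(sc),
                threshold_g_nS=threshold_conductance(dc),
            )
        )
        if progress and (i + 1) % 50 == 0:
            print(f"{i + 1}/{len(pop)} LIF instances", flush=True)
    rows = pd.DataFrame(rows)
    summary = {
        "n": int(len(rows)),
        "spearman_dynamic_vs_static_counts": _corr_or_nan(
            rows["static_count"], rows["dynamic_count"]
        ),
        "spearman_threshold_g_vs_rheobase": _corr_or_nan(
            rows["rheobase_pA"], rows["threshold_g_nS"]
        ),
    }
    table = ResultTable(rows=rows, summary=summary, config=config)
    if config.out_dir:
        table.save(config.out_dir)
    return table
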