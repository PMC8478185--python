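# vclamp — virtual electrophysiology of hippocampal neuron phenotypes

Conventional measures of intrinsic excitability come from step-current
protocols, but neurons in vivo integrate fluctuating synaptic conductances.
`vclamp` asks how well the static measures predict the dynamic ones. It
simulates three-compartment Hodgkin–Huxley model neurons of three
hippocampal phenotypes — regular firing, delayed firing (inward-rectifier
K-current, I_Kir) and stuttering (slowly inactivating D-type Kv1 current,
I_D) — under two protocols:

* **static**: 400 ms current steps, −160 → +200 pA in 5 pA increments;
* **dynamic**: simulated synaptic bombardment — mixed AMPA/GABA
  conductances (τ = 10 ms, E = 0 / −72 mV) driven by replayed Poissonian
  presynaptic waveforms, with the AMPA peak ramped 0 → 25 nS in 0.5 nS
  steps (GABA 1 nS steps), 2.5 s on + 2.5 s rest per cycle.

Every current follows the template `I = g·m^p·h·(E − V)` with tanh-sigmoid
steady states and bell-shaped voltage-dependent time constants. Populations
are generated by Gaussian variation of the maximal conductances,
capacitance, leak reversal and couplings. The per-cell excitability
measures are the rheobase, the threshold AMPA conductance, the cumulative
(total) spike count of each protocol, the Belehrádek-fitted first-spike
latency at 1.3× rheobase, input resistance, resting potential and sag
ratio; populations are summarized by Spearman rank correlations and
percent-change statistics.

The package reproduces, in silico, the study's main findings: static and
dynamic excitability are only weakly correlated across a biophysically
diverse population (Corr_S ≈ 0.5) although a purely passive
integrate-and-fire control stays near-perfectly correlated (≥ 0.95);
removing I_Kir from delayed-firing models boosts the synaptic response more
than the static one while removing I_D from stuttering models does the
opposite; and slowing the D-current's kinetics moves static and dynamic
firing in opposite directions.

## Worked example

```python
import vclamp as vc
from vclamp.protocols import (CurrentStepProtocol, SynapticBombardmentProtocol,
                              make_bombardment_drive, run_static_protocol,
                              run_dynamic_protocol, repetitive_firing_transition)

model = vc.canonical_model("stuttering")
static = run_static_protocol(model, CurrentStepProtocol())
curve = vc.io_curve(static)
print("rheobase [pA]     :", vc.rheobase(curve))
print("static cum. count :", vc.cumulative_spike_count(curve))
print("input R [MOhm]    :", round(vc.input_resistance(static), 1))
print("sag ratio         :", round(vc.sag_ratio(static), 2))
print("transition [pA]   :", repetitive_firing_transition(
    curve, spike_times=static.meta["spike_times"]))

drive = make_bombardment_drive(SynapticBombardmentProtocol(), seed=1)
dynamic = run_dynamic_protocol(model, drive)
dcurve = vc.io_curve(dynamic)
print("threshold g [nS]  :", vc.threshold_conductance(dcurve))
print("dynamic cum. count:", vc.cumulative_spike_count(dcurve))
```

prints

```
rheobase [pA]     : 115.0
static cum. count : 70
input R [MOhm]    : 184.4
sag ratio         : 0.26
transition [pA]   : 195.0
threshold g [nS]  : 5.5
dynamic cum. count: 1268
```

— the stuttering signature: high rheobase, very low static spike count with
single spikes near rheobase, an abrupt jump to repetitive firing at
+195 pA, a voltage sag, and a comparatively vigorous response to synaptic
bombardment. `vc.canonical_model("delayed")` shows the mirror image (low
rheobase, high static count, long first-spike latency, suppressed synaptic
response).

Population experiments are orchestrated by `vclamp.experiments`
(`experiment_fig3`, `experiment_blockade`, `experiment_kinetics`,
`experiment_lif_control`) or from the shell:

```
vclamp run fig3     --seed 1 --n 50  --out runs/fig3
vclamp run blockade --seed 1 --n 20 --phenotype delayed --current Kir --out runs/kir
vclamp run kinetics --seed 1 --sweep d_tau --subset 25 --out runs/dtau
vclamp run lif      --seed 1 --out runs/lif
```

Each run writes `rows.tsv` (per-instance features), `summary.json`
(correlations, medians, percent changes), the presynaptic waveforms as
ASCII files, and a `manifest.json` with the config hash and seeds.

## Layout

| module                | contents |
|-----------------------|----------|
| `vclamp.biophys`      | gating/current/synapse specs, cell model, integration driver |
| `vclamp._kernel`      | compiled exponential-Euler sweep loop (numba) |
| `vclamp.reference`    | independent RK4 reference integrator for validation |
| `vclamp.populations`  | canonical phenotypes, Gaussian populations, Poisson waveforms, LIF control |
| `vclamp.protocols`    | step and bombardment protocols, virtual pharmacology, kinetic sweeps |
| `vclamp.features`     | spike detection, I-O curves, rheobase, Belehrádek latency fit, Spearman |
| `vclamp.experiments`  | end-to-end population experiments and result tables |
| `vclamp.modelio`      | YAML model configs (bit-exact round-trip), recording export |
| `vclamp.cli`          | `vclamp run …` command-line interface |

The model equations, parameter choices, calibration rationale and known
limitations are documented in [`docs/methods.md`](docs/methods.md).
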