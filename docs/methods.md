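# Methods

## The question the package addresses

Intrinsic excitability is conventionally measured with step-current
protocols, yet neurons in vivo are driven by fluctuating synaptic
conductances. `vclamp` implements a virtual-electrophysiology study of this
mismatch: conductance-based model populations of three hippocampal
phenotypes (regular firing, delayed firing, stuttering) are driven both by
a static current-step protocol and by simulated Poissonian synaptic
bombardment, and the static vs. dynamic excitability measures are compared
— including virtual pharmacology (removal of the Kir and D-type K-currents)
and sweeps of their kinetic parameters.

## Cell model

Each cell has three compartments (soma, axon, dendrite) with capacitances
`C` (pF), leak conductances/reversals, and electrical couplings `g_sx`
(soma–axon) and `g_sd` (soma–dendrite). Every voltage-gated current follows
the Hodgkin–Huxley template

    I_i = g_i · m^p · h · (E_i − V)                      [nS·mV = pA]

with first-order gating `dx/dt = (x_inf(V) − x)/tau_x(V)`, steady states

    x_inf(V) = 1/2 + 1/2 tanh((V − V_half)/V_slope)

and bell-shaped time constants

    tau_x(V) = (tau_max − tau_min)(1 − tanh²((V − V_tau_half)/V_tau_slope)) + tau_min.

A negative `V_slope` gives gates that open with hyperpolarization
(inactivation gates; Kir and h activation). The unit system is
mV / ms / nS / pA / pF throughout, chosen because it is closed (nS·mV = pA,
pF·mV/ms = pA).

The calcium machinery is a deliberately minimal single-pool formalism: the
low-threshold Ca current (CaT) feeds a first-order pool,
`d[Ca]/dt = φ·I_Ca − ([Ca] − Ca_rest)/τ_Ca`, and the Ca-gated K-current
activates instantaneously as `[Ca]/([Ca] + K_half)`. Concentration units
are arbitrary; only the ratio to `K_half` matters.

Synapses follow a first-order transmitter-release law driven by a
presynaptic voltage waveform:

    I_syn = g_syn · S · (E_syn − V),
    dS/dt = (S_inf(V_pre) − S) / (τ_syn (1 − S_inf(V_pre))),
    S_inf = tanh((V_pre − V_th)/V_slope)  for V_pre > V_th, else 0.

`S_inf` is clamped at 1 − 1e−6 because the rate law divides by
`(1 − S_inf)`. Because `S` depends only on `V_pre`, each waveform's
activation series is integrated once and replayed identically to every
instance and sweep — mirroring a conductance-clamp rig replaying stored
waveform files.

## Canonical phenotypes

The three canonical parameter sets were designed to reproduce the defining
behaviors of the phenotypes:

* **regular** — Na/Kd spiking, small h-current (voltage sag), low rheobase
  (+60 pA), continuous monotone f-I curve.
* **delayed** — an inward-rectifier K-current (Kir: activation midpoint
  −91 mV, peak activation time constant 10 ms, reversal −90 mV) holds the
  resting potential near −75 mV, produces strong inward rectification under
  hyperpolarizing steps, and delays the first spike (slow pre-spike ramp);
  no h-current. A large, slow soma (32 pF) makes the cell comparatively
  insensitive to fast synaptic fluctuations.
* **stuttering** — a slowly inactivating D-type (Kv1) current (activation
  τ_max 14 ms, inactivation τ_max 200 ms at fixed ratio) enforces a single
  short-latency spike near rheobase, irregular firing above it, and a
  discontinuous jump to repetitive firing at +195 pA; low input resistance,
  strong delayed-rectifier (outward rectification), h-current (sag), and a
  small fast soma (10 pF) that makes the cell respond vigorously to
  synaptic transients.

Membrane capacitance is the main axis separating static from dynamic
excitability across phenotypes: it rescales the response to brief
fluctuating inputs roughly as 1/C while leaving steady-state I-O relations
(rheobase, step-evoked rates) nearly unchanged. This is what lets the
stuttering model combine the lowest static spike counts with among the
highest dynamic counts, and the delayed model the reverse — the corner
structure behind the weak pooled correlation.

Key derived measures of the canonical models (printed by the worked example
in the README): input resistance regular 341 MΩ, delayed 274 MΩ, stuttering
184 MΩ; near-rheobase first-spike latency ≈ 35 ms (delayed) vs ≈ 6 ms
(stuttering); sag ratio > 0.2 for regular and stuttering, ≈ 0 for delayed.

## Protocols

* **Static**: current steps of 400 ms, −160 to +200 pA in 5 pA increments
  (73 sweeps), 1.25 s cycle, step onset 100 ms into the cycle. Spikes are
  counted inside the step window only.
* **Dynamic**: mixed AMPA/GABA bombardment. Per sweep k (k = 0..50) the
  peak conductances are g_AMPA = 0.5k nS and g_GABA = 1k nS; synaptic time
  constant 10 ms for both; reversals 0 / −72 mV; 2.5 s of drive + 2.5 s
  rest per 5 s cycle. Spikes are counted during the on-phase.

State carries over between sweeps (the experimental protocols cycle
continuously); the first sweep starts from a settled resting state.

The presynaptic waveforms are homogeneous-Poisson pulse trains (1 ms
rectangles from −65 to +20 mV). Rates default to 40 Hz (excitatory) and
60 Hz (inhibitory); with the release sigmoid slope of 35 mV a single pulse
drives S to ≈ 0.33. These three numbers are the calibration of the drive:
they were chosen once so that (i) all three canonical phenotypes reach
threshold within the 0–25 nS schedule, (ii) the dynamic I-O keeps growing
over the schedule rather than locking one spike to each presynaptic event,
and (iii) the passive LIF control retains its tight static/dynamic
coupling. Near-saturating release (S ≈ 0.9 per event) is specifically
avoided: it produces a post-event depolarization block that caps every
cell at one spike per event and erases the conductance dependence of the
dynamic response.

## Numerics

* Integrator: exponential Euler for gating and synaptic states, forward
  Euler for voltages, fixed dt = 0.025 ms; recordings are downsampled to
  0.05 ms (20 kHz). 0.025 ms is used (rather than, say, 0.02) so the
  integration step divides the recording interval exactly.
* Gate steady states and per-step decay factors are tabulated on a 0.05 mV
  grid over [−150, 100] mV with linear interpolation; the table entries are
  exact evaluations, and interpolation error at this resolution is far
  below integration error.
* Validation: an independent fixed-step RK4 integrator evaluating the
  equations directly (no tables, no operator splitting) at dt/4 reproduces
  the spike counts of all three canonical models exactly across the step
  protocol; first-spike latencies agree within 1 ms. Later spikes in long
  trains accumulate phase drift of up to ~1.6 ms between the two schemes —
  a phase, not topology, discrepancy.
* Divergence guard: |V| > 200 mV sustained for more than 1 ms aborts the
  instance with a diagnostic; population runs record such instances as
  flagged rows and continue.
* Spike detection: upward crossings of −10 mV at the soma with a 2 ms
  refractory guard. Axonal spikelets that fail to reach −10 mV at the soma
  are not counted.

## Feature extraction

Rheobase (smallest step current with ≥ 1 spike) and threshold AMPA
conductance (smallest g_AMPA with ≥ 1 spike) are missing (NaN) when the
cell never fires up to the protocol maximum; the cumulative count is then
0 and such rows are kept. First-spike latencies across suprathreshold
steps are fitted with the three-parameter Belehrádek power law
`L(I) = a (I − b)^c` (fit in log space, offset `b` profiled on
`[min(I) − 500, min(I) − 1]`); `Latency_1.3 = L(1.3 × rheobase)`. Input
resistance is the slope of steady-state ΔV vs ΔI over the −20..0 pA steps
(last 50 ms of the step); the sag ratio is
`(peak − steady)/(peak − baseline)` on the −160 pA sweep, clamped to
[0, 1]. Spearman correlation is Pearson on average ranks (ties get average
ranks).

## Populations

Instances are drawn by Gaussian variation around the canonical model:
maximal conductances of all voltage-gated currents (relative SD 25%),
membrane capacitance (common factor, SD 15%), leak reversal potential
(SD 2 mV, common shift) and the two coupling conductances (SD 25%).
Kinetic parameters and reversals are never varied. Negative draws for
nonnegative parameters are resampled (not clipped). One master seed
deterministically derives all child seeds (populations, waveforms, LIF).

The LIF control varies membrane capacitance, leak conductance, leak
reversal and spike threshold with the same scheme (15% / 25% / 2 mV /
2 mV), nominals C = 60 pF, g_L = 3 nS, E_L = −65 mV, V_th = −45 mV,
V_reset = −60 mV, t_ref = 3 ms. Subthreshold dynamics are passive RC;
threshold crossings reset the voltage and clamp it for the refractory
period. A stereotyped +30 mV sample is painted into the trace at each
spike so the same threshold-crossing detector serves LIF and HH recordings.

## Manipulation experiments

* **Blockade** sets a named current's total conductance to zero (all-or-
  none; no dose–response). Percent-change summaries exclude instances with
  zero baseline count; their rows are retained.
* **Kinetic sweeps**: Kir activation midpoint −91 → −75 mV (+2 mV, 9
  settings) and Kir activation τ_max 10 → 130 ms (+15 ms); D-current
  coupled midpoint shift (activation and inactivation midpoints move
  together, preserving the window overlap) and coupled τ_max rescaling
  2 → 18 ms (+2 ms, activation and inactivation τ scaled by the same
  factor so their ratio is fixed; τ_min co-scales proportionally with
  τ_max). Sweeps run on a fixed seeded subset chosen by stratified
  sampling on the cumulative static count.

## What the generator does and does not emulate

The synthetic populations vary only conductance magnitudes and passive
parameters; real hippocampal cultures additionally vary morphology,
channel kinetics, synaptic connectivity and spontaneous network activity.
Passing tests therefore demonstrate that conductance-magnitude diversity
plus the two K-currents are *sufficient* to reproduce the static/dynamic
divergence and its pharmacology — not that they are the only cause in
biological recordings. Biological effect sizes (the wet-pharmacology
percent changes and the recorded-cell correlations) are not reproducible
from simulations and are out of scope.

## Known limitations and open choices

* The canonical stuttering model's threshold AMPA conductance is higher
  than the delayed model's, whereas recorded stuttering neurons started
  firing at lower conductances than delayed ones; the population-level
  count structure is reproduced, the threshold-map ordering is not.
* A small depolarizing shift of the D window pushes the repetitive-firing
  transition above the +200 pA protocol cap, so the canonical static count
  dips before growing along the coupled D midpoint sweep; the dynamic
  count is monotone non-decreasing.
* The Ca/KCa formalism is a minimal stand-in (single pool, instantaneous
  saturating activation) and is kept weak enough not to dominate any of
  the reported measures.
* Default problem sizes for the study-level checks are 50 instances per
  phenotype (correlation), 8–10 instance subsets (blockade and kinetic
  sweeps) and 200 LIF instances; the full-scale reproduction at 200
  instances per phenotype runs with `--n 200` and changes no directions,
  only tightens the estimates.
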