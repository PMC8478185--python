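"""Excitability and physiological measures extracted from recordings.

The two scalar excitability measures are the rheobase (smallest step
current evoking a spike) with its synaptic analogue (threshold AMPA
conductance) and the cumulative spike count over all sweeps of a protocol.
First-spike latencies across suprathreshold steps are summarized by a
Belehradek power-law fit L(I) = a (I - b)^c evaluated at 1.3x rheobase.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import optimize, stats

from .biophys import Recording

__all__ = [
    "SpikeTrain",
    "IOCurve",
    "FeatureRecord",
    "BelehradekFit",
    "FitError",
    "SPIKE_THRESHOLD",
    "SPIKE_GUARD",
    "detect_spikes",
    "io_curve",
    "rheobase",
    "threshold_conductance",
    "cumulative_spike_count",
    "fit_belehradek",
    "latency_1_3",
    "input_resistance",
    "resting_potential",
    "sag_ratio",
    "spearman",
    "relative_change",
    "extract_features",
]

#: Spikes are upward crossings of this somatic voltage (mV) ...
SPIKE_THRESHOLD = -10.0
#: ... separated by at least this refractory guard (ms).
SPIKE_GUARD = 2.0


class FitError(RuntimeError):
    """Raised when a latency fit is under-determined or fails to converge."""


@dataclass
class SpikeTrain:
    """Spike times (ms, relative to stimulus onset) of one sweep."""

    sweep: int
    times: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=np.float64)
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("spike times must be strictly increasing")
        self.times = t

    @property
    def count(self) -> int:
        return int(self.times.size)


@dataclass
class IOCurve:
    """Input-output relation: spike count (and first-spike latency) per sweep.

    ``stimulus`` is the step current (pA) or the AMPA conductance (nS).
    ``latency`` is NaN on sweeps without spikes.
    """

    stimulus: np.ndarray
    counts: np.ndarray
    latency: np.ndarray
    kind: str = "current_step"


@dataclass
class BelehradekFit:
    """L(I) = a (I - b)^c with c < 0 and b below the fitted currents."""

    a: float
    b: float
    c: float
    residual: float

    def __call__(self, I):
        return self.a * np.power(np.asarray(I, dtype=float) - self.b, self.c)


@dataclass
class FeatureRecord:
    """Per-instance excitability summary.

    Missing rheobase / threshold conductance (never fired up to the protocol
    maximum) is NaN and implies the corresponding cumulative count is 0.
    """

    rheobase: float
    threshold_g: float
    static_count: int
    dynamic_count: int
    latency_1_3: float
    input_resistance: float
    resting_potential: float
    sag_ratio: float
    flags: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "rheobase_pA": self.rheobase,
            "threshold_g_nS": self.threshold_g,
            "static_count": self.static_count,
            "dynamic_count": self.dynamic_count,
            "latency13_ms": self.latency_1_3,
            "input_resistance_MOhm": self.input_resistance,
            "resting_mV": self.resting_potential,
            "sag_ratio": self.sag_ratio,
        }


# ---------------------------------------------------------------------------
# spike detection and I-O curves
# ---------------------------------------------------------------------------


def detect_spikes(
    trace: np.ndarray,
    dt: float,
    window: tuple[float, float],
    threshold: float = SPIKE_THRESHOLD,
    guard: float = SPIKE_GUARD,
    sweep: int = 0,
) -> SpikeTrain:
    """Upward threshold crossings within ``window`` (ms from trace start)."""
    v = np.asarray(trace)
    i0 = int(round(window[0] / dt))
    i1 = min(int(round(window[1] / dt)), v.size)
    if i0 < 0 or i0 > v.size:
        raise ValueError("window outside trace")
    seg = v[i0:i1]
    above = seg > threshold
    cross = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if above.size and above[0]:
        cross = np.concatenate(([0], cross))
    times = []
    last = -np.inf
    for idx in cross:
        t = idx * dt
        if t - last >= guard:
            times.append(t)
            last = t
    return SpikeTrain(sweep=sweep, times=np.asarray(times))


def io_curve(rec: Recording, threshold: float = SPIKE_THRESHOLD) -> IOCurve:
    """Per-sweep spike counts and first-spike latencies over the stimulation
    window.  Latency is measured from stimulus onset."""
    t0, t1 = rec.window
    counts = np.zeros(rec.n_sweeps, dtype=int)
    lat = np.full(rec.n_sweeps, np.nan)
    for s in range(rec.n_sweeps):
        st = detect_spikes(rec.sweeps[s], rec.dt, (t0, t1), threshold=threshold, sweep=s)
        counts[s] = st.count
        if st.count:
            lat[s] = st.times[0]
    if rec.stimulus_kind == "synaptic":
        stim = np.asarray(rec.stimulus)[:, 0]
    else:
        stim = np.asarray(rec.stimulus, dtype=float)
    return IOCurve(stimulus=stim, counts=counts, latency=lat, kind=rec.stimulus_kind)


def rheobase(curve: IOCurve) -> float:
    """Smallest step current with at least one spike; NaN if never firing."""
    idx = np.flatnonzero(curve.counts >= 1)
    return float(curve.stimulus[idx[0]]) if idx.size else float("nan")


def threshold_conductance(curve: IOCurve) -> float:
    """Smallest AMPA conductance with at least one spike; NaN if silent."""
    idx = np.flatnonzero(curve.counts >= 1)
    return float(curve.stimulus[idx[0]]) if idx.size else float("nan")


def cumulative_spike_count(curve: IOCurve) -> int:
    """Total spike count over all sweeps of the protocol."""
    return int(np.sum(curve.counts))


# ---------------------------------------------------------------------------
# latency fit
# ---------------------------------------------------------------------------


def fit_belehradek(currents, latencies) -> BelehradekFit:
    """Least-squares Belehradek fit to first-spike latencies.

    Fitted in log space: for a trial offset ``b`` the model is linear in
    (log a, c); the scalar profile over b is minimized on
    ``[min(I) - 500, min(I) - 1]``.  Requires >= 4 points.
    """
    I = np.asarray(currents, dtype=float)
    L = np.asarray(latencies, dtype=float)
    keep = np.isfinite(I) & np.isfinite(L) & (L > 0)
    I, L = I[keep], L[keep]
    if I.size < 4:
        raise FitError("need at least 4 (current, latency) pairs")
    logL = np.log(L)
    b_hi = I.min() - 1.0
    b_lo = I.min() - 500.0

    def profile(b):
        x = np.log(I - b)
        A = np.column_stack([np.ones_like(x), x])
        coef, res, *_ = np.linalg.lstsq(A, logL, rcond=None)
        r = logL - A @ coef
        return float(r @ r), coef

    res = optimize.minimize_scalar(
        lambda b: profile(b)[0], bounds=(b_lo, b_hi), method="bounded",
        options={"xatol": 1e-6},
    )
    if not res.success:
        raise FitError("Belehradek fit did not converge")
    b = float(res.x)
    sse, (loga, c) = profile(b)
    return BelehradekFit(a=float(np.exp(loga)), b=b, c=float(c), residual=sse)


def latency_1_3(fit: BelehradekFit, rheo: float) -> float:
    """Fitted latency at 1.3x rheobase (ms); NaN propagates from rheobase."""
    if not np.isfinite(rheo):
        return float("nan")
    x = 1.3 * rheo
    if x <= fit.b:
        raise ValueError("evaluation point at or below the fit offset b")
    return float(fit(x))


# ---------------------------------------------------------------------------
# passive measures
# ---------------------------------------------------------------------------


def _steady_and_baseline(rec: Recording, s: int) -> tuple[float, float]:
    t0, t1 = rec.window
    v = rec.sweeps[s]
    i_on = int(round(t0 / rec.dt))
    i_off = int(round(t1 / rec.dt))
    n50 = int(round(50.0 / rec.dt))
    steady = float(np.mean(v[i_off - n50 : i_off]))
    base = float(np.mean(v[max(0, i_on - n50) : i_on])) if i_on > 0 else float("nan")
    return steady, base


def input_resistance(rec: Recording) -> float:
    """Slope (MOhm) of steady-state dV vs dI over small hyperpolarizing
    steps (-20..0 pA), steady state taken over the last 50 ms of the step."""
    if rec.stimulus_kind != "current_step":
        raise ValueError("input resistance requires a current-step recording")
    amps = np.asarray(rec.stimulus, dtype=float)
    sel = np.flatnonzero((amps >= -20.0) & (amps <= 0.0))
    if sel.size < 2:
        raise ValueError("no subthreshold hyperpolarizing sweeps in range")
    dV = np.array([_steady_and_baseline(rec, s)[0] for s in sel])
    slope = np.polyfit(amps[sel], dV, 1)[0]  # mV/pA = GOhm
    return float(slope * 1000.0)


def resting_potential(rec: Recording) -> float:
    """Mean pre-stimulus baseline of the zero-current sweep (or all sweeps)."""
    amps = np.asarray(rec.stimulus, dtype=float)
    if amps.ndim == 1:
        zero = np.flatnonzero(amps == 0.0)
        sel = zero if zero.size else np.arange(rec.n_sweeps)
    else:
        sel = np.arange(rec.n_sweeps)
    vals = [_steady_and_baseline(rec, s)[1] for s in sel]
    return float(np.nanmean(vals))


def sag_ratio(rec: Recording, amplitude: Optional[float] = None) -> float:
    """(peak hyperpolarization - steady state)/(peak - baseline) on the most
    hyperpolarized sweep; 0 for a monotone charging curve.  Always in [0, 1].
    """
    amps = np.asarray(rec.stimulus, dtype=float)
    if amplitude is None:
        s = int(np.argmin(amps))
    else:
        s = int(np.argmin(np.abs(amps - amplitude)))
    t0, t1 = rec.window
    i_on = int(round(t0 / rec.dt))
    i_off = int(round(t1 / rec.dt))
    v = rec.sweeps[s]
    peak = float(np.min(v[i_on:i_off]))
    steady, base = _steady_and_baseline(rec, s)
    denom = peak - base
    if denom >= -1e-9:
        return 0.0
    ratio = (peak - steady) / denom
    return float(min(max(ratio, 0.0), 1.0))


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------


def spearman(x, y) -> float:
    """Spearman rank correlation: Pearson correlation of average ranks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length vectors with >= 3 entries")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValueError("zero variance in ranked data")
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry)))


def relative_change(before: float, after: float) -> float:
    """Percent change 100*(after - before)/before; requires before > 0."""
    if before <= 0:
        raise ValueError("relative change undefined for zero baseline")
    return 100.0 * (after - before) / before


# ---------------------------------------------------------------------------
# full per-instance extraction
# ---------------------------------------------------------------------------


def extract_features(
    static_rec: Recording, dynamic_rec: Optional[Recording] = None
) -> FeatureRecord:
    """All excitability measures of one instance from its two recordings."""
    sc = io_curve(static_rec)
    rheo = rheobase(sc)
    static_n = cumulative_spike_count(sc)
    flags = {}

    lat13 = float("nan")
    if np.isfinite(rheo):
        has = np.isfinite(sc.latency)
        if has.sum() >= 4:
            try:
                fit = fit_belehradek(sc.stimulus[has], sc.latency[has])
                lat13 = latency_1_3(fit, rheo)
            except (FitError, ValueError) as e:  # pragma: no cover - rare
                flags["latency_fit"] = str(e)
        else:
            flags["latency_fit"] = "fewer than 4 suprathreshold latencies"

    try:
        rin = input_resistance(static_rec)
    except ValueError as e:
        rin = float("nan")
        flags["input_resistance"] = str(e)
    vrest = resting_potential(static_rec)
    sag = sag_ratio(static_rec)

    thr_g = float("nan")
    dyn_n = 0
    if dynamic_rec is not None:
        dc = io_curve(dynamic_rec)
        thr_g = threshold_conductance(dc)
        dyn_n = cumulative_spike_count(dc)
    return FeatureRecord(
        rheobase=rheo,
        threshold_g=thr_g,
        static_count=static_n,
        dynamic_count=dyn_n,
        latency_1_3=lat13,
        input_resistance=rin,
        resting_potential=vrest,
        sag_ratio=sag,
        flags=flags,
    )
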