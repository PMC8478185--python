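"""Excitability measures: spike detection, I-O curves, latency fits, stats."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import vclamp as vc
from vclamp.biophys import Recording
from vclamp.features import (
    BelehradekFit,
    FitError,
    IOCurve,
    cumulative_spike_count,
    detect_spikes,
    fit_belehradek,
    input_resistance,
    io_curve,
    latency_1_3,
    relative_change,
    rheobase,
    sag_ratio,
    spearman,
    threshold_conductance,
)


def _trace_with_spikes(times, dt=0.05, length=500.0, width=1.0, base=-65.0):
    v = np.full(int(length / dt), base)
    for t in times:
        i = int(t / dt)
        v[i : i + int(width / dt)] = 20.0
    return v


class TestDetectSpikes:
    def test_flat_trace_has_no_spikes(self):
        v = np.full(2000, -60.0)
        assert detect_spikes(v, 0.05, (0.0, 100.0)).count == 0

    def test_counts_distinct_crossings(self):
        v = _trace_with_spikes([50.0, 120.0, 300.0])
        st_ = detect_spikes(v, 0.05, (0.0, 500.0))
        assert st_.count == 3
        assert np.allclose(st_.times, [50.0, 120.0, 300.0], atol=0.06)

    def test_refractory_guard_merges_close_crossings(self):
        v = _trace_with_spikes([100.0, 100.5], width=0.2)
        assert detect_spikes(v, 0.05, (0.0, 500.0), guard=2.0).count == 1

    def test_window_excludes_outside_spikes(self):
        v = _trace_with_spikes([50.0, 450.0])
        assert detect_spikes(v, 0.05, (100.0, 400.0)).count == 0


class TestIOCurveAndThresholds:
    def test_rheobase_is_first_level_with_a_spike(self):
        c = IOCurve(stimulus=np.array([-10.0, -5, 0, 5, 10]),
                    counts=np.array([0, 0, 0, 1, 2]),
                    latency=np.array([np.nan, np.nan, np.nan, 20.0, 10.0]))
        assert rheobase(c) == 5.0

    def test_rheobase_missing_when_silent(self):
        c = IOCurve(stimulus=np.array([0.0, 5, 10]), counts=np.zeros(3, int),
                    latency=np.full(3, np.nan))
        assert np.isnan(rheobase(c))
        assert cumulative_spike_count(c) == 0

    def test_rheobase_at_lowest_level(self):
        c = IOCurve(stimulus=np.array([-10.0, 0.0]), counts=np.array([2, 3]),
                    latency=np.array([5.0, 4.0]))
        assert rheobase(c) == -10.0

    def test_threshold_conductance_boundaries(self):
        c = IOCurve(stimulus=np.array([0.0, 0.5, 1.0]),
                    counts=np.array([0, 0, 2]),
                    latency=np.array([np.nan, np.nan, 30.0]), kind="synaptic")
        assert threshold_conductance(c) == 1.0
        spont = IOCurve(stimulus=np.array([0.0, 0.5]), counts=np.array([1, 2]),
                        latency=np.array([9.0, 8.0]), kind="synaptic")
        assert threshold_conductance(spont) == 0.0

    def test_cumulative_count_is_order_invariant_sum(self):
        counts = np.array([1, 2, 3])
        c = IOCurve(stimulus=np.arange(3.0), counts=counts,
                    latency=np.full(3, 1.0))
        cr = IOCurve(stimulus=np.arange(3.0), counts=counts[::-1],
                     latency=np.full(3, 1.0))
        assert cumulative_spike_count(c) == cumulative_spike_count(cr) == 6

    def test_io_curve_consistency_on_simulated_recording(self, regular_static):
        curve = io_curve(regular_static)
        # kernel-side detection covers the whole sweep; restrict to the
        # stimulation window to compare with the trace-side counts
        t0, t1 = regular_static.window
        counts = [
            int(np.sum((np.asarray(t) >= t0) & (np.asarray(t) < t1)))
            for t in regular_static.meta["spike_times"]
        ]
        assert list(curve.counts) == counts
        assert cumulative_spike_count(curve) == sum(counts)


class TestBelehradek:
    def test_parameter_recovery_on_noiseless_data(self):
        a, b, c = 500.0, 20.0, -0.8
        I = np.linspace(40.0, 200.0, 20)
        L = a * (I - b) ** c
        fit = fit_belehradek(I, L)
        assert fit.a == pytest.approx(a, rel=0.01)
        assert fit.b == pytest.approx(b, rel=0.01)
        assert fit.c == pytest.approx(c, rel=0.01)

    def test_underdetermined_fit_is_an_error(self):
        with pytest.raises(FitError):
            fit_belehradek([10.0, 20.0, 30.0], [5.0, 4.0, 3.0])

    def test_fitted_curve_strictly_decreasing_for_negative_exponent(self):
        I = np.linspace(40.0, 200.0, 12)
        fit = fit_belehradek(I, 300.0 * (I - 25.0) ** -0.5)
        vals = fit(np.linspace(45.0, 195.0, 50))
        assert np.all(np.diff(vals) < 0)

    def test_latency_at_1p3_rheobase_direct_oracle(self):
        fit = BelehradekFit(a=500.0, b=20.0, c=-0.8, residual=0.0)
        got = latency_1_3(fit, rheo=100.0)
        assert got == pytest.approx(500.0 * (130.0 - 20.0) ** -0.8, abs=1e-9)
        assert got == pytest.approx(11.64, abs=0.01)

    def test_latency_propagates_missing_rheobase(self):
        fit = BelehradekFit(a=500.0, b=20.0, c=-0.8, residual=0.0)
        assert np.isnan(latency_1_3(fit, float("nan")))

    def test_latency_rejects_evaluation_below_offset(self):
        fit = BelehradekFit(a=500.0, b=200.0, c=-0.8, residual=0.0)
        with pytest.raises(ValueError):
            latency_1_3(fit, rheo=100.0)


class TestPassiveMeasures:
    def test_input_resistance_of_passive_cell(self, passive_cell):
        # g_L = 2 nS -> 500 MOhm
        from vclamp.protocols import CurrentStepProtocol, run_static_protocol

        proto = CurrentStepProtocol(start=-20.0, increment=5.0, stop=0.0,
                                    duration=400.0, cycle=800.0, onset=100.0)
        rec = run_static_protocol(passive_cell, proto)
        assert input_resistance(rec) == pytest.approx(500.0, rel=0.01)

    def test_sag_zero_for_monotone_passive_charging(self, passive_cell):
        from vclamp.protocols import CurrentStepProtocol, run_static_protocol

        proto = CurrentStepProtocol(start=-160.0, increment=80.0, stop=0.0,
                                    duration=400.0, cycle=800.0, onset=100.0)
        rec = run_static_protocol(passive_cell, proto)
        # monotone charging: only the unsettled tail of the exponential
        assert sag_ratio(rec) == pytest.approx(0.0, abs=0.01)

    def test_sag_positive_with_h_current(self, regular_static):
        assert 0.0 < sag_ratio(regular_static) <= 1.0


class TestSpearman:
    def test_perfect_monotone_relations(self):
        x = np.arange(10.0)
        assert spearman(x, 3 * x + 1) == pytest.approx(1.0)
        assert spearman(x, -(x**3)) == pytest.approx(-1.0)

    def test_small_example_pearson_on_ranks(self):
        assert spearman([1, 2, 3], [3, 1, 2]) == pytest.approx(-0.5)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_matches_brute_force_rank_pearson_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 6, size=25).astype(float)  # heavy ties
        y = rng.integers(0, 6, size=25).astype(float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return

        def brute_rank(v):
            r = np.empty_like(v)
            for i, vi in enumerate(v):
                less = np.sum(v < vi)
                eq = np.sum(v == vi)
                r[i] = less + (eq + 1) / 2.0
            return r

        rx, ry = brute_rank(x), brute_rank(y)
        num = np.sum((rx - rx.mean()) * (ry - ry.mean()))
        den = np.sqrt(np.sum((rx - rx.mean()) ** 2) * np.sum((ry - ry.mean()) ** 2))
        assert spearman(x, y) == pytest.approx(num / den, abs=1e-12)


class TestRelativeChange:
    def test_basic_percentages(self):
        assert relative_change(10, 10) == 0.0
        assert relative_change(10, 30) == pytest.approx(200.0)

    def test_zero_baseline_guarded(self):
        with pytest.raises(ValueError):
            relative_change(0, 5)
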