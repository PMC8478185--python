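"""Protocol definitions, virtual pharmacology and kinetic manipulations."""

import numpy as np
import pytest

import vclamp as vc
from vclamp.features import io_curve
from vclamp.protocols import (
    D_TAU_GRID,
    D_VHALF_GRID,
    KIR_TAU_GRID,
    KIR_VHALF_GRID,
    CurrentStepProtocol,
    KineticSweepSchedule,
    SynapticBombardmentProtocol,
    block_current,
    make_bombardment_drive,
    repetitive_firing_transition,
    run_dynamic_protocol,
    run_population_experiment,
    run_static_protocol,
    scale_time_constants,
    shift_activation_midpoint,
)


class TestProtocolDefinitions:
    def test_default_step_protocol_has_73_sweeps(self):
        amps = CurrentStepProtocol().amplitudes
        assert len(amps) == 73
        assert amps[0] == -160.0 and amps[-1] == 200.0
        assert np.allclose(np.diff(amps), 5.0)

    def test_default_bombardment_has_51_sweeps_and_locked_schedules(self):
        p = SynapticBombardmentProtocol()
        assert p.n_sweeps == 51
        assert p.g_exc_schedule[-1] == 25.0
        assert np.allclose(p.g_inh_schedule, 2.0 * p.g_exc_schedule)
        assert p.cycle == 5000.0

    def test_invalid_protocols_rejected(self):
        with pytest.raises(ValueError):
            CurrentStepProtocol(increment=0.0)
        with pytest.raises(ValueError):
            CurrentStepProtocol(duration=1300.0)
        with pytest.raises(ValueError):
            KineticSweepSchedule("Kir", "vhalf", (0.0,))

    def test_published_sweep_grids(self):
        assert len(KIR_VHALF_GRID.grid) == 9
        assert KIR_VHALF_GRID.grid[0] == -91.0 and KIR_VHALF_GRID.grid[-1] == -75.0
        assert len(KIR_TAU_GRID.grid) == 9
        assert KIR_TAU_GRID.grid[0] == 10.0 and KIR_TAU_GRID.grid[-1] == 130.0
        assert D_TAU_GRID.grid[0] == 2.0 and D_TAU_GRID.grid[-1] == 18.0
        assert D_VHALF_GRID.couple_inactivation and D_TAU_GRID.couple_inactivation


class TestProtocolExecution:
    def test_passive_cell_never_spikes(self, passive_cell):
        # stay below the spike-detection voltage: a 500 MOhm passive cell
        # driven to +200 pA would trivially cross it by charging alone
        rec = run_static_protocol(passive_cell, CurrentStepProtocol(
            start=-160.0, increment=60.0, stop=80.0))
        assert all(len(t) == 0 for t in rec.meta["spike_times"])

    def test_dynamic_protocol_deterministic_and_silent_at_zero_g(
        self, canonical, drive
    ):
        r1 = run_dynamic_protocol(canonical["stuttering"], drive)
        r2 = run_dynamic_protocol(canonical["stuttering"], drive)
        assert np.array_equal(r1.sweeps, r2.sweeps)
        assert len(r1.meta["spike_times"][0]) == 0  # g = 0 sweep

    def test_waveform_shorter_than_on_phase_rejected(self):
        from vclamp.populations import generate_presynaptic_waveform

        p = SynapticBombardmentProtocol()
        short = generate_presynaptic_waveform(10.0, 100.0, seed=0)
        with pytest.raises(ValueError):
            make_bombardment_drive(p, seed=1, waveforms=(short, short))


class TestVirtualPharmacology:
    def test_block_zeroes_conductance_and_preserves_original(self, canonical):
        m = canonical["delayed"]
        g0 = m.current("Kir").g_total
        blocked = block_current(m, "Kir")
        assert blocked.current("Kir").g_total == 0.0
        assert m.current("Kir").g_total == g0

    def test_block_unknown_current_rejected(self, canonical):
        with pytest.raises(KeyError):
            block_current(canonical["regular"], "Kir")

    def test_blocking_zero_conductance_is_identity_in_behavior(
        self, passive_cell, canonical, short_protocol
    ):
        m = canonical["delayed"]
        zero = block_current(m, "Kir")
        again = block_current(zero, "Kir")
        r1 = run_static_protocol(zero, short_protocol)
        r2 = run_static_protocol(again, short_protocol)
        assert np.array_equal(r1.sweeps, r2.sweeps)


class TestKineticManipulations:
    def test_midpoint_shift_sets_value_and_null_shift_is_identity(self, canonical):
        m = canonical["delayed"]
        shifted = shift_activation_midpoint(m, "Kir", -83.0)
        assert shifted.current("Kir").activation.V_half == -83.0
        same = shift_activation_midpoint(m, "Kir", m.current("Kir").activation.V_half)
        assert same == m

    def test_coupled_shift_preserves_window_overlap(self, canonical):
        m = canonical["stuttering"]
        d0 = m.current("D")
        gap0 = d0.activation.V_half - d0.inactivation.V_half
        shifted = shift_activation_midpoint(m, "D", d0.activation.V_half + 6.0,
                                            couple_inactivation=True)
        d1 = shifted.current("D")
        assert d1.activation.V_half - d1.inactivation.V_half == pytest.approx(gap0)

    def test_coupling_without_inactivation_rejected(self, canonical):
        with pytest.raises(ValueError):
            shift_activation_midpoint(canonical["delayed"], "Kir", -80.0,
                                      couple_inactivation=True)

    def test_tau_scaling_proportional_and_ratio_preserving(self, canonical):
        m = canonical["stuttering"]
        d0 = m.current("D")
        ratio0 = d0.inactivation.tau_max / d0.activation.tau_max
        scaled = scale_time_constants(m, "D", 2.0, couple_inactivation=True)
        d1 = scaled.current("D")
        assert d1.activation.tau_max == pytest.approx(2.0)
        assert d1.activation.tau_min / d1.activation.tau_max == pytest.approx(
            d0.activation.tau_min / d0.activation.tau_max
        )
        assert d1.inactivation.tau_max / d1.activation.tau_max == pytest.approx(ratio0)

    def test_unit_factor_is_identity(self, canonical):
        m = canonical["delayed"]
        same = scale_time_constants(m, "Kir", m.current("Kir").activation.tau_max)
        assert same == m


class TestTransitionDetector:
    def _curve(self, counts):
        from vclamp.features import IOCurve

        c = np.asarray(counts, dtype=int)
        return IOCurve(stimulus=np.arange(len(c)) * 5.0, counts=c,
                       latency=np.full(len(c), np.nan))

    def test_requires_sustained_close_spiking(self):
        curve = self._curve([0, 1, 1, 3, 3])
        spikes = [[], [10.0], [12.0], [10.0, 50.0, 90.0], [5.0, 30.0, 55.0]]
        assert repetitive_firing_transition(curve, spike_times=spikes) == 15.0

    def test_ignores_widely_spaced_spikes(self):
        curve = self._curve([0, 3])
        spikes = [[], [10.0, 250.0, 490.0]]  # ISIs >= 200 ms
        assert np.isnan(repetitive_firing_transition(curve, spike_times=spikes))


class TestPopulationRunner:
    def test_rows_and_identity_manipulation(self, canonical, drive, short_protocol):
        models = [canonical["regular"]]
        df = run_population_experiment(models, short_protocol, None,
                                       manipulation=lambda m: m)
        assert len(df) == 2
        base = df[df.condition == "baseline"].iloc[0]
        manip = df[df.condition == "manipulated"].iloc[0]
        assert base["static_count"] == manip["static_count"]

    def test_empty_population_rejected(self, short_protocol):
        with pytest.raises(ValueError):
            run_population_experiment([], short_protocol, None)
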