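"""Population sampling, presynaptic waveforms and the LIF control model."""

import math

import numpy as np
import pytest
from scipy import stats

import vclamp as vc
from vclamp.populations import (
    LIFModel,
    PhenotypeDistribution,
    canonical_model,
    default_distribution,
    generate_presynaptic_waveform,
    lif_simulate,
    read_waveform_ascii,
    sample_lif_population,
    sample_population,
    write_waveform_ascii,
)


class TestCanonicalModels:
    def test_phenotype_current_complement(self):
        delayed = canonical_model("delayed")
        stut = canonical_model("stuttering")
        reg = canonical_model("regular")
        assert "Kir" in delayed.current_names()
        assert "D" in stut.current_names()
        assert "h" in reg.current_names() and "h" in stut.current_names()
        assert "h" not in delayed.current_names()
        assert "Kir" not in reg.current_names() and "D" not in reg.current_names()

    def test_deterministic_construction(self):
        assert canonical_model("stuttering") == canonical_model("stuttering")

    def test_unknown_phenotype_rejected(self):
        with pytest.raises(ValueError):
            canonical_model("bursting")


class TestSamplePopulation:
    def test_population_size(self):
        pop = sample_population(default_distribution("regular"), 7, seed=3)
        assert len(pop) == 7

    def test_zero_sd_collapses_to_canonical(self):
        dist = PhenotypeDistribution(
            phenotype="delayed",
            conductance_sd={},
            C_rel_sd=0.0, E_leak_sd=0.0, coupling_rel_sd=0.0,
        )
        pop = sample_population(dist, 3, seed=0)
        assert all(m == canonical_model("delayed") for m in pop)

    def test_seeded_reproducibility(self):
        d = default_distribution("stuttering")
        assert sample_population(d, 5, seed=11) == sample_population(d, 5, seed=11)
        assert sample_population(d, 5, seed=11) != sample_population(d, 5, seed=12)

    def test_sample_means_approach_table_means(self):
        """Law of large numbers on the drawn Na conductance and capacitance."""
        d = default_distribution("regular")
        pop = sample_population(d, 4000, seed=5)
        base = canonical_model("regular")
        na = np.array([m.current("Na").g_total for m in pop])
        se = d.conductance_sd["Na"] / math.sqrt(len(pop))
        assert abs(na.mean() - base.current("Na").g_total) < 4 * se
        cf = np.array([m.C[0] for m in pop]) / base.C[0]
        assert abs(cf.mean() - 1.0) < 4 * d.C_rel_sd / math.sqrt(len(pop)) + 5e-3

    def test_nonnegative_parameters(self):
        d = default_distribution("stuttering")
        for m in sample_population(d, 50, seed=9):
            assert all(c.g_total >= 0 for c in m.currents)
            assert m.g_sx >= 0 and m.g_sd >= 0


class TestPresynapticWaveform:
    def test_zero_rate_is_flat_baseline(self):
        wf = generate_presynaptic_waveform(0.0, 500.0, seed=1)
        assert np.all(wf.V == wf.baseline)

    def test_same_seed_bit_identical(self):
        a = generate_presynaptic_waveform(40.0, 1000.0, seed=7)
        b = generate_presynaptic_waveform(40.0, 1000.0, seed=7)
        assert np.array_equal(a.V, b.V)

    def test_pulses_exceed_synaptic_threshold(self):
        wf = generate_presynaptic_waveform(40.0, 1000.0, seed=2)
        assert wf.V.max() == wf.peak > -20.0
        assert wf.baseline < -20.0

    def test_event_counts_are_poisson(self):
        """Chi-square goodness of fit of per-waveform event counts."""
        rate, dur = 10.0, 2000.0
        lam = rate * dur / 1000.0
        counts = []
        for seed in range(400):
            wf = generate_presynaptic_waveform(rate, dur, dt=0.05, seed=seed,
                                               pulse_width=0.05)
            # count rising edges
            up = (wf.V[1:] == wf.peak) & (wf.V[:-1] != wf.peak)
            counts.append(int(up.sum()))
        counts = np.array(counts)
        # bin tails so expected counts stay >= 5
        edges = [0, 15, 17, 19, 21, 23, 25, 100]
        obs = np.histogram(counts, bins=edges)[0]
        probs = []
        for lo, hi in zip(edges[:-1], edges[1:]):
            probs.append(stats.poisson.cdf(hi - 1, lam) - stats.poisson.cdf(lo - 1, lam))
        exp = np.array(probs) * len(counts)
        chi2 = np.sum((obs - exp) ** 2 / exp)
        p = 1 - stats.chi2.cdf(chi2, df=len(obs) - 1)
        assert p > 0.01

    def test_subsample_pulse_width_rejected(self):
        with pytest.raises(ValueError):
            generate_presynaptic_waveform(10.0, 100.0, dt=0.1, seed=0,
                                          pulse_width=0.01)

    def test_ascii_round_trip(self, tmp_path):
        wf = generate_presynaptic_waveform(30.0, 200.0, seed=4)
        path = tmp_path / "wave.txt"
        write_waveform_ascii(wf, path)
        back = read_waveform_ascii(path)
        assert back.dt == wf.dt and back.rate == wf.rate and back.seed == wf.seed
        assert np.allclose(back.V, wf.V, atol=1e-4)


class TestLIF:
    def test_threshold_above_reset_enforced(self):
        with pytest.raises(ValueError):
            LIFModel(V_threshold=-60.0, V_reset=-55.0)
        for m in sample_lif_population(100, seed=3):
            assert m.V_threshold > m.V_reset

    def test_zero_cv_population_is_identical(self):
        pop = sample_lif_population(5, seed=1, C_rel_sd=0.0, g_rel_sd=0.0,
                                    E_leak_sd=0.0, V_th_sd=0.0)
        assert all(m == pop[0] for m in pop)

    def test_subthreshold_current_never_spikes(self):
        m = LIFModel()
        # steady state E_L + I/g below threshold
        I = 0.9 * m.g_leak * (m.V_threshold - m.E_leak)
        rec = lif_simulate(m, [I], sweep_duration=2000.0, stim_on=100.0,
                           stim_off=1900.0)
        assert rec.meta["spike_counts"][0] == 0

    def test_zero_input_rests_at_leak_reversal(self):
        m = LIFModel()
        rec = lif_simulate(m, [0.0], sweep_duration=500.0, stim_on=0.0, stim_off=0.0)
        assert rec.sweeps[0][-1] == pytest.approx(m.E_leak, abs=1e-9)

    def test_suprathreshold_isi_matches_closed_form(self):
        m = LIFModel(C=60.0, g_leak=3.0, E_leak=-65.0, V_threshold=-45.0,
                     V_reset=-60.0, t_refractory=3.0)
        I = 120.0
        rec = lif_simulate(m, [I], sweep_duration=3000.0, stim_on=0.0,
                           stim_off=3000.0, dt=0.005)
        times = rec.meta["spike_times"][0]
        isi = np.diff(times)
        tau = m.C / m.g_leak
        T = m.t_refractory + tau * math.log(
            (I / m.g_leak - (m.V_reset - m.E_leak))
            / (I / m.g_leak - (m.V_threshold - m.E_leak))
        )
        assert np.allclose(isi[2:], T, rtol=0.01)


def test_population_manifest_lists_all_sampled_parameters():
    from vclamp.populations import population_manifest

    pop = sample_population(default_distribution("delayed"), 4, seed=8)
    df = population_manifest(pop, seed=8)
    assert len(df) == 4
    assert "g_Kir_nS" in df.columns and "C_soma_pF" in df.columns
    assert df["g_Kir_nS"].tolist() == [m.current("Kir").g_total for m in pop]
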