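"""Tests for the seeded simulators."""

import math

import numpy as np
import pytest

from audiomech import de_subsets, spectra, synthetic, sweeps, transducer
from audiomech.constants import BOLTZMANN, DEFAULT_TEMPERATURE


class TestOscillatorParams:
    def test_from_resonance_round_trip(self):
        p = synthetic.OscillatorParams.from_resonance(337.52, 0.69, 7.745e-11)
        assert p.natural_frequency_hz == pytest.approx(337.52, rel=1e-12)
        assert p.quality_factor == pytest.approx(0.69, rel=1e-12)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(mass_kg=-1e-11, stiffness_n_per_m=1e-4, damping_ns_per_m=1e-7),
            dict(mass_kg=1e-11, stiffness_n_per_m=0.0, damping_ns_per_m=1e-7),
            dict(mass_kg=1e-11, stiffness_n_per_m=1e-4, damping_ns_per_m=-1e-7),
            dict(
                mass_kg=1e-11,
                stiffness_n_per_m=1e-4,
                damping_ns_per_m=1e-7,
                temperature_k=-1.0,
            ),
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            synthetic.OscillatorParams(**kwargs)


class TestFreeFluctuation:
    def test_zero_temperature_ringdown(self):
        # noise-free limit: deterministic decay at f0 * sqrt(1 - 1/(4 Q^2))
        q = 12.0
        f0 = 300.0
        p = synthetic.OscillatorParams.from_resonance(
            f0, q, 7.745e-11, temperature_k=0.0
        )
        dt = 1e-5
        t, x, v = synthetic.langevin_trajectory(p, 0.5, dt, seed=0, x0=1e-8, v0=0.0)
        # ringdown frequency from zero-crossing spacing
        signs = np.sign(x)
        crossings = np.where(np.diff(signs) != 0)[0]
        periods = 2.0 * np.diff(crossings * dt)
        f_measured = 1.0 / np.mean(periods)
        f_expected = f0 * math.sqrt(1.0 - 1.0 / (4.0 * q**2))
        assert f_measured == pytest.approx(f_expected, rel=1e-3)
        # envelope decays monotonically
        from scipy.signal import find_peaks

        peaks, _ = find_peaks(np.abs(x))
        env = np.abs(x)[peaks]
        assert np.all(np.diff(env) < 0)

    def test_equipartition_variance(self):
        # f0/Q from the female active row; variance of x vs k_B T / k
        p = synthetic.OscillatorParams.from_resonance(220.03, 1.19, 7.745e-11)
        _, x, _ = synthetic.langevin_trajectory(p, 10.0, 2e-5, seed=42)
        expected = BOLTZMANN * DEFAULT_TEMPERATURE / p.stiffness_n_per_m
        assert x.var() == pytest.approx(expected, rel=0.10)

    def test_seeded_determinism(self):
        p = synthetic.OscillatorParams.from_resonance(300.0, 2.0, 7.745e-11)
        a = synthetic.simulate_free_fluctuation(p, 0.5, 2e-5, seed=7)
        b = synthetic.simulate_free_fluctuation(p, 0.5, 2e-5, seed=7)
        assert np.array_equal(a.samples, b.samples)
        c = synthetic.simulate_free_fluctuation(p, 0.5, 2e-5, seed=8)
        assert not np.array_equal(a.samples, c.samples)

    def test_unstable_dt_rejected_with_hint(self):
        p = synthetic.OscillatorParams.from_resonance(500.0, 2.0, 7.745e-11)
        with pytest.raises(ValueError, match="1/\\(20 f0\\)"):
            synthetic.simulate_free_fluctuation(p, 1.0, 1e-3, seed=0)

    @pytest.mark.parametrize("duration,dt", [(0.0, 1e-5), (1.0, -1e-5)])
    def test_nonpositive_inputs_rejected(self, duration, dt):
        p = synthetic.OscillatorParams.from_resonance(300.0, 2.0, 7.745e-11)
        with pytest.raises(ValueError):
            synthetic.simulate_free_fluctuation(p, duration, dt, seed=0)

    def test_fluctuation_dissipation_consistency(self):
        # doubling gamma at fixed k, m, T leaves <x^2> unchanged, halves Q
        base = synthetic.OscillatorParams.from_resonance(300.0, 4.0, 7.745e-11)
        doubled = synthetic.OscillatorParams(
            mass_kg=base.mass_kg,
            stiffness_n_per_m=base.stiffness_n_per_m,
            damping_ns_per_m=2.0 * base.damping_ns_per_m,
        )
        assert doubled.quality_factor == pytest.approx(
            base.quality_factor / 2.0, rel=1e-12
        )
        var_base = []
        var_doubled = []
        q_doubled = []
        for seed in range(8):
            _, xb, _ = synthetic.langevin_trajectory(base, 8.0, 2e-5, seed=seed)
            _, xd, _ = synthetic.langevin_trajectory(doubled, 8.0, 2e-5, seed=seed + 100)
            var_base.append(xb.var())
            var_doubled.append(xd.var())
            tr = synthetic.simulate_free_fluctuation(doubled, 8.0, 2e-5, seed=seed + 100)
            fit = spectra.fit_oscillator(spectra.compute_spectrum(tr))
            q_doubled.append(fit.quality_factor)
        assert np.median(var_doubled) == pytest.approx(np.median(var_base), rel=0.15)
        assert np.median(q_doubled) == pytest.approx(base.quality_factor / 2.0, rel=0.25)

    def test_active_boost_raises_variance(self):
        p0 = synthetic.OscillatorParams.from_resonance(300.0, 2.0, 7.745e-11)
        p1 = synthetic.OscillatorParams.from_resonance(
            300.0, 2.0, 7.745e-11, active_boost=3.0
        )
        _, x0, _ = synthetic.langevin_trajectory(p0, 5.0, 2e-5, seed=3)
        _, x1, _ = synthetic.langevin_trajectory(p1, 5.0, 2e-5, seed=3)
        assert x1.var() == pytest.approx(4.0 * x0.var(), rel=0.2)

    def test_sso_superposes_limit_cycle(self):
        sso = synthetic.SsoMode(amplitude_m=5e-8, frequency_hz=352.79)
        p = synthetic.OscillatorParams.from_resonance(
            303.55, 1.36, 1.229e-10, sso=sso
        )
        trace = synthetic.simulate_free_fluctuation(p, 2.0, 2e-5, seed=9)
        assert trace.oscillation_label == "SSO"
        assert trace.state_label == "active"
        # the limit cycle dominates: velocity RMS near the deterministic value
        expected_rms = sso.amplitude_m * 2 * math.pi * sso.frequency_hz / math.sqrt(2)
        assert np.std(trace.samples) == pytest.approx(expected_rms, rel=0.2)

    def test_state_labels(self):
        p = synthetic.OscillatorParams.from_resonance(300.0, 2.0, 7.745e-11)
        assert synthetic.simulate_free_fluctuation(p, 0.2, 2e-5, seed=0).state_label == "passive"
        pa = synthetic.OscillatorParams.from_resonance(
            300.0, 2.0, 7.745e-11, active_boost=1.0
        )
        tr = synthetic.simulate_free_fluctuation(pa, 0.2, 2e-5, seed=0)
        assert tr.state_label == "active"
        assert tr.oscillation_label == "quiescent"


class TestSweepTrial:
    def test_null_stimulus_is_pure_noise(self):
        p = synthetic.OscillatorParams.from_resonance(445.0, 2.0, 7.745e-11)
        stim = sweeps.SweepStimulus(amplitude=0.0)
        trial = synthetic.simulate_sweep_trial(p, stim, noise_level=0.3, seed=1)
        assert trial.displacement.std() == pytest.approx(0.3, rel=0.1)
        assert abs(trial.displacement.mean()) < 0.05

    def test_seeded_determinism(self):
        p = synthetic.OscillatorParams.from_resonance(445.0, 2.0, 7.745e-11)
        stim = sweeps.SweepStimulus(amplitude=1.0)
        a = synthetic.simulate_sweep_trial(p, stim, noise_level=0.02, seed=5)
        b = synthetic.simulate_sweep_trial(p, stim, noise_level=0.02, seed=5)
        assert np.array_equal(a.displacement, b.displacement)
        assert np.array_equal(a.cap, b.cap)

    def test_noise_free_envelope_peak_at_planted_resonance(self):
        q = 2.15
        f_peak = 445.0
        f0 = f_peak / math.sqrt(1.0 - 1.0 / (2.0 * q**2))
        p = synthetic.OscillatorParams.from_resonance(f0, q, 7.745e-11)
        stim = sweeps.SweepStimulus(amplitude=1.0)
        trial = synthetic.simulate_sweep_trial(p, stim, noise_level=0.0, seed=0)
        t = np.arange(trial.displacement.size) * trial.dt
        # envelope of the analytic response peaks where f(t) = planted resonance
        env_peak_t = t[int(np.argmax(np.abs(trial.displacement)))]
        f_at_peak = stim.frequency_at(env_peak_t)
        assert f_at_peak == pytest.approx(trial.truth["mechanical_bf_hz"], abs=5.0)

    def test_stimulus_above_nyquist_rejected(self):
        p = synthetic.OscillatorParams.from_resonance(445.0, 2.0, 7.745e-11)
        stim = sweeps.SweepStimulus(f_end_hz=9000.0)
        with pytest.raises(ValueError, match="Nyquist"):
            synthetic.simulate_sweep_trial(p, stim, dt=1e-4, seed=0)


class TestGatingExperiment:
    @pytest.fixture
    def truth(self):
        return transducer.GatingFit(
            n_transducers=1000,
            gating_force_n=1e-14,
            set_point_m=0.0,
            asymptotic_stiffness_n_per_m=1e-5,
        )

    def test_noise_free_points_on_model_curve(self, truth):
        exp = synthetic.simulate_gating_experiment(truth, displacement_noise=0.0, seed=0)
        predicted = transducer.gating_force_model(truth, exp.displacements)
        np.testing.assert_allclose(predicted, exp.forces, rtol=1e-7)

    def test_step_count_twenty_per_sign(self, truth):
        exp = synthetic.simulate_gating_experiment(truth, n_steps=20, seed=0)
        assert exp.forces.size == 40
        assert (exp.forces < 0).sum() == 20
        assert (exp.forces > 0).sum() == 20

    def test_force_magnitudes_log_spaced_and_monotone(self, truth):
        exp = synthetic.simulate_gating_experiment(truth, seed=0)
        pos = exp.forces[exp.forces > 0]
        ratios = pos[1:] / pos[:-1]
        assert np.allclose(ratios, ratios[0], rtol=1e-9)
        assert np.all(np.diff(pos) > 0)

    def test_negative_noise_rejected(self, truth):
        with pytest.raises(ValueError):
            synthetic.simulate_gating_experiment(truth, displacement_noise=-0.1, seed=0)

    def test_seeded_determinism(self, truth):
        a = synthetic.simulate_gating_experiment(truth, displacement_noise=0.01, seed=3)
        b = synthetic.simulate_gating_experiment(truth, displacement_noise=0.01, seed=3)
        assert np.array_equal(a.displacements, b.displacements)


class TestDETables:
    def test_planted_counts_recovered_exactly(self):
        params = synthetic.DESimParams(n_genes=5000, n_full_recovery=100,
                                       n_male_independent=50, n_partial_recovery=25,
                                       n_mvf_only=200, n_female_up=75, seed=1)
        tables = synthetic.simulate_de_tables(params)
        counts = de_subsets.subset_counts(
            de_subsets.classify_subsets(tables.mvf, tables.ivf, tables.mvi)
        )
        assert counts["full_recovery"] == 100
        assert counts["male_independent"] == 50
        assert counts["partial_recovery"] == 25
        assert counts["mvf_only"] == 200

    def test_truth_labels_match_planted_sizes(self):
        params = synthetic.DESimParams(n_genes=3000, n_full_recovery=10,
                                       n_male_independent=20, n_partial_recovery=30,
                                       n_mvf_only=40, seed=2)
        tables = synthetic.simulate_de_tables(params)
        vc = tables.truth.value_counts()
        assert vc[de_subsets.LABEL_FULL] == 10
        assert vc[de_subsets.LABEL_MVF_ONLY] == 40

    def test_seeded_determinism(self):
        params = synthetic.DESimParams(n_genes=2000, seed=9)
        a = synthetic.simulate_de_tables(params)
        b = synthetic.simulate_de_tables(params)
        for ta, tb in ((a.mvf, b.mvf), (a.ivf, b.ivf), (a.mvi, b.mvi)):
            assert ta.equals(tb)

    def test_oversized_subsets_rejected(self):
        with pytest.raises(ValueError):
            synthetic.DESimParams(n_genes=100, n_full_recovery=632)

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValueError):
            synthetic.DESimParams(n_genes=5000, fdr_threshold=1.5)


class TestSensitivityCurve:
    def test_planted_gain_exact_without_noise(self):
        intensities, sens, truth = synthetic.simulate_sensitivity_curve(13.95, noise=0.0)
        assert sens[-1] / sens[0] == pytest.approx(13.95, rel=1e-9)
        assert truth["gain"] == 13.95

    def test_gain_one_is_flat(self):
        _, sens, _ = synthetic.simulate_sensitivity_curve(1.0, noise=0.0)
        assert np.ptp(sens) == 0.0

    def test_unreachable_gain_rejected(self):
        with pytest.raises(ValueError):
            synthetic.simulate_sensitivity_curve(1e9)
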