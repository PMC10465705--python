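"""Rupture-time extraction: sigmoid fits and the distance heuristic."""

import numpy as np
import pytest

from dsbkinetics.detection import (DetectorSettings, SigmoidTransitionFit,
                                   analyze_replica, estimate_delta_U,
                                   fit_sigmoid, moving_average,
                                   rupture_time_heuristic)
from dsbkinetics.mechanics import ScenarioConfig
from dsbkinetics.synthetic import (DistanceTrace, EnergyTrace,
                                   GeneratorParams, generate_distance_trace,
                                   generate_energy_trace, sigmoid_mean_path)


def make_energy_trace(E_min=0.0, E_max=16.0, m=0.05, t50=500.0,
                      duration=1000.0, dt=0.1, noise_sigma=0.0, seed=0):
    gp = GeneratorParams(E_min=E_min, E_max=E_max, m_true=m,
                         noise_sigma=noise_sigma, duration=duration, dt=dt)
    return generate_energy_trace(ScenarioConfig(b_d=0), t50, gp,
                                 np.random.default_rng(seed))


class TestMovingAverage:
    def test_window_one_is_identity(self):
        x = np.array([3.0, 1.0, 4.0, 1.0, 5.0])
        np.testing.assert_array_equal(moving_average(x, 1), x)

    def test_constant_series_preserved(self):
        x = np.full(20, 7.0)
        np.testing.assert_allclose(moving_average(x, 5), x)

    def test_truncated_edges(self):
        out = moving_average(np.array([1.0, 2, 3, 4, 5]), 3)
        np.testing.assert_allclose(out, [1.5, 2, 3, 4, 4.5])

    @pytest.mark.parametrize("window", [2, 0, 99])
    def test_rejects_bad_windows(self, window):
        with pytest.raises(ValueError):
            moving_average(np.arange(10, dtype=float), window)


class TestSigmoidFit:
    def test_noiseless_inversion_to_machine_tolerance(self):
        tr = make_energy_trace()
        fit = fit_sigmoid(tr, smoothing_window=1)
        assert fit.converged
        assert fit.E_min == pytest.approx(0.0, abs=1e-6 * 16)
        assert fit.E_max == pytest.approx(16.0, rel=1e-6)
        assert fit.m == pytest.approx(0.05, rel=1e-6)
        assert fit.t50 == pytest.approx(500.0, rel=1e-6)

    def test_flat_noisy_trace_is_censored(self):
        rng = np.random.default_rng(11)
        t = np.arange(1000) * 0.1
        tr = EnergyTrace(times=t, energies=rng.normal(0, 2, size=1000))
        fit = fit_sigmoid(tr)
        assert not fit.converged

    def test_t50_coverage_on_noisy_traces(self):
        """3-s.e. interval around the fitted t50 covers the truth in the
        vast majority of noisy replicas (noise s.d. 2 kT, 1e4 samples)."""
        hits = 0
        n_seeds = 40
        for seed in range(n_seeds):
            tr = make_energy_trace(noise_sigma=2.0, seed=seed)
            fit = fit_sigmoid(tr)
            assert fit.converged
            se = np.sqrt(fit.pcov[3, 3])
            hits += abs(fit.t50 - 500.0) <= 3 * se
        assert hits >= 35

    def test_t50_invariant_under_time_translation(self):
        tr = make_energy_trace(noise_sigma=1.0, seed=3)
        fit = fit_sigmoid(tr)
        shifted = EnergyTrace(times=tr.times + 123.0, energies=tr.energies)
        fit2 = fit_sigmoid(shifted)
        assert fit2.t50 - fit.t50 == pytest.approx(123.0, abs=1e-6)

    def test_smoothing_window_stability_on_noiseless_trace(self):
        tr = make_energy_trace()
        dt = tr.times[1] - tr.times[0]
        t50s = [fit_sigmoid(tr, smoothing_window=w).t50
                for w in (1, 5, 11, 21)]
        assert max(t50s) - min(t50s) < 21 * dt

    def test_estimator_api(self):
        tr = make_energy_trace()
        est = SigmoidTransitionFit(smoothing_window=1)
        assert est.get_params()["smoothing_window"] == 1
        est.fit(tr.times, tr.energies)
        pred = est.predict(tr.times)
        np.testing.assert_allclose(pred, tr.energies, atol=1e-6)
        with pytest.raises(ValueError):
            est.fit(tr.times[:10], tr.energies[:10])   # too short


class TestDeltaU:
    def test_midpoint_arithmetic(self):
        tr = make_energy_trace()
        fit = fit_sigmoid(tr, smoothing_window=1)
        assert estimate_delta_U(fit) == pytest.approx(8.0, rel=1e-6)

    def test_translation_invariance(self):
        for E_min, amp in [(5.0, 2.0), (-3.4, 27.0)]:
            tr = make_energy_trace(E_min=E_min, E_max=E_min + 2 * amp)
            fit = fit_sigmoid(tr, smoothing_window=1)
            assert estimate_delta_U(fit) == pytest.approx(amp, rel=1e-6)

    def test_scales_linearly_with_energy(self):
        tr = make_energy_trace()
        scaled = EnergyTrace(times=tr.times, energies=3.0 * tr.energies)
        f1 = fit_sigmoid(tr, smoothing_window=1)
        f2 = fit_sigmoid(scaled, smoothing_window=1)
        assert estimate_delta_U(f2) == pytest.approx(
            3.0 * estimate_delta_U(f1), rel=1e-6)

    def test_unconverged_fit_rejected(self):
        rng = np.random.default_rng(1)
        t = np.arange(1000) * 0.1
        fit = fit_sigmoid(EnergyTrace(times=t,
                                      energies=rng.normal(size=1000)))
        with pytest.raises(ValueError):
            estimate_delta_U(fit)

    def test_smoothed_data_reading_close_to_analytic(self):
        tr = make_energy_trace(noise_sigma=1.0, seed=9)
        fit = fit_sigmoid(tr)
        analytic = estimate_delta_U(fit)
        smoothed = estimate_delta_U(fit, tr, from_smoothed=True)
        assert smoothed == pytest.approx(analytic, rel=0.2)


class TestDistanceHeuristic:
    def test_noiseless_ramp_onset_within_one_frame(self):
        gp = GeneratorParams(d_noise_sigma=0, duration=100.0, dt=0.1)
        tr = generate_distance_trace(ScenarioConfig(b_d=0), 50.0, gp,
                                     np.random.default_rng(0))
        tau = rupture_time_heuristic(tr)
        assert tau == pytest.approx(50.0, abs=2 * 0.1)

    def test_trace_below_threshold_is_censored(self):
        t = np.arange(1000) * 0.1
        d = np.full(1000, 1.0)
        tr = DistanceTrace(times=t, min_distance=d)
        assert rupture_time_heuristic(tr, threshold=5.0) is None

    def test_flat_noisy_trace_is_censored_with_auto_threshold(self):
        rng = np.random.default_rng(17)
        t = np.arange(2000) * 0.1
        d = np.clip(1.0 + 0.15 * rng.normal(size=2000), 0, None)
        assert rupture_time_heuristic(DistanceTrace(times=t,
                                                    min_distance=d)) is None

    def test_short_spike_ignored_by_persistence(self):
        t = np.arange(1000) * 0.1
        d = np.full(1000, 1.0)
        d[200:203] = 50.0                      # 3-frame excursion
        d[600:] = 1.0 + 2.0 * (t[600:] - 60.)  # real rupture ramp
        tr = DistanceTrace(times=t, min_distance=d)
        # ramp 1 + 2 (t - 60) crosses the 5.0 threshold at t = 62
        tau = rupture_time_heuristic(tr, threshold=5.0, persistence=10)
        assert tau == pytest.approx(62.0, abs=0.2)

    def test_rejects_bad_parameters(self):
        t = np.arange(100) * 0.1
        tr = DistanceTrace(times=t, min_distance=np.ones(100))
        with pytest.raises(ValueError):
            rupture_time_heuristic(tr, persistence=0)
        with pytest.raises(ValueError):
            rupture_time_heuristic(tr, threshold=-1.0)


class TestAnalyzeReplica:
    def test_paired_noiseless_traces_agree_within_one_frame(self):
        sc = ScenarioConfig(b_d=0)
        gp = GeneratorParams(noise_sigma=0, d_noise_sigma=0,
                             duration=100.0, dt=0.1)
        rng = np.random.default_rng(0)
        e = generate_energy_trace(sc, 50.0, gp, rng)
        d = generate_distance_trace(sc, 50.0, gp, rng)
        ev = analyze_replica(e, d,
                             DetectorSettings(smoothing_window=1))
        assert not ev.censored
        assert ev.tau == pytest.approx(50.0, abs=1e-3)
        assert ev.agreement is not None
        assert ev.agreement <= 2 * 0.1 / 100.0

    def test_energy_only_input_flags_missing_channel(self):
        e = make_energy_trace(noise_sigma=1.0, seed=2)
        ev = analyze_replica(e, None)
        assert ev.tau is not None
        assert ev.tau_heuristic is None
        assert ev.agreement is None

    def test_mismatched_time_bases_rejected(self):
        e = make_energy_trace()
        t = np.arange(50) * 1.0
        d = DistanceTrace(times=t, min_distance=np.ones(50))
        with pytest.raises(ValueError):
            analyze_replica(e, d)

    def test_median_criterion_agreement_below_2pct_of_span(
            self, mixed_ensemble):
        """The sigmoid flex and the distance criterion frame the same
        event: median |tau - tau_heuristic| stays below 2% of the trace
        span across a mixed noisy ensemble."""
        _, _, traces = mixed_ensemble
        ags = [analyze_replica(e, d).agreement for e, d in traces]
        ags = [a for a in ags if a is not None]
        assert len(ags) > 100
        assert np.median(ags) < 0.02
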