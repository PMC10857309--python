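"""The oddball/gaze simulator: design counts, kernel shape, noise model."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cogvergence import (
    ResponseKernel,
    SimulationParams,
    TrackerSpec,
    build_epochs,
    exclusion_rate,
    generate_paradigm,
    kernel_curve,
    simulate_cohort,
    simulate_subject,
    write_cohort,
)
from cogvergence.errors import ParameterError
from cogvergence.pipeline import AnalysisConfig, curves_for_recording
from cogvergence.window_stats import WindowDefinition, subject_modulation_index, window_mean


class TestParadigm:
    @pytest.mark.parametrize("seed", [0, 1, 42])
    def test_default_design_counts(self, seed):
        log = generate_paradigm(seed=seed)
        assert len(log) == 100
        assert log.n_targets == 20
        assert log.n_distractors == 80

    def test_small_session_forced_count(self):
        log = generate_paradigm(n_trials=5, p_target=0.2, seed=0)
        assert log.n_targets == 1

    def test_seeding_contract(self):
        a = generate_paradigm(seed=5)
        b = generate_paradigm(seed=5)
        c = generate_paradigm(seed=6)
        pd.testing.assert_frame_equal(a.trials, b.trials)
        assert not a.trials["condition"].equals(c.trials["condition"])
        assert c.n_targets == 20  # counts invariant across seeds

    def test_trial_cadence_and_strings(self):
        log = generate_paradigm(mask_ms=2000.0, stim_ms=2000.0, seed=2)
        onsets = log.trials["stimulus_onset"].to_numpy()
        assert np.all(np.diff(onsets) == 4000.0)
        assert (log.trials["stimulus_onset"]
                == log.trials["mask_onset"] + 2000.0).all()
        assert log.trials["stimulus_string"].str.len().eq(11).all()
        assert log.trials["stimulus_string"].str.fullmatch("[A-Za-z]+").all()

    def test_invalid_p_target_rejected(self):
        with pytest.raises(ParameterError):
            generate_paradigm(p_target=1.5)


class TestKernel:
    def test_zero_amplitude_kernel_is_flat(self):
        k = ResponseKernel(peak_amp=0.0, delay_amp=0.0)
        t = np.linspace(-200, 2000, 500)
        assert np.all(kernel_curve(k, t) == 0.0)

    def test_shape_landmarks(self):
        k = ResponseKernel(latency=300, peak_time=450, peak_amp=0.3, delay_amp=0.12)
        t = np.linspace(-200, 2000, 2201)
        y = kernel_curve(k, t)
        assert np.all(y[t < 300] == 0.0)
        assert y[np.searchsorted(t, 450.0)] == pytest.approx(0.3, abs=1e-9)
        assert np.max(y) == pytest.approx(0.3, abs=1e-9)
        # sustained component dominates the 600-1250 ms span
        sustain = y[(t >= 700) & (t <= 1250)]
        assert np.all(sustain > 0.5 * 0.12)

    def test_continuity(self):
        k = ResponseKernel()
        t = np.linspace(0, 2000, 40001)
        y = kernel_curve(k, t)
        assert np.max(np.abs(np.diff(y))) < 0.01  # no jumps at piece boundaries

    def test_invalid_kernel_rejected(self):
        with pytest.raises(ParameterError):
            ResponseKernel(latency=500, peak_time=450)


class TestSimulateSubject:
    def test_noiseless_geometry_round_trip(self, geometry):
        params = SimulationParams(
            n_subjects=1, subject_sd=0.0,
            target_kernel=ResponseKernel(peak_amp=0.0, delay_amp=0.0),
            distractor_kernel=ResponseKernel(peak_amp=0.0, delay_amp=0.0),
            trackers={"ET": TrackerSpec(noise_sd=0.0, dropout_prob=0.0)})
        rec, events = simulate_subject(params, "s1", "ET", geometry, seed=0)
        from cogvergence.vergence import gamma_from_gaze, symmetric_fixation_gamma
        gamma = gamma_from_gaze(rec.samples["left_x"].to_numpy(),
                                rec.samples["right_x"].to_numpy(), geometry)
        expected = symmetric_fixation_gamma(geometry.viewing_distance, geometry.ipd)
        np.testing.assert_allclose(gamma, expected, atol=1e-9)

    def test_no_dropout_means_no_invalid_samples(self, noiseless_params, geometry):
        rec, _ = simulate_subject(noiseless_params, "s1", "ET", geometry, seed=1)
        assert (rec.samples[["valid_left", "valid_right"]] == 0).all().all()

    def test_unknown_tracker_rejected(self, noiseless_params, geometry):
        with pytest.raises(ParameterError, match="XX"):
            simulate_subject(noiseless_params, "s1", "XX", geometry, seed=1)

    def test_event_locked_response_peaks_near_peak_time(
            self, noiseless_params, geometry):
        rec, events = simulate_subject(noiseless_params, "s1", "ET", geometry, seed=4)
        cfg = AnalysisConfig(trackers=("ET",))
        curves, _ = curves_for_recording(rec, events, cfg)
        avg = [c for c in curves if c.condition == "target"]
        mean_v = np.mean([c.v for c in avg], axis=0)
        t = avg[0].t_rel
        t_peak = t[np.argmax(mean_v)]
        assert 400.0 <= t_peak <= 500.0  # kernel peak at 450 ms

    def test_exclusion_rate_matches_binomial_oracle(self, geometry):
        """Empirical trial exclusion under per-sample dropout tracks the
        closed-form binomial tail over a whole cohort's worth of trials."""
        p_drop = 0.2
        params = SimulationParams(
            n_subjects=1, subject_sd=0.0,
            trackers={"ET": TrackerSpec(noise_sd=0.05, dropout_prob=p_drop)})
        rates, n_trials = [], 0
        for seed in range(10):  # 10 sessions x 100 trials
            rec, events = simulate_subject(params, "s", "ET", geometry, seed=seed)
            epochs = build_epochs(rec, events, geometry)
            rates.append(exclusion_rate(epochs))
            n_trials += len(epochs)
        n_epoch_samples = 66  # (-200, 2000) ms at 30 Hz
        expected = stats.binom.sf(14, n_epoch_samples, p_drop)
        observed = np.mean(rates)
        ci = 1.96 * np.sqrt(expected * (1 - expected) / n_trials)
        assert abs(observed - expected) < ci + 0.01


class TestCohort:
    def test_default_cohort_structure(self):
        params = SimulationParams(n_subjects=4, seed=1)
        cohort = simulate_cohort(params)
        assert len(cohort.subject_ids) == 4
        assert set(cohort.recordings) == {
            (s, t) for s in cohort.subject_ids for t in ("ET", "WC")}
        assert len(cohort.ground_truth) == 4
        assert all(len(cohort.events[s]) == 100 for s in cohort.subject_ids)

    def test_fixed_seed_reproduces_cohort_bitwise(self):
        params = SimulationParams(n_subjects=2, seed=11)
        a = simulate_cohort(params)
        b = simulate_cohort(SimulationParams(n_subjects=2, seed=11))
        for key in a.recordings:
            pd.testing.assert_frame_equal(a.recordings[key].samples,
                                          b.recordings[key].samples)
        pd.testing.assert_frame_equal(a.ground_truth, b.ground_truth)

    def test_trial_totals_scale_with_cohort(self):
        params = SimulationParams(n_subjects=28, seed=0)
        logs = [generate_paradigm(seed=s) for s in range(params.n_subjects)]
        assert sum(l.n_distractors for l in logs) == 2240
        assert sum(l.n_targets for l in logs) == 560

    def test_write_cohort_tree(self, tmp_path):
        params = SimulationParams(n_subjects=2, seed=5)
        out = write_cohort(simulate_cohort(params), tmp_path / "data")
        assert (out / "ground_truth.csv").exists()
        assert (out / "manifest.yaml").exists()
        for s in ("sub-01", "sub-02"):
            assert (out / s / "events.csv").exists()
            assert (out / s / "gaze_ET.csv").exists()
            assert (out / s / "gaze_WC.csv").exists()


class TestStatisticalStructure:
    def test_noise_increases_window_mean_spread(self, geometry):
        """Across-trial SD of window means grows monotonically with noise."""
        sds = []
        for noise in (0.02, 0.08, 0.3):
            params = SimulationParams(
                n_subjects=1, subject_sd=0.0,
                trackers={"ET": TrackerSpec(noise_sd=noise, dropout_prob=0.0)})
            rec, events = simulate_subject(params, "s", "ET", geometry, seed=77)
            cfg = AnalysisConfig(trackers=("ET",))
            curves, _ = curves_for_recording(rec, events, cfg)
            win = WindowDefinition().mi_window
            vals = [window_mean(c, win) for c in curves if c.condition == "distractor"]
            sds.append(np.std(vals, ddof=1))
        assert sds[0] < sds[1] < sds[2]

    def test_target_modulation_positive_under_default_noise(self):
        params = SimulationParams(n_subjects=3, seed=21)
        params.trackers = {"ET": params.trackers["ET"]}
        cohort = simulate_cohort(params)
        cfg = AnalysisConfig(trackers=("ET",))
        for sid in cohort.subject_ids:
            curves, _ = curves_for_recording(
                cohort.recordings[(sid, "ET")], cohort.events[sid], cfg)
            s = subject_modulation_index(
                [c for c in curves if c.condition == "target"],
                [c for c in curves if c.condition == "distractor"])
            assert s.mi > 0
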