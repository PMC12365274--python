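import numpy as np
import pytest

from gazeshift.events import (DetectionError, DetectorParams, compute_kinematics,
                              detect_blinks, detect_fixations, detect_saccades)
from gazeshift.simulate import SimulationTruth, simulate_trial

from conftest import make_trial


def ramp_trial(geometry, rate=500.0, speed_deg_s=10.0):
    dt = 1000.0 / rate
    t = np.arange(0.0, 1000.0, dt)
    y = speed_deg_s * t / 1000.0
    return make_trial(t, np.zeros_like(t), y, geometry)


class TestKinematics:
    def test_constant_position_zero_velocity(self, trial_factory):
        kin = compute_kinematics(trial_factory(x=1.0, y=2.0))
        core = kin.iloc[5:-5]
        assert np.allclose(core["speed"], 0.0, atol=1e-9)
        assert np.allclose(core["accel"].dropna(), 0.0, atol=1e-9)

    def test_linear_ramp_recovers_slope(self, geometry):
        kin = compute_kinematics(ramp_trial(geometry, speed_deg_s=10.0))
        core = kin["speed"].iloc[10:-10]
        assert np.allclose(core, 10.0, atol=1e-6)

    def test_smooth_fixational_jitter_stays_subthreshold(self, layout, geometry,
                                                         design_row):
        # 1 s of simulated fixation with 0.05 deg jitter never looks saccadic
        truth = SimulationTruth(p_toward=0.0, p_blink=0.0, p_baseline_outlier=0.0,
                                fix_noise_sd_deg=0.05, trial_span_ms=(0.0, 1000.0))
        exceed = 0
        for seed in range(100):
            trial, _ = simulate_trial(design_row, truth, layout, geometry, seed)
            kin = compute_kinematics(trial)
            if np.nanmax(kin["speed"]) >= 30.0:
                exceed += 1
        assert exceed <= 1

    def test_edges_and_invalid_runs_are_nan(self, trial_factory):
        valid = np.ones(801, bool)
        valid[300:350] = False
        kin = compute_kinematics(trial_factory(valid=valid))
        assert kin["speed"].iloc[:2].isna().all()
        assert kin["speed"].iloc[300:350].isna().all()

    def test_too_short_trial_errors(self, geometry):
        t = np.arange(0, 8, 2.0)
        trial = make_trial(t, np.zeros(4), np.zeros(4), geometry)
        with pytest.raises(DetectionError):
            compute_kinematics(trial)


class TestBlinks:
    def test_no_invalid_samples_no_blinks(self, trial_factory):
        assert detect_blinks(trial_factory()) == []

    def test_invalid_run_padded_by_50ms(self, trial_factory):
        valid = np.ones(801, bool)
        valid[400:440] = False                     # 80 ms run at 500 Hz
        trial = trial_factory(valid=valid)
        t = trial.t_ms
        blinks = detect_blinks(trial)
        assert len(blinks) == 1
        assert blinks[0].onset_ms == pytest.approx(t[400] - 50.0)
        assert blinks[0].offset_ms == pytest.approx(t[439] + 50.0)

    def test_edge_blink_clipped_to_trial(self, trial_factory):
        valid = np.ones(801, bool)
        valid[:10] = False
        trial = trial_factory(valid=valid)
        blinks = detect_blinks(trial)
        assert blinks[0].onset_ms == trial.t_ms[0]


class TestSaccadeDetection:
    def test_pure_fixation_no_events(self, design_row, layout, geometry, quiet_truth):
        for seed in range(5):
            trial, _ = simulate_trial(design_row, quiet_truth, layout, geometry, seed)
            assert detect_saccades(trial) == []

    def test_injected_saccade_detected_with_small_onset_error(self, design_row,
                                                              layout, geometry):
        truth = SimulationTruth(p_toward=1.0, p_blink=0.0, p_baseline_outlier=0.0)
        trial, label = simulate_trial(design_row, truth, layout, geometry, 21,
                                      inject={"latency_ms": 300.0,
                                              "amplitude_deg": 5.0,
                                              "duration_ms": 40.0})
        events = detect_saccades(trial)
        assert len(events) == 1
        assert abs(events[0].onset_ms - 300.0) <= 6.0
        assert events[0].amplitude_deg == pytest.approx(5.0, abs=0.6)
        assert events[0].vertical_component_deg < -1.0      # downward, toward mouth

    def test_two_saccades_in_onset_order(self, geometry):
        dt = 2.0
        t = np.arange(-500.0, 1100.0, dt)
        y = np.zeros_like(t)
        for onset, sign in ((200.0, -1.0), (400.0, 1.0)):
            z = 8.0 * (t - onset - 20.0) / 40.0
            prof = 1.0 / (1.0 + np.exp(-np.clip(z, -30, 30)))
            prof[t <= onset] = 0.0
            prof[t >= onset + 40.0] = 1.0
            y = y + sign * 5.0 * prof
        trial = make_trial(t, np.zeros_like(t), y, geometry)
        events = detect_saccades(trial)
        assert len(events) == 2
        assert events[0].onset_ms < events[1].onset_ms
        assert events[0].vertical_component_deg < 0 < events[1].vertical_component_deg

    def test_events_never_overlap(self, design_row, layout, geometry):
        truth = SimulationTruth(p_toward=1.0, p_blink=0.3, p_baseline_outlier=0.1)
        for seed in range(30):
            trial, _ = simulate_trial(design_row, truth, layout, geometry, seed)
            events = detect_saccades(trial)
            for a, b in zip(events, events[1:]):
                assert a.offset_ms < b.onset_ms

    def test_lower_velocity_threshold_never_fewer_events(self, design_row, layout,
                                                         geometry):
        truth = SimulationTruth(p_toward=1.0, p_blink=0.0, p_baseline_outlier=0.0)
        for seed in range(10):
            trial, _ = simulate_trial(design_row, truth, layout, geometry, seed)
            n_default = len(detect_saccades(trial, DetectorParams()))
            n_low = len(detect_saccades(
                trial, DetectorParams(velocity_threshold_deg_s=15.0)))
            assert n_low >= n_default

    def test_saccade_during_blink_discarded(self, geometry):
        dt = 2.0
        t = np.arange(-500.0, 1100.0, dt)
        z = 8.0 * (t - 320.0) / 40.0
        prof = 1.0 / (1.0 + np.exp(-np.clip(z, -30, 30)))
        prof[t <= 300.0] = 0.0
        prof[t >= 340.0] = 1.0
        valid = (t < 290.0) | (t > 350.0)
        trial = make_trial(t, np.zeros_like(t), 5.0 * prof, geometry, valid=valid)
        assert detect_saccades(trial) == []

    def test_detector_recall_and_false_alarms(self, design_row, layout, geometry):
        # scaled-down version of the 1000-trial recovery check
        truth = SimulationTruth(p_toward=1.0, p_blink=0.0, p_baseline_outlier=0.0)
        hits = 0
        n = 150
        for seed in range(n):
            trial, label = simulate_trial(design_row, truth, layout, geometry, seed)
            events = detect_saccades(trial)
            ok = [e for e in events if abs(e.onset_ms - label.latency_ms) <= 6.0]
            hits += bool(ok)
        assert hits / n >= 0.98
        quiet = SimulationTruth(p_toward=0.0, p_blink=0.0, p_baseline_outlier=0.0)
        false_alarms = sum(
            bool(detect_saccades(simulate_trial(design_row, quiet, layout, geometry,
                                                10_000 + s)[0]))
            for s in range(n))
        assert false_alarms / n <= 0.01


def test_fixations_tile_gaps_between_events(design_row, layout, geometry):
    truth = SimulationTruth(p_toward=1.0, p_blink=0.0, p_baseline_outlier=0.0)
    trial, _ = simulate_trial(design_row, truth, layout, geometry, 2)
    saccades = detect_saccades(trial)
    fixations = detect_fixations(trial, saccades=saccades, blinks=[])
    assert len(fixations) >= 2
    for fx in fixations:
        for sc in saccades:
            assert fx.offset_ms <= sc.onset_ms or fx.onset_ms >= sc.offset_ms
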