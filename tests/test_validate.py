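import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gazeshift.design import TrialDesign
from gazeshift.events import OculomotorEvent, detect_blinks
from gazeshift.simulate import SimulationTruth, simulate_trial
from gazeshift.validate import (ValidationParams, baseline_position,
                                filter_participants, recursive_outlier_mask,
                                validate_trials)

from conftest import make_trial
from oracles import recursive_outliers_bruteforce


class TestRecursiveOutlierMask:
    def test_constant_values_no_outliers(self):
        assert not recursive_outlier_mask([5.0] * 5).any()

    def test_single_extreme_flagged(self):
        rng = np.random.default_rng(0)
        values = np.append(rng.normal(0, 1, 50), 25.0)
        mask = recursive_outlier_mask(values)
        assert mask.tolist() == recursive_outliers_bruteforce(values.tolist())
        assert mask[-1]
        assert mask[:-1].sum() == 0

    def test_two_sided_extremes_flagged(self):
        rng = np.random.default_rng(2)
        values = np.concatenate([rng.normal(0, 1, 50), [-25.0, 25.0]])
        mask = recursive_outlier_mask(values)
        assert mask[-2] and mask[-1]
        assert mask.tolist() == recursive_outliers_bruteforce(values.tolist())

    def test_recursion_peels_masked_outliers(self):
        # the milder outlier only becomes extreme after the big one is removed
        rng = np.random.default_rng(3)
        values = np.concatenate([rng.normal(0, 1, 80), [12.0, 60.0]])
        mask = recursive_outlier_mask(values)
        assert mask.tolist() == recursive_outliers_bruteforce(values.tolist())
        assert mask[-1]

    @pytest.mark.parametrize("n", [0, 1, 2, 3])
    def test_short_inputs_all_false(self, n):
        assert not recursive_outlier_mask(list(range(n))).any()

    def test_matches_bruteforce_oracle_on_random_vectors(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            n = int(rng.integers(3, 200))
            v = rng.normal(0, 1, n)
            for _ in range(int(rng.integers(0, 4))):
                v[rng.integers(n)] = rng.choice([-1, 1]) * rng.uniform(5, 40)
            mine = recursive_outlier_mask(v)
            assert mine.tolist() == recursive_outliers_bruteforce(v.tolist())

    @given(st.lists(st.floats(-1e3, 1e3).map(lambda v: round(v, 6)),
                    min_size=1, max_size=60))
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_oracle_equivalence_property(self, values):
        # gaze baselines live on a degree scale; micro-degree rounding keeps
        # the float comparison free of squared-deviation underflow
        mine = recursive_outlier_mask(values)
        assert mine.tolist() == recursive_outliers_bruteforce(values)

    @given(st.lists(st.floats(-1e3, 1e3), min_size=3, max_size=40))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_mask_never_flags_everything(self, values):
        mask = recursive_outlier_mask(values)
        assert (~mask).sum() >= 2


class TestBaseline:
    def test_constant_gaze_recovered(self, trial_factory):
        trial = trial_factory(x=1.0, y=2.0)
        bx, by = baseline_position(trial)
        assert bx == pytest.approx(1.0, abs=1e-9)
        assert by == pytest.approx(2.0, abs=1e-9)

    def test_jittered_baseline_near_truth(self, design_row, layout, geometry):
        truth = SimulationTruth(p_toward=0.0, p_blink=0.0, p_baseline_outlier=0.0)
        devs = [np.hypot(*baseline_position(
            simulate_trial(design_row, truth, layout, geometry, s)[0]))
            for s in range(50)]
        # smooth jitter: baseline means stay well within the sample SD
        assert np.mean(devs) < truth.fix_noise_sd_deg

    def test_all_invalid_baseline_returns_none(self, trial_factory):
        trial = trial_factory(valid=np.zeros(801, bool))
        assert baseline_position(trial) is None

    def test_baseline_uses_only_prestimulus_window(self, geometry):
        t = np.arange(-500.0, 1100.0, 2.0)
        y = np.where(t < 0, 1.0, 9.0)     # gaze jumps at onset
        trial = make_trial(t, np.zeros_like(t), y, geometry)
        _, by = baseline_position(trial)
        assert by == pytest.approx(1.0, abs=1e-9)


def _quiet_trials(design, layout, geometry, n, seed0=0, block=1, noise_sd=0.0):
    truth = SimulationTruth(p_toward=0.0, p_blink=0.0, p_baseline_outlier=0.0,
                            fix_noise_sd_deg=noise_sd)
    trials = []
    from dataclasses import replace
    for i in range(n):
        d = replace(design, trial_index=i + 1, block=block)
        trial, _ = simulate_trial(d, truth, layout, geometry, seed0 + i)
        trial.trial_index = i + 1
        trials.append(trial)
    return trials


class TestValidateTrials:
    def test_clean_block_fully_valid(self, design_row, layout, geometry):
        trials = _quiet_trials(design_row, layout, geometry, 40)
        out = validate_trials(trials, [[] for _ in trials])
        assert out["valid"].all()

    def test_single_drifted_trial_flagged(self, design_row, layout, geometry):
        trials = _quiet_trials(design_row, layout, geometry, 40)
        drift = trials[17]
        drift.samples["y_px"] -= 300.0            # ~8 deg upward baseline shift
        out = validate_trials(trials, [[] for _ in trials])
        assert not out.loc[17, "valid"]
        assert out.loc[17, "exclusion_reason"] == "baseline_outlier_y"
        assert out.drop(index=17)["valid"].all()

    @pytest.mark.parametrize("blink_span,expected_valid", [
        ((100.0, 180.0), False),    # intersects [-300, 150]
        ((200.0, 260.0), True),     # entirely after the window
        ((-400.0, -350.0), True),   # entirely before
        ((140.0, 150.0), False),    # touches the upper edge
    ])
    def test_blink_window_intersection(self, design_row, layout, geometry,
                                       blink_span, expected_valid):
        trials = _quiet_trials(design_row, layout, geometry, 20)
        blinks = [[] for _ in trials]
        blinks[4] = [OculomotorEvent("blink", *blink_span)]
        out = validate_trials(trials, blinks)
        assert out.loc[4, "valid"] == expected_valid
        if not expected_valid:
            assert out.loc[4, "exclusion_reason"] == "blink_in_window"

    def test_outlier_detection_runs_per_block(self, design_row, layout, geometry):
        # the same drifted baseline is an outlier within its own block only
        block1 = _quiet_trials(design_row, layout, geometry, 30, block=1)
        block2 = _quiet_trials(design_row, layout, geometry, 30, seed0=100, block=2)
        for tr in block2:
            tr.samples["y_px"] -= 300.0           # whole block drifted together
            tr.trial_index += 30
        out = validate_trials(block1 + block2, [[] for _ in range(60)])
        assert out["valid"].all()                 # consistent within each block


class TestFilterParticipants:
    @staticmethod
    def _outcomes(n_valid, n_total, pid="p01"):
        return pd.DataFrame({"participant": [pid] * n_total,
                             "valid": [True] * n_valid + [False] * (n_total - n_valid)})

    def test_just_below_70_percent_excluded(self):
        kept, excluded, frac = filter_participants(self._outcomes(201, 288))
        assert excluded == ["p01"] and kept == []

    def test_at_or_above_70_percent_kept(self):
        kept, excluded, _ = filter_participants(self._outcomes(202, 288))
        assert kept == ["p01"] and excluded == []

    def test_all_valid_kept(self):
        kept, excluded, _ = filter_participants(self._outcomes(288, 288))
        assert kept == ["p01"]


def test_exclusion_rate_brackets_reported_range(layout, geometry):
    """Default nuisance rates produce a realistic 5-15% trial exclusion rate."""
    from gazeshift.design import DesignSpec
    from gazeshift.simulate import iter_simulated_participants

    spec = DesignSpec(orientations=("upright",), presentation_times_ms=(150,),
                      fixation_locations=("eyes", "mouth"), trials_per_cell=16,
                      faces_per_sex_per_cell=8, blocks=1)   # 96-trial blocks
    rates = []
    for session in iter_simulated_participants(
            spec, 6, SimulationTruth(), layout, geometry, seed=500):
        blinks = [detect_blinks(t) for t in session.trials]
        out = validate_trials(session.trials, blinks)
        rates.append(1.0 - out["valid"].mean())
    assert 0.05 <= np.mean(rates) <= 0.15
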