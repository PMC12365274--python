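import numpy as np
import pandas as pd
import pytest

from gazeshift import GazeTrial, ScreenGeometry, deg_to_px
from gazeshift.design import DesignSpec, TrialDesign
from gazeshift.simulate import FeatureLayout, SimulationTruth


@pytest.fixture(scope="session")
def geometry():
    return ScreenGeometry.exp1()


@pytest.fixture(scope="session")
def geometry_exp2():
    return ScreenGeometry.exp2()


@pytest.fixture(scope="session")
def layout():
    return FeatureLayout()


@pytest.fixture
def clean_truth():
    """No blinks, no drift, every trial a toward-saccade."""
    return SimulationTruth(p_toward=1.0, p_opposite=0.0, p_blink=0.0,
                           p_baseline_outlier=0.0)


@pytest.fixture
def quiet_truth():
    """No saccades, blinks or drift: pure fixation trials."""
    return SimulationTruth(p_toward=0.0, p_opposite=0.0, p_blink=0.0,
                           p_baseline_outlier=0.0)


@pytest.fixture(scope="session")
def small_spec():
    """3 emotions x 2 fixations, 4 trials/cell, one block (24 trials)."""
    return DesignSpec(orientations=("upright",), presentation_times_ms=(150,),
                      fixation_locations=("eyes", "mouth"), trials_per_cell=4,
                      faces_per_sex_per_cell=2, blocks=1)


@pytest.fixture
def design_row():
    return TrialDesign("p01", 1, 1, "fearful", "upright", 150, "eyes", "s001", "female")


def make_trial(t_ms, x_deg, y_deg, geometry, valid=None, design=None,
               participant="p01", trial=1):
    """Build a GazeTrial from degree-space position arrays."""
    x_px, y_px = deg_to_px(np.asarray(x_deg, float), np.asarray(y_deg, float), geometry)
    samples = pd.DataFrame({
        "t_ms": np.asarray(t_ms, float), "x_px": x_px, "y_px": y_px,
        "valid": np.ones(len(t_ms), bool) if valid is None else np.asarray(valid, bool),
    })
    return GazeTrial(participant, trial, samples, geometry, design)


@pytest.fixture
def trial_factory(geometry):
    def factory(duration_ms=(-500, 1100), rate_hz=500.0, x=0.0, y=0.0, valid=None,
                design=None, trial=1):
        dt = 1000.0 / rate_hz
        t = np.arange(duration_ms[0], duration_ms[1] + dt / 2, dt)
        x_arr = np.broadcast_to(np.asarray(x, float), t.shape).copy()
        y_arr = np.broadcast_to(np.asarray(y, float), t.shape).copy()
        return make_trial(t, x_arr, y_arr, geometry, valid=valid, design=design,
                          trial=trial)
    return factory
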