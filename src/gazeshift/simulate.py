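"""Synthetic gaze and response generator with known ground truth.

Replaces the recorded eye-tracking sessions with a simulator whose every
stochastic ingredient is labelled, so the downstream detector, validation and
statistics stages can be tested by parameter recovery.

The generator emulates the regularities of the recorded data it stands in
for: fixational drift as temporally smooth Gaussian noise around the
fixated-feature anchor, at most one saccade per trial (first saccades are the
analysis unit) with a smooth logistic position profile and main-sequence
duration scaling, blinks as runs of invalid samples, occasional whole-trial
baseline drift, and categorical emotion responses drawn from a row-stochastic
confusion matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .design import EMOTIONS, DesignSpec, TrialDesign, build_design, designs_to_frame
from .geometry import GazeTrial, ScreenGeometry, deg_to_px

__all__ = [
    "SimulationTruth",
    "FeatureLayout",
    "TruthLabel",
    "ParticipantSession",
    "SimulatedExperiment",
    "simulate_trial",
    "simulate_response",
    "simulate_experiment",
    "iter_simulated_participants",
]

UPPER_FACE = frozenset({"eyes", "left_eye", "glabella", "right_eye"})
LOWER_FACE = frozenset({"mouth", "mouth_center", "left_cheek", "right_cheek"})

_DEFAULT_CONFUSION = np.array([
    [0.94, 0.03, 0.03],
    [0.03, 0.94, 0.03],
    [0.03, 0.03, 0.94],
])


class UnknownCellError(KeyError):
    """A design cell has no entry in the truth's probability table."""


@dataclass(frozen=True)
class FeatureLayout:
    """Positions of facial-feature anchors in degrees, face upright.

    Coordinates are face-centric with y up; when a feature is at initial
    fixation the face is shifted so that anchor sits on the fixation cross.
    Inversion flips the sign of every vertical anchor.
    """

    vertical_separation_deg: float = 5.0
    lateral_offset_deg: float = 1.8

    def anchor(self, feature: str, orientation: str = "upright") -> tuple[float, float]:
        half = self.vertical_separation_deg / 2.0
        lat = {"left_eye": -1, "left_cheek": -1, "right_eye": 1, "right_cheek": 1}
        x = lat.get(feature, 0) * self.lateral_offset_deg
        if feature in UPPER_FACE:
            y = half
        elif feature in LOWER_FACE:
            y = -half
        else:
            raise UnknownCellError(f"unknown fixation feature {feature!r}")
        if orientation == "inverted":
            y = -y
        return (x, y)

    def toward_sign(self, initial_fixation: str, orientation: str) -> float:
        """Sign of the vertical displacement toward the other major feature.

        +1 is upward in degree space: starting on the screen-upper feature the
        qualifying gaze shift is downward (-1), and vice versa.
        """
        _, y = self.anchor(initial_fixation, orientation)
        return -1.0 if y > 0 else 1.0


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class SimulationTruth:
    """Ground-truth parameter set for one simulated session.

    ``p_toward`` may be a single probability for all cells, or a mapping
    keyed by the full (emotion, orientation, presentation_time, fixation)
    cell, by (emotion, fixation), or by emotion alone.
    """

    p_toward: float | Mapping = 0.25
    p_opposite: float = 0.0065
    latency_median_ms: float = 280.0
    latency_sigma: float = 0.35
    latency_window_ms: tuple[float, float] = (160.0, 920.0)
    amplitude_mean_deg: float = 4.0
    amplitude_sd_deg: float = 1.0
    amplitude_min_deg: float = 1.5
    horizontal_sd_deg: float = 0.4
    fix_noise_sd_deg: float = 0.3
    jitter_timescale_ms: float = 50.0
    p_blink: float = 0.05
    p_baseline_outlier: float = 0.03
    outlier_offset_range_sd: tuple[float, float] = (5.0, 12.0)
    confusion: np.ndarray = field(default_factory=lambda: _DEFAULT_CONFUSION.copy())
    rt_median_ms: float = 600.0
    rt_sigma: float = 0.25
    emotions: tuple[str, ...] = EMOTIONS
    trial_span_ms: tuple[float, float] = (-500.0, 1100.0)

    def __post_init__(self) -> None:
        conf = np.asarray(self.confusion, dtype=float)
        if conf.shape != (len(self.emotions),) * 2:
            raise ValueError("confusion matrix shape must match the emotion set")
        if not np.allclose(conf.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("confusion rows must sum to 1")
        for name in ("p_opposite", "p_blink", "p_baseline_outlier"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability")
        lo, hi = self.latency_window_ms
        if not (150.0 < lo < hi < 1000.0):
            raise ValueError("latency window must lie strictly inside (150, 1000) ms")

    def p_toward_for(self, design: TrialDesign) -> float:
        if isinstance(self.p_toward, (int, float)):
            return float(self.p_toward)
        for key in (design.cell, (design.emotion, design.initial_fixation), design.emotion):
            if key in self.p_toward:
                return float(self.p_toward[key])
        raise UnknownCellError(f"no p_toward entry for cell {design.cell}")

    @classmethod
    def identity_responses(cls, **kw) -> "SimulationTruth":
        return cls(confusion=np.eye(3), **kw)

    @classmethod
    def uniform_responses(cls, **kw) -> "SimulationTruth":
        return cls(confusion=np.full((3, 3), 1.0 / 3.0), **kw)


@dataclass
class TruthLabel:
    """What the generator injected into one trial."""

    participant_id: str
    trial_index: int
    saccade_kind: str = "none"          # toward | opposite | none
    latency_ms: float = math.nan
    amplitude_deg: float = math.nan
    vertical_deg: float = math.nan
    duration_ms: float = math.nan
    blink: bool = False
    blink_onset_ms: float = math.nan
    blink_offset_ms: float = math.nan
    baseline_outlier: bool = False
    outlier_dx_deg: float = 0.0
    outlier_dy_deg: float = 0.0
    response: str | None = None
    rt_ms: float = math.nan


def _smooth_jitter(n: int, sd_deg: float, timescale_ms: float, dt_ms: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Temporally smooth fixational drift with the given stationary SD.

    White noise filtered with a Gaussian kernel (sigma = timescale); the
    analytic L2 norm of the kernel rescales back to the target SD, keeping
    sample-to-sample velocities physiologically slow.
    """
    if sd_deg == 0.0:
        return np.zeros(n)
    sigma = max(timescale_ms / dt_ms, 1e-6)
    w = rng.standard_normal(n)
    sm = gaussian_filter1d(w, sigma, mode="reflect")
    # ||g||_2 of a discrete Gaussian kernel ~ (2 sigma sqrt(pi))^(-1/2)
    return sm * sd_deg * math.sqrt(2.0 * sigma * math.sqrt(math.pi))


def _logistic_profile(t_ms: np.ndarray, onset_ms: float, duration_ms: float) -> np.ndarray:
    """Smooth 0->1 displacement ramp over [onset, onset+duration].

    Normalized logistic (z spanning +-4) so the position is exactly 0 before
    onset and 1 after offset, with a unimodal velocity peak at midpoint.
    """
    z = 8.0 * (t_ms - onset_ms - duration_ms / 2.0) / duration_ms
    lo, hi = 1.0 / (1.0 + math.exp(4.0)), 1.0 / (1.0 + math.exp(-4.0))
    frac = (1.0 / (1.0 + np.exp(-np.clip(z, -30, 30))) - lo) / (hi - lo)
    frac[t_ms <= onset_ms] = 0.0
    frac[t_ms >= onset_ms + duration_ms] = 1.0
    return frac


def _sample_latency(truth: SimulationTruth, rng: np.random.Generator) -> float:
    mu = math.log(truth.latency_median_ms)
    lo, hi = truth.latency_window_ms
    for _ in range(1000):
        lat = math.exp(rng.normal(mu, truth.latency_sigma))
        if lo < lat < hi:
            return lat
    return 0.5 * (lo + hi)  # pathological parameters; fall back to window centre


def _sample_amplitude(truth: SimulationTruth, rng: np.random.Generator) -> float:
    for _ in range(1000):
        a = rng.normal(truth.amplitude_mean_deg, truth.amplitude_sd_deg)
        if a >= truth.amplitude_min_deg:
            return a
    return truth.amplitude_min_deg


def _main_sequence_duration(amplitude_deg: float, rng: np.random.Generator) -> float:
    """Saccade duration from an affine main-sequence rule, clipped to 30-60 ms."""
    return float(np.clip(21.0 + 2.2 * amplitude_deg + rng.uniform(0.0, 4.0), 30.0, 60.0))


def simulate_trial(design: TrialDesign, truth: SimulationTruth, layout: FeatureLayout,
                   geometry: ScreenGeometry, seed,
                   inject: Mapping | None = None) -> tuple[GazeTrial, TruthLabel]:
    """Simulate one trial's gaze stream.

    ``inject`` optionally forces stochastic choices for fixture construction:
    keys ``saccade`` ('toward'|'opposite'|None), ``blink``, ``baseline_outlier``,
    ``latency_ms``, ``amplitude_deg``.
    """
    rng = _as_rng(seed)
    inject = dict(inject or {})
    p_toward = truth.p_toward_for(design)

    dt = geometry.sample_interval_ms
    t0, t1 = truth.trial_span_ms
    t = np.arange(t0, t1 + dt / 2.0, dt)
    n = len(t)

    label = TruthLabel(design.participant_id, design.trial_index)

    x = _smooth_jitter(n, truth.fix_noise_sd_deg, truth.jitter_timescale_ms, dt, rng)
    y = _smooth_jitter(n, truth.fix_noise_sd_deg, truth.jitter_timescale_ms, dt, rng)

    # whole-trial baseline drift (uncorrected head/eye drift between trials)
    u = rng.uniform()
    if inject.get("baseline_outlier", u < truth.p_baseline_outlier):
        mag = rng.uniform(*truth.outlier_offset_range_sd) * max(truth.fix_noise_sd_deg, 0.05)
        ang = rng.uniform(0.0, 2.0 * math.pi)
        label.baseline_outlier = True
        label.outlier_dx_deg = mag * math.cos(ang)
        label.outlier_dy_deg = mag * math.sin(ang)
        x += label.outlier_dx_deg
        y += label.outlier_dy_deg

    # at most one first saccade, toward the peripheral feature or opposite
    u = rng.uniform()
    kind = inject.get("saccade",
                      "toward" if u < p_toward
                      else "opposite" if u < p_toward + truth.p_opposite
                      else None)
    if kind is not None:
        lat = float(inject.get("latency_ms", _sample_latency(truth, rng)))
        amp = float(inject.get("amplitude_deg", _sample_amplitude(truth, rng)))
        dur = float(inject.get("duration_ms", _main_sequence_duration(amp, rng)))
        sign = layout.toward_sign(design.initial_fixation, design.orientation)
        if kind == "opposite":
            sign = -sign
        dx = rng.normal(0.0, truth.horizontal_sd_deg)
        dy = sign * math.sqrt(max(amp * amp - dx * dx, 1.44))
        prof = _logistic_profile(t, lat, dur)
        x += dx * prof
        y += dy * prof
        label.saccade_kind = kind
        label.latency_ms = lat
        label.amplitude_deg = math.hypot(dx, dy)
        label.vertical_deg = dy
        label.duration_ms = dur

    valid = np.ones(n, dtype=bool)
    u = rng.uniform()
    if inject.get("blink", u < truth.p_blink):
        b0 = rng.uniform(-300.0, 100.0)
        bdur = rng.uniform(60.0, 150.0)
        valid &= ~((t >= b0) & (t <= b0 + bdur))
        label.blink = True
        label.blink_onset_ms = b0
        label.blink_offset_ms = b0 + bdur

    x_px, y_px = deg_to_px(x, y, geometry)
    samples = pd.DataFrame({"t_ms": t, "x_px": x_px, "y_px": y_px, "valid": valid})
    trial = GazeTrial(design.participant_id, design.trial_index, samples, geometry, design)
    return trial, label


def simulate_response(design: TrialDesign, truth: SimulationTruth, seed) -> tuple[str, float]:
    """Draw an emotion classification and response time for one trial."""
    rng = _as_rng(seed)
    try:
        row = np.asarray(truth.confusion)[truth.emotions.index(design.emotion)]
    except ValueError:
        raise UnknownCellError(f"no confusion row for emotion {design.emotion!r}") from None
    response = str(rng.choice(truth.emotions, p=row))
    rt = float(math.exp(rng.normal(math.log(truth.rt_median_ms), truth.rt_sigma)))
    return response, rt


@dataclass
class ParticipantSession:
    """One simulated participant: design rows, gaze trials and truth labels."""

    participant_id: str
    designs: list[TrialDesign]
    trials: list[GazeTrial]
    labels: pd.DataFrame


@dataclass
class SimulatedExperiment:
    participants: list[ParticipantSession]

    @property
    def n_trials(self) -> int:
        return sum(len(p.trials) for p in self.participants)

    def design_frame(self) -> pd.DataFrame:
        return pd.concat([designs_to_frame(p.designs) for p in self.participants],
                         ignore_index=True)

    def label_frame(self) -> pd.DataFrame:
        return pd.concat([p.labels for p in self.participants], ignore_index=True)


def iter_simulated_participants(spec: DesignSpec, n_participants: int,
                                truth: SimulationTruth, layout: FeatureLayout,
                                geometry: ScreenGeometry, seed: int
                                ) -> Iterator[ParticipantSession]:
    """Lazily simulate participants (memory-friendly for large sessions).

    A master ``SeedSequence`` spawns independent per-participant and per-trial
    streams, so any participant is reproducible from (seed, index) alone.
    """
    for p_idx in range(n_participants):
        pid = f"p{p_idx + 1:02d}"
        design_seed = np.random.SeedSequence([seed, p_idx, 0])
        designs = build_design(spec, design_seed, participant_id=pid)
        trials, rows = [], []
        for trial_idx, d in enumerate(designs, start=1):
            trial_ss = np.random.SeedSequence([seed, p_idx, 1, trial_idx])
            gaze_ss, resp_ss = trial_ss.spawn(2)
            gt, lab = simulate_trial(d, truth, layout, geometry,
                                     np.random.default_rng(gaze_ss))
            resp, rt = simulate_response(d, truth, np.random.default_rng(resp_ss))
            lab.response = resp
            lab.rt_ms = rt
            trials.append(gt)
            row = lab.__dict__ | {"emotion": d.emotion, "orientation": d.orientation,
                                  "presentation_time_ms": d.presentation_time_ms,
                                  "initial_fixation": d.initial_fixation,
                                  "block": d.block,
                                  "correct": resp == d.emotion}
            rows.append(row)
        labels = pd.DataFrame(rows).rename(
            columns={"participant_id": "participant", "trial_index": "trial"})
        yield ParticipantSession(pid, designs, trials, labels)


def simulate_null_proportions(n_participants: int, levels: Mapping[str, Sequence],
                              trials_per_cell: int, seed,
                              mean_p: float = 0.15, concentration: float = 20.0
                              ) -> pd.DataFrame:
    """Condition-null saccade-proportion sessions at the behavioural level.

    Each participant gets a Beta-distributed switching propensity (mean
    ``mean_p``) applied identically to every condition cell; observed cell
    proportions are binomial counts over ``trials_per_cell`` trials.  Used to
    calibrate the false-positive rate of the downstream ANOVA.
    """
    import itertools as _it

    rng = _as_rng(seed)
    cells = list(_it.product(*levels.values()))
    a = mean_p * concentration
    b = (1.0 - mean_p) * concentration
    rows = []
    for i in range(n_participants):
        p_i = rng.beta(a, b)
        for cell in cells:
            k = rng.binomial(trials_per_cell, p_i)
            rows.append(dict(zip(levels, cell)) |
                        {"participant": f"p{i + 1:02d}",
                         "proportion_toward": k / trials_per_cell})
    return pd.DataFrame(rows)


def simulate_experiment(spec: DesignSpec, n_participants: int, truth: SimulationTruth,
                        layout: FeatureLayout | None = None,
                        geometry: ScreenGeometry | None = None,
                        seed: int = 0) -> SimulatedExperiment:
    """Simulate a full multi-participant session in memory."""
    layout = layout or FeatureLayout()
    geometry = geometry or ScreenGeometry.exp1()
    return SimulatedExperiment(list(iter_simulated_participants(
        spec, n_participants, truth, layout, geometry, seed)))
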