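"""Velocity/acceleration-threshold segmentation of gaze streams.

Saccades are maximal runs of samples whose smoothed velocity exceeds 30 deg/s
OR whose acceleration magnitude reaches 8000 deg/s^2; runs closer than a merge
gap are joined, runs shorter than a minimum duration are dropped, and runs
overlapping blinks (padded invalid-sample intervals) are discarded.
Differentiation happens in degree space, per contiguous run of valid samples,
using a symmetric Savitzky-Golay derivative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .geometry import GazeTrial

__all__ = [
    "DetectorParams",
    "OculomotorEvent",
    "FixationEvent",
    "compute_kinematics",
    "detect_blinks",
    "detect_saccades",
    "detect_fixations",
    "events_to_frame",
]


class DetectionError(ValueError):
    pass


@dataclass(frozen=True)
class DetectorParams:
    """Kinematic thresholds and post-processing knobs.

    Defaults pin the two published thresholds (30 deg/s, 8000 deg/s^2); the
    remaining values approximate a vendor parser's behaviour and are declared
    here rather than inherited from it.
    """

    velocity_threshold_deg_s: float = 30.0
    accel_threshold_deg_s2: float = 8000.0
    min_duration_ms: float = 4.0
    merge_gap_ms: float = 20.0
    velocity_window_samples: int = 5
    blink_pad_ms: float = 50.0

    def __post_init__(self) -> None:
        if self.velocity_threshold_deg_s <= 0 or self.accel_threshold_deg_s2 <= 0:
            raise DetectionError("thresholds must be positive")
        if self.velocity_window_samples < 3 or self.velocity_window_samples % 2 == 0:
            raise DetectionError("velocity_window_samples must be odd and >= 3")


@dataclass(frozen=True)
class OculomotorEvent:
    kind: str                      # "saccade" | "blink"
    onset_ms: float
    offset_ms: float
    start_deg: tuple[float, float] = (np.nan, np.nan)
    end_deg: tuple[float, float] = (np.nan, np.nan)
    amplitude_deg: float = np.nan
    vertical_component_deg: float = np.nan   # positive = upward
    peak_velocity_deg_s: float = np.nan

    @property
    def duration_ms(self) -> float:
        return self.offset_ms - self.onset_ms


@dataclass(frozen=True)
class FixationEvent:
    onset_ms: float
    offset_ms: float
    centroid_deg: tuple[float, float]


def _bool_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Inclusive (start, stop) index pairs of True runs."""
    if not mask.any():
        return []
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return [(int(a), int(b) - 1) for a, b in zip(idx[::2], idx[1::2])]


def compute_kinematics(trial: GazeTrial, params: DetectorParams = DetectorParams()
                       ) -> pd.DataFrame:
    """Per-sample velocity and acceleration in degree space.

    Velocity comes from a Savitzky-Golay first derivative (order-2 polynomial
    over ``velocity_window_samples``) applied separately to each contiguous
    run of valid samples; acceleration is the forward first difference of
    speed.  Half-window edges of each run and all invalid samples are NaN.
    """
    w = params.velocity_window_samples
    if int(trial.valid.sum()) < w:
        raise DetectionError(
            f"trial {trial.participant_id}/{trial.trial_index}: fewer than "
            f"{w} valid samples")
    t = trial.t_ms
    x_deg, y_deg = trial.positions_deg()
    dt_s = np.median(np.diff(t)) / 1000.0

    n = len(t)
    vx = np.full(n, np.nan)
    vy = np.full(n, np.nan)
    half = w // 2
    for a, b in _bool_runs(trial.valid):
        if b - a + 1 < w:
            continue
        sl = slice(a, b + 1)
        vx[sl] = savgol_filter(x_deg[sl], w, 2, deriv=1, delta=dt_s)
        vy[sl] = savgol_filter(y_deg[sl], w, 2, deriv=1, delta=dt_s)
        vx[a:a + half] = vy[a:a + half] = np.nan
        vx[b - half + 1:b + 1] = vy[b - half + 1:b + 1] = np.nan

    speed = np.hypot(vx, vy)
    accel = np.full(n, np.nan)
    accel[:-1] = np.diff(speed) / dt_s
    return pd.DataFrame({"t_ms": t, "x_deg": x_deg, "y_deg": y_deg,
                         "vx": vx, "vy": vy, "speed": speed, "accel": accel})


def detect_blinks(trial: GazeTrial, params: DetectorParams = DetectorParams()
                  ) -> list[OculomotorEvent]:
    """Maximal invalid-sample runs, padded by ``blink_pad_ms`` and clipped."""
    t = trial.t_ms
    events = []
    for a, b in _bool_runs(~trial.valid):
        onset = max(t[a] - params.blink_pad_ms, t[0])
        offset = min(t[b] + params.blink_pad_ms, t[-1])
        if events and onset <= events[-1].offset_ms:
            prev = events.pop()
            onset = prev.onset_ms
        events.append(OculomotorEvent("blink", float(onset), float(offset)))
    return events


def detect_saccades(trial: GazeTrial, params: DetectorParams = DetectorParams(),
                    kinematics: pd.DataFrame | None = None,
                    blinks: list[OculomotorEvent] | None = None
                    ) -> list[OculomotorEvent]:
    """Threshold the kinematics into saccade events, sorted by onset."""
    kin = kinematics if kinematics is not None else compute_kinematics(trial, params)
    blinks = blinks if blinks is not None else detect_blinks(trial, params)
    t = kin["t_ms"].to_numpy()
    speed = kin["speed"].to_numpy()
    accel = kin["accel"].to_numpy()

    with np.errstate(invalid="ignore"):
        mask = (speed > params.velocity_threshold_deg_s) | \
               (np.abs(accel) >= params.accel_threshold_deg_s2)
    mask &= ~np.isnan(speed)
    for bl in blinks:
        mask &= ~((t >= bl.onset_ms) & (t <= bl.offset_ms))

    runs = _bool_runs(mask)
    merged: list[list[int]] = []
    for a, b in runs:
        if merged and t[a] - t[merged[-1][1]] < params.merge_gap_ms:
            merged[-1][1] = b
        else:
            merged.append([a, b])

    x = kin["x_deg"].to_numpy()
    y = kin["y_deg"].to_numpy()
    events = []
    for a, b in merged:
        if t[b] - t[a] < params.min_duration_ms:
            continue
        if any(t[a] <= bl.offset_ms and t[b] >= bl.onset_ms for bl in blinks):
            continue
        events.append(OculomotorEvent(
            "saccade", float(t[a]), float(t[b]),
            (float(x[a]), float(y[a])), (float(x[b]), float(y[b])),
            float(np.hypot(x[b] - x[a], y[b] - y[a])),
            float(y[b] - y[a]),
            float(np.nanmax(speed[a:b + 1]))))
    return events


def detect_fixations(trial: GazeTrial, params: DetectorParams = DetectorParams(),
                     saccades: list[OculomotorEvent] | None = None,
                     blinks: list[OculomotorEvent] | None = None) -> list[FixationEvent]:
    """Periods of relatively stable gaze between saccades and blinks."""
    if saccades is None:
        saccades = detect_saccades(trial, params)
    if blinks is None:
        blinks = detect_blinks(trial, params)
    t = trial.t_ms
    x_deg, y_deg = trial.positions_deg()
    occupied = sorted([(e.onset_ms, e.offset_ms) for e in saccades + blinks])
    fixations = []
    cursor = t[0]
    for on, off in occupied + [(t[-1], t[-1])]:
        if on > cursor:
            sel = (t >= cursor) & (t < on) & trial.valid
            if sel.sum() >= 2:
                fixations.append(FixationEvent(
                    float(cursor), float(on),
                    (float(x_deg[sel].mean()), float(y_deg[sel].mean()))))
        cursor = max(cursor, off)
    return fixations


def events_to_frame(events: Sequence[OculomotorEvent], participant: str = "",
                    trial: int = 0) -> pd.DataFrame:
    """Tidy one-row-per-event table for CSV export."""
    return pd.DataFrame([{
        "participant": participant, "trial": trial, "kind": e.kind,
        "onset_ms": e.onset_ms, "offset_ms": e.offset_ms,
        "start_x_deg": e.start_deg[0], "start_y_deg": e.start_deg[1],
        "end_x_deg": e.end_deg[0], "end_y_deg": e.end_deg[1],
        "amplitude_deg": e.amplitude_deg,
        "vertical_component_deg": e.vertical_component_deg,
        "peak_velocity_deg_s": e.peak_velocity_deg_s,
    } for e in events])
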