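"""Screen geometry, pixel/visual-degree conversion and gaze-sample IO.

Pixel space follows the display convention (origin top-left, y down).
Degree space is centred on the screen with positive y pointing *up*, so an
"upward saccade" has a positive vertical component.  Timestamps are
milliseconds relative to stimulus onset (negative = pre-stimulus).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

if TYPE_CHECKING:  # pragma: no cover
    from .design import TrialDesign

__all__ = [
    "ScreenGeometry",
    "GazeTrial",
    "px_to_deg",
    "deg_to_px",
    "frames_to_ms",
    "read_gaze_table",
    "write_gaze_table",
]


class GeometryError(ValueError):
    """Invalid screen geometry or gaze-table contents."""


@dataclass(frozen=True)
class ScreenGeometry:
    """Physical display and recording parameters.

    Per-axis cm/px scales are kept separate; square pixels are not assumed.
    """

    width_px: int
    height_px: int
    width_cm: float
    height_cm: float
    viewing_distance_cm: float
    sampling_rate_hz: float = 500.0
    refresh_rate_hz: float = 60.0

    def __post_init__(self) -> None:
        for name in ("width_px", "height_px", "width_cm", "height_cm",
                     "viewing_distance_cm", "sampling_rate_hz", "refresh_rate_hz"):
            if getattr(self, name) <= 0:
                raise GeometryError(f"{name} must be strictly positive")

    @property
    def cm_per_px_x(self) -> float:
        return self.width_cm / self.width_px

    @property
    def cm_per_px_y(self) -> float:
        return self.height_cm / self.height_px

    @property
    def sample_interval_ms(self) -> float:
        return 1000.0 / self.sampling_rate_hz

    @classmethod
    def exp1(cls) -> "ScreenGeometry":
        """24" 1920x1200 @ 60 Hz display, 500 Hz tracking, ~62.5 cm viewing."""
        return cls(1920, 1200, 51.69, 32.31, 62.5, 500.0, 60.0)

    @classmethod
    def exp2(cls) -> "ScreenGeometry":
        """24" 1920x1080 @ 144 Hz display, 1000 Hz tracking, 55 cm viewing."""
        return cls(1920, 1080, 53.14, 29.89, 55.0, 1000.0, 144.0)

    @classmethod
    def from_yaml(cls, path) -> "ScreenGeometry":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh)


def px_to_deg(x_px, y_px, geometry: ScreenGeometry):
    """Convert pixel coordinates to visual degrees from screen centre.

    The angle on each axis is ``atan(offset_cm / viewing_distance_cm)``;
    positive x is rightward, positive y is *upward*.
    """
    cx = geometry.width_px / 2.0
    cy = geometry.height_px / 2.0
    dx_cm = (np.asarray(x_px, dtype=float) - cx) * geometry.cm_per_px_x
    dy_cm = (cy - np.asarray(y_px, dtype=float)) * geometry.cm_per_px_y
    d = geometry.viewing_distance_cm
    return (np.degrees(np.arctan2(dx_cm, d)), np.degrees(np.arctan2(dy_cm, d)))


def deg_to_px(x_deg, y_deg, geometry: ScreenGeometry):
    """Inverse of :func:`px_to_deg`; round-trips to numerical precision."""
    d = geometry.viewing_distance_cm
    dx_cm = np.tan(np.radians(np.asarray(x_deg, dtype=float))) * d
    dy_cm = np.tan(np.radians(np.asarray(y_deg, dtype=float))) * d
    x_px = geometry.width_px / 2.0 + dx_cm / geometry.cm_per_px_x
    y_px = geometry.height_px / 2.0 - dy_cm / geometry.cm_per_px_y
    return x_px, y_px


def frames_to_ms(n_frames: int, refresh_rate_hz: float) -> float:
    """Duration of ``n_frames`` video frames in milliseconds."""
    if refresh_rate_hz <= 0:
        raise GeometryError("refresh_rate_hz must be positive")
    if n_frames < 0:
        raise GeometryError("n_frames must be non-negative")
    return 1000.0 * n_frames / refresh_rate_hz


@dataclass
class GazeTrial:
    """Gaze samples for a single trial.

    ``samples`` holds columns ``t_ms, x_px, y_px, valid`` with strictly
    increasing ``t_ms``; invalid samples mark track loss (blinks).
    """

    participant_id: str
    trial_index: int
    samples: pd.DataFrame
    geometry: ScreenGeometry
    design: "TrialDesign | None" = None

    REQUIRED = ("t_ms", "x_px", "y_px", "valid")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.samples.columns]
        if missing:
            raise GeometryError(
                f"trial {self.participant_id}/{self.trial_index}: missing columns {missing}")
        t = self.samples["t_ms"].to_numpy()
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise GeometryError(
                f"trial {self.participant_id}/{self.trial_index}: t_ms not strictly increasing")

    @property
    def t_ms(self) -> np.ndarray:
        return self.samples["t_ms"].to_numpy(dtype=float)

    @property
    def valid(self) -> np.ndarray:
        return self.samples["valid"].to_numpy(dtype=bool)

    def positions_deg(self):
        """(x_deg, y_deg) arrays for all samples."""
        return px_to_deg(self.samples["x_px"].to_numpy(dtype=float),
                         self.samples["y_px"].to_numpy(dtype=float),
                         self.geometry)


GAZE_COLUMNS = ["participant", "trial", "t_ms", "x_px", "y_px", "valid"]


def write_gaze_table(trials: Iterable[GazeTrial], path) -> None:
    """Write trials to a tidy CSV (columns participant, trial, t_ms, x_px, y_px, valid)."""
    frames = []
    for tr in trials:
        df = tr.samples.loc[:, ["t_ms", "x_px", "y_px", "valid"]].copy()
        df.insert(0, "trial", tr.trial_index)
        df.insert(0, "participant", tr.participant_id)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=GAZE_COLUMNS)
    out.to_csv(path, index=False)


def read_gaze_table(path, geometry: ScreenGeometry,
                    designs: "dict[tuple[str, int], TrialDesign] | None" = None
                    ) -> list[GazeTrial]:
    """Read a gaze CSV back into :class:`GazeTrial` objects.

    Validates the required columns and monotonic timestamps; errors name the
    offending trial.  ``designs`` may map (participant, trial) to design rows.
    """
    df = pd.read_csv(path)
    missing = [c for c in GAZE_COLUMNS if c not in df.columns]
    if missing:
        raise GeometryError(f"gaze table {path}: missing columns {missing}")
    trials = []
    for (pid, idx), grp in df.groupby(["participant", "trial"], sort=True):
        samples = grp.loc[:, ["t_ms", "x_px", "y_px", "valid"]].reset_index(drop=True)
        samples["valid"] = samples["valid"].astype(bool)
        design = designs.get((str(pid), int(idx))) if designs else None
        trials.append(GazeTrial(str(pid), int(idx), samples, geometry, design))
    return trials
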