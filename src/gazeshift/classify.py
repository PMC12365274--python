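"""First-saccade selection, direction classification and cell aggregation.

The analysis unit is the first saccade with onset in [150, 1000] ms after
stimulus onset.  A saccade qualifies as a gaze shift only when its vertical
endpoint-to-endpoint component reaches 1 degree of visual angle; smaller
shifts count as continued fixation of the initially presented feature.
Direction is classified purely by the signed vertical component relative to
the screen half of the initially fixated feature: starting on the upper-half
feature, a downward shift is "toward" the peripheral feature (the mouth
region for upright faces) and an upward one heads for the facial outline;
starting on the lower half the mapping reverses.  Face inversion flips which
screen half a feature label occupies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .events import OculomotorEvent
from .simulate import LOWER_FACE, UPPER_FACE

__all__ = [
    "ClassificationParams",
    "first_saccade",
    "classify_direction",
    "aggregate_cells",
    "collapse_locations",
    "plot_endpoints",
    "TOWARD", "OPPOSITE", "NONE",
]

TOWARD = "toward_periphery"
OPPOSITE = "opposite_or_outline"
NONE = "none"

LOCATION_COLLAPSE = {
    "left_eye": "left", "left_cheek": "left",
    "glabella": "middle", "mouth_center": "middle",
    "right_eye": "right", "right_cheek": "right",
}


@dataclass(frozen=True)
class ClassificationParams:
    window_ms: tuple[float, float] = (150.0, 1000.0)
    min_vertical_amplitude_deg: float = 1.0
    upper_face_fixations: frozenset = UPPER_FACE
    lower_face_fixations: frozenset = LOWER_FACE

    def __post_init__(self) -> None:
        if self.min_vertical_amplitude_deg <= 0:
            raise ValueError("min_vertical_amplitude_deg must be positive")
        if self.upper_face_fixations & self.lower_face_fixations:
            raise ValueError("upper/lower fixation sets must be disjoint")


def first_saccade(events: Sequence[OculomotorEvent],
                  params: ClassificationParams = ClassificationParams()
                  ) -> OculomotorEvent | None:
    """Earliest saccade with onset inside the analysis window.

    Saccades before the window do not qualify but also do not block a later
    qualifying saccade.
    """
    lo, hi = params.window_ms
    for ev in sorted((e for e in events if e.kind == "saccade"),
                     key=lambda e: e.onset_ms):
        if lo <= ev.onset_ms <= hi:
            return ev
    return None


def classify_direction(saccade: OculomotorEvent | None, initial_fixation: str,
                       orientation: str = "upright",
                       params: ClassificationParams = ClassificationParams()) -> str:
    """Categorize a first saccade as toward the peripheral feature, opposite, or none."""
    if initial_fixation in params.upper_face_fixations:
        screen_upper = orientation != "inverted"
    elif initial_fixation in params.lower_face_fixations:
        screen_upper = orientation == "inverted"
    else:
        raise KeyError(f"unknown initial fixation {initial_fixation!r}")

    if saccade is None:
        return NONE
    vc = saccade.vertical_component_deg
    if abs(vc) < params.min_vertical_amplitude_deg:
        return NONE
    downward = vc < 0
    return TOWARD if downward == screen_upper else OPPOSITE


def aggregate_cells(outcomes: pd.DataFrame,
                    factors: Sequence[str] = ("emotion", "orientation",
                                              "presentation_time_ms", "initial_fixation"),
                    category_col: str = "first_saccade_category") -> pd.DataFrame:
    """Per participant x condition saccade counts and proportions.

    Only valid trials enter the counts; the proportion of toward-saccades is
    relative to ALL valid trials of the cell (no-saccade and opposite trials
    included).  Cells with no valid trial get NaN proportion and are flagged.
    """
    valid = outcomes[outcomes["valid"]]
    keys = ["participant", *factors]
    counts = (valid.groupby(keys, sort=True)[category_col]
              .value_counts().unstack(fill_value=0))
    for cat in (TOWARD, OPPOSITE, NONE):
        if cat not in counts.columns:
            counts[cat] = 0
    out = counts.rename(columns={TOWARD: "n_toward", OPPOSITE: "n_opposite",
                                 NONE: "n_none"}).reset_index()
    out = out[keys + ["n_toward", "n_opposite", "n_none"]]
    out.columns.name = None

    # reinstate cells whose trials were all invalid
    full = (outcomes.groupby(keys, sort=True).size().rename("n_scheduled").reset_index()
            .merge(out, on=keys, how="left")
            .fillna({"n_toward": 0, "n_opposite": 0, "n_none": 0}))
    full["n_valid"] = (full["n_toward"] + full["n_opposite"] + full["n_none"]).astype(int)
    with np.errstate(invalid="ignore", divide="ignore"):
        full["proportion_toward"] = np.where(
            full["n_valid"] > 0, full["n_toward"] / full["n_valid"], np.nan)
    full["empty_cell"] = full["n_valid"] == 0
    return full.drop(columns="n_scheduled")


def collapse_locations(summary: pd.DataFrame,
                       column: str = "initial_fixation") -> pd.DataFrame:
    """Map the six fixation locations onto left/middle/right for posthocs."""
    out = summary.copy()
    unknown = set(out[column]) - set(LOCATION_COLLAPSE)
    if unknown:
        raise KeyError(f"locations not collapsible to left/middle/right: {sorted(unknown)}")
    out["location"] = out[column].map(LOCATION_COLLAPSE)
    out["face_half"] = np.where(out[column].isin(list(UPPER_FACE)), "upper", "lower")
    return out


def plot_endpoints(endpoints: pd.DataFrame, ax=None, hue: str = "initial_fixation"):
    """Minimal scatter of first-saccade endpoints in degree space."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 5))
    for label, grp in endpoints.groupby(hue):
        ax.scatter(grp["end_x_deg"], grp["end_y_deg"], s=8, alpha=0.5, label=str(label))
    ax.axhline(0, lw=0.5, color="grey")
    ax.axvline(0, lw=0.5, color="grey")
    ax.set_xlabel("x (deg)")
    ax.set_ylabel("y (deg, up positive)")
    ax.legend(frameon=False, fontsize=8)
    return ax
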