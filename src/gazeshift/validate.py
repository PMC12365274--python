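"""Trial- and participant-level inclusion rules.

A trial is excluded when a blink intersects the window [-300, 150] ms around
stimulus onset, or when its baseline gaze position (mean over [-300, 0) ms)
is a recursive outlier among the trials of its block.  Participants with
fewer than 70% valid trials are dropped.

The recursive outlier routine: temporarily set aside the current minimum and
maximum, take mean and SD (n-1 denominator) of the rest, and permanently
flag the extreme(s) deviating more than ``multiplier`` SDs from that mean;
repeat until an iteration flags nothing.  Ties at an extreme are flagged
together; the recursion halts once fewer than ``min_n`` values remain.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .events import OculomotorEvent
from .geometry import GazeTrial

__all__ = [
    "ValidationParams",
    "baseline_position",
    "recursive_outlier_mask",
    "validate_trials",
    "filter_participants",
]


@dataclass(frozen=True)
class ValidationParams:
    baseline_window_ms: tuple[float, float] = (-300.0, 0.0)     # [lo, hi)
    blink_exclusion_window_ms: tuple[float, float] = (-300.0, 150.0)  # [lo, hi]
    outlier_sd_multiplier: float = 3.0
    min_valid_fraction: float = 0.70
    min_values_for_recursion: int = 3

    def __post_init__(self) -> None:
        if self.baseline_window_ms[0] >= self.baseline_window_ms[1]:
            raise ValueError("baseline window ill-ordered")
        if self.outlier_sd_multiplier <= 0:
            raise ValueError("outlier_sd_multiplier must be positive")
        if not 0.0 < self.min_valid_fraction <= 1.0:
            raise ValueError("min_valid_fraction must be in (0, 1]")


def baseline_position(trial: GazeTrial, params: ValidationParams = ValidationParams()
                      ) -> tuple[float, float] | None:
    """Mean degree position of valid samples in the pre-stimulus window.

    Returns None when no valid baseline sample exists (the trial is then
    flagged as blink-contaminated by :func:`validate_trials`).
    """
    lo, hi = params.baseline_window_ms
    t = trial.t_ms
    sel = (t >= lo) & (t < hi) & trial.valid
    if not sel.any():
        return None
    x_deg, y_deg = trial.positions_deg()
    return float(x_deg[sel].mean()), float(y_deg[sel].mean())


def recursive_outlier_mask(values: Sequence[float], multiplier: float = 3.0,
                           min_n: int = 3) -> np.ndarray:
    """Boolean mask of recursively detected extreme values.

    Each iteration sets aside one instance of the current min and max,
    computes mean and sample SD of the remainder, and permanently flags an
    extreme (all tied instances of it) when it deviates more than
    ``multiplier`` x SD from that mean.  Stops when nothing new is flagged,
    when fewer than ``min_n`` values remain, or when the SD would be
    computed from fewer than two values.
    """
    v = np.asarray(values, dtype=float)
    mask = np.zeros(len(v), dtype=bool)
    while True:
        active = np.flatnonzero(~mask)
        if len(active) < min_n:
            break
        vals = v[active]
        vmin, vmax = vals.min(), vals.max()
        if vmin == vmax:
            break
        # set aside ONE instance of each extreme for the reference statistics
        keep = np.ones(len(vals), dtype=bool)
        keep[int(np.argmin(vals))] = False
        keep[int(np.argmax(vals))] = False
        rest = vals[keep]
        if len(rest) < 2:
            break
        mean, sd = rest.mean(), rest.std(ddof=1)
        flagged = False
        if abs(vmin - mean) > multiplier * sd:
            mask[active[vals == vmin]] = True
            flagged = True
        if abs(vmax - mean) > multiplier * sd:
            mask[active[vals == vmax]] = True
            flagged = True
        if not flagged:
            break
    return mask


def _blink_in_window(blinks: Iterable[OculomotorEvent],
                     window: tuple[float, float]) -> bool:
    lo, hi = window
    return any(b.onset_ms <= hi and b.offset_ms >= lo for b in blinks)


def validate_trials(trials: Sequence[GazeTrial],
                    blinks_per_trial: Sequence[list[OculomotorEvent]],
                    params: ValidationParams = ValidationParams()) -> pd.DataFrame:
    """Apply the exclusion rules; one row per trial.

    Baseline-outlier detection runs separately on the x and y baseline
    coordinates of each experimental block within each participant.
    Returns columns participant, block, trial, baseline_x_deg, baseline_y_deg,
    valid, exclusion_reason.
    """
    rows = []
    for trial, blinks in zip(trials, blinks_per_trial, strict=True):
        base = baseline_position(trial, params)
        block = trial.design.block if trial.design is not None else 1
        rows.append({
            "participant": trial.participant_id,
            "block": block,
            "trial": trial.trial_index,
            "baseline_x_deg": np.nan if base is None else base[0],
            "baseline_y_deg": np.nan if base is None else base[1],
            "blink_in_window": base is None or _blink_in_window(
                blinks, params.blink_exclusion_window_ms),
        })
    df = pd.DataFrame(rows)

    df["baseline_outlier_x"] = False
    df["baseline_outlier_y"] = False
    for _, grp in df.groupby(["participant", "block"], sort=False):
        ok = grp["baseline_x_deg"].notna()
        idx = grp.index[ok]
        if len(idx):
            df.loc[idx, "baseline_outlier_x"] = recursive_outlier_mask(
                grp.loc[idx, "baseline_x_deg"].to_numpy(),
                params.outlier_sd_multiplier, params.min_values_for_recursion)
            df.loc[idx, "baseline_outlier_y"] = recursive_outlier_mask(
                grp.loc[idx, "baseline_y_deg"].to_numpy(),
                params.outlier_sd_multiplier, params.min_values_for_recursion)

    reason = np.where(df["blink_in_window"], "blink_in_window",
                      np.where(df["baseline_outlier_x"], "baseline_outlier_x",
                               np.where(df["baseline_outlier_y"], "baseline_outlier_y",
                                        "none")))
    df["exclusion_reason"] = reason
    df["valid"] = reason == "none"
    return df.drop(columns=["blink_in_window", "baseline_outlier_x", "baseline_outlier_y"])


def filter_participants(outcomes: pd.DataFrame,
                        params: ValidationParams = ValidationParams()
                        ) -> tuple[list[str], list[str], pd.DataFrame]:
    """Split participants into kept/excluded by the valid-trial fraction.

    Exclusion is strict: a participant is dropped iff the fraction of valid
    trials over ALL their trials is < ``min_valid_fraction``.
    """
    frac = outcomes.groupby("participant")["valid"].agg(
        valid_fraction="mean", n_valid="sum", n_total="size").reset_index()
    excluded = frac.loc[frac["valid_fraction"] < params.min_valid_fraction,
                        "participant"].astype(str).tolist()
    kept = frac.loc[frac["valid_fraction"] >= params.min_valid_fraction,
                    "participant"].astype(str).tolist()
    return kept, excluded, frac
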