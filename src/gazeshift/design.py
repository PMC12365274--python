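"""Factorial trial-sequence scheduler for the two experiments.

Builds balanced, randomized trial lists crossing emotional expression,
orientation, presentation time and initial-fixation location, with the two
procedural constraints used in the studies: the same expression never occurs
on more than ``max_run_length`` successive trials, and every (synthetic)
stimulus identifier is used at most once per participant, sex-balanced
within each condition cell.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DesignSpec",
    "TrialDesign",
    "InfeasibleDesignError",
    "build_design",
    "split_blocks",
    "designs_to_frame",
    "frame_to_designs",
]

EMOTIONS = ("fearful", "happy", "neutral")
SEXES = ("female", "male")


class InfeasibleDesignError(ValueError):
    """The requested design cannot satisfy its constraints."""


@dataclass(frozen=True)
class DesignSpec:
    """Factor structure of one experimental session (or block type)."""

    emotions: tuple[str, ...] = EMOTIONS
    orientations: tuple[str, ...] = ("upright", "inverted")
    presentation_times_ms: tuple[int, ...] = (50, 150)
    fixation_locations: tuple[str, ...] = ("eyes", "mouth")
    trials_per_cell: int = 12
    faces_per_sex_per_cell: int = 6
    max_run_length: int = 3
    blocks: int = 3

    def __post_init__(self) -> None:
        if self.trials_per_cell <= 0 or self.max_run_length <= 0 or self.blocks <= 0:
            raise InfeasibleDesignError("trials_per_cell, max_run_length and blocks must be positive")
        if self.faces_per_sex_per_cell:
            if self.trials_per_cell != len(SEXES) * self.faces_per_sex_per_cell:
                raise InfeasibleDesignError(
                    "sex balancing requires trials_per_cell == 2 * faces_per_sex_per_cell")
        if self.total_trials % self.blocks:
            raise InfeasibleDesignError(
                f"{self.total_trials} trials cannot be split into {self.blocks} equal blocks")

    @property
    def cells(self) -> list[tuple[str, str, int, str]]:
        return list(itertools.product(self.emotions, self.orientations,
                                      self.presentation_times_ms, self.fixation_locations))

    @property
    def total_trials(self) -> int:
        return len(self.cells) * self.trials_per_cell

    # canonical study designs -------------------------------------------------
    @classmethod
    def exp1(cls) -> "DesignSpec":
        """3 emotions x 2 orientations x 2 presentation times x 2 fixations, 12/cell."""
        return cls()

    @classmethod
    def exp2_block1(cls) -> "DesignSpec":
        """3 emotions x 2 fixations (eyes/mouth), 18/cell, 108 trials, one block."""
        return cls(orientations=("upright",), presentation_times_ms=(150,),
                   fixation_locations=("eyes", "mouth"), trials_per_cell=18,
                   faces_per_sex_per_cell=9, blocks=1)

    @classmethod
    def exp2_block2(cls) -> "DesignSpec":
        """3 emotions x 6 fixation locations, 10/cell, 180 trials in two sessions."""
        return cls(orientations=("upright",), presentation_times_ms=(150,),
                   fixation_locations=("left_eye", "glabella", "right_eye",
                                       "left_cheek", "mouth_center", "right_cheek"),
                   trials_per_cell=10, faces_per_sex_per_cell=5, blocks=2)


@dataclass(frozen=True)
class TrialDesign:
    """One scheduled trial."""

    participant_id: str
    block: int
    trial_index: int
    emotion: str
    orientation: str
    presentation_time_ms: int
    initial_fixation: str
    stimulus_id: str
    stimulus_sex: str

    @property
    def cell(self) -> tuple[str, str, int, str]:
        return (self.emotion, self.orientation, self.presentation_time_ms,
                self.initial_fixation)


def _max_run(emotions: Sequence[str]) -> int:
    longest = run = 1
    for prev, cur in zip(emotions, emotions[1:]):
        run = run + 1 if cur == prev else 1
        longest = max(longest, run)
    return longest if emotions else 0


def _runs_ok(emotions: Sequence[str], cap: int) -> bool:
    return _max_run(emotions) <= cap


def _constrained_insertion(items: list, cap: int, rng: np.random.Generator) -> list:
    """Greedy randomized sequencing that never extends a run past ``cap``.

    Retries from scratch on dead ends; feasibility is checked by the caller.
    """
    for _ in range(1000):
        pool = list(items)
        rng.shuffle(pool)
        out: list = []
        stuck = False
        while pool:
            tail = out[-cap:] if len(out) >= cap else out
            blocked = tail[-1].emotion if len(tail) == cap and len({t.emotion for t in tail}) == 1 else None
            candidates = [i for i, it in enumerate(pool) if it.emotion != blocked]
            if not candidates:
                stuck = True
                break
            out.append(pool.pop(candidates[int(rng.integers(len(candidates)))]))
        if not stuck:
            return out
    raise InfeasibleDesignError("run-length constraint unsatisfiable (insertion fallback failed)")


def build_design(spec: DesignSpec, seed: int, participant_id: str = "p01",
                 max_shuffle_attempts: int = 10_000) -> list[TrialDesign]:
    """Build one participant's randomized trial sequence.

    Each condition cell contributes exactly ``trials_per_cell`` trials with
    unique sex-balanced stimulus identifiers; the sequence is a uniform random
    shuffle re-drawn until no expression runs longer than ``max_run_length``
    (constrained insertion as a fallback), then cut into equal blocks.
    """
    # feasibility of the run-length cap for the emotion multiset
    per_emotion = spec.total_trials // len(spec.emotions)
    others = spec.total_trials - per_emotion
    if per_emotion > spec.max_run_length * (others + 1):
        raise InfeasibleDesignError(
            f"run-length cap {spec.max_run_length} infeasible: {per_emotion} trials of one "
            f"expression against {others} others")

    rng = np.random.default_rng(seed)
    counters: dict[tuple[str, str], int] = {}
    trials: list[TrialDesign] = []
    for emotion, orientation, pt, fixation in spec.cells:
        if spec.faces_per_sex_per_cell:
            sexes = [s for s in SEXES for _ in range(spec.faces_per_sex_per_cell)]
        else:
            sexes = [SEXES[i % 2] for i in range(spec.trials_per_cell)]
        for sex in sexes:
            k = counters.get((emotion, sex), 0)
            counters[(emotion, sex)] = k + 1
            trials.append(TrialDesign(participant_id, 0, 0, emotion, orientation,
                                      pt, fixation, f"{emotion}_{sex}_{k:03d}", sex))

    order = None
    for _ in range(max_shuffle_attempts):
        perm = rng.permutation(len(trials))
        cand = [trials[i] for i in perm]
        if _runs_ok([t.emotion for t in cand], spec.max_run_length):
            order = cand
            break
    if order is None:
        order = _constrained_insertion(trials, spec.max_run_length, rng)

    per_block = spec.total_trials // spec.blocks
    return [replace(t, block=i // per_block + 1, trial_index=i + 1)
            for i, t in enumerate(order)]


def split_blocks(design: Sequence[TrialDesign], blocks: int) -> list[list[TrialDesign]]:
    """Order-preserving partition into equal-sized blocks."""
    n = len(design)
    if blocks <= 0 or n % blocks:
        raise InfeasibleDesignError(f"{n} trials not divisible into {blocks} blocks")
    per = n // blocks
    return [list(design[i * per:(i + 1) * per]) for i in range(blocks)]


DESIGN_COLUMNS = ["participant", "block", "trial", "emotion", "orientation",
                  "presentation_time_ms", "initial_fixation", "stimulus_id", "stimulus_sex"]


def designs_to_frame(designs: Sequence[TrialDesign]) -> pd.DataFrame:
    return pd.DataFrame(
        [(t.participant_id, t.block, t.trial_index, t.emotion, t.orientation,
          t.presentation_time_ms, t.initial_fixation, t.stimulus_id, t.stimulus_sex)
         for t in designs], columns=DESIGN_COLUMNS)


def frame_to_designs(df: pd.DataFrame) -> list[TrialDesign]:
    missing = [c for c in DESIGN_COLUMNS if c not in df.columns]
    if missing:
        raise InfeasibleDesignError(f"design table missing columns {missing}")
    return [TrialDesign(str(r.participant), int(r.block), int(r.trial), r.emotion,
                        r.orientation, int(r.presentation_time_ms), r.initial_fixation,
                        r.stimulus_id, r.stimulus_sex)
            for r in df.itertuples()]
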