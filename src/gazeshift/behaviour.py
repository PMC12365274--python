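"""Confusion tables and Wagner-style unbiased hit rates.

The unbiased hit rate Hu for an emotion is the squared number of correct
classifications divided by the product of the number of stimuli presented
with that emotion and the number of trials on which the participant chose
that emotion.  It equals hit rate x precision, so it corrects the raw hit
rate for individual response biases, is 1 only for perfect one-to-one
performance, and is bounded above by the raw hit rate.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .design import EMOTIONS

__all__ = ["confusion_from_outcomes", "unbiased_hit_rate", "hu_table"]


def unbiased_hit_rate(hits: int, n_presented: int, n_chosen: int) -> float:
    """Hu = hits^2 / (n_presented * n_chosen); 0 when the category was never chosen."""
    if n_presented <= 0:
        return float("nan")
    if n_chosen == 0:
        return 0.0
    return (hits * hits) / (n_presented * n_chosen)


def confusion_from_outcomes(outcomes: pd.DataFrame,
                            cell_factors: Sequence[str] = ("orientation",
                                                           "presentation_time_ms",
                                                           "initial_fixation"),
                            emotions: Sequence[str] = EMOTIONS,
                            respect_validity: bool = True) -> pd.DataFrame:
    """Long-format stimulus x response confusion counts per participant and cell.

    ``cell_factors`` define the condition cell (the emotion factor is the
    confusion row).  With ``respect_validity`` (default) the gaze-validity
    mask is applied, mirroring the eye-movement analysis; otherwise every
    responded trial counts.  Trials without a recorded response are dropped.
    """
    df = outcomes.dropna(subset=["response"])
    if respect_validity and "valid" in df.columns:
        df = df[df["valid"]]
    unknown = set(df["response"]) - set(emotions)
    if unknown:
        raise ValueError(f"response labels outside the emotion set: {sorted(unknown)}")

    keys = ["participant", *cell_factors]
    counts = (df.groupby([*keys, "emotion", "response"], sort=True)
              .size().rename("count").reset_index())
    # densify: every stimulus x response combination present, zero-filled
    cells = df.groupby(keys, sort=True).size().reset_index()[keys]
    grid = cells.merge(pd.DataFrame(
        [(e, r) for e in emotions for r in emotions], columns=["emotion", "response"]),
        how="cross") if len(cells) else counts.iloc[:0]
    if len(cells):
        counts = grid.merge(counts, on=[*keys, "emotion", "response"], how="left") \
            .fillna({"count": 0})
        counts["count"] = counts["count"].astype(int)
    return counts


def hu_table(confusion: pd.DataFrame,
             cell_factors: Sequence[str] = ("orientation", "presentation_time_ms",
                                            "initial_fixation")) -> pd.DataFrame:
    """Unbiased hit rate per participant x cell x emotion from confusion counts."""
    keys = ["participant", *cell_factors]
    rows = []
    for cell, grp in confusion.groupby(keys, sort=True):
        mat = grp.pivot_table(index="emotion", columns="response",
                              values="count", aggfunc="sum", fill_value=0)
        presented = mat.sum(axis=1)
        chosen = mat.sum(axis=0)
        for emo in mat.index:
            hits = int(mat.loc[emo, emo]) if emo in mat.columns else 0
            rows.append(dict(zip(keys, cell if isinstance(cell, tuple) else (cell,)))
                        | {"emotion": emo,
                           "n_presented": int(presented[emo]),
                           "n_chosen": int(chosen.get(emo, 0)),
                           "hits": hits,
                           "hu": unbiased_hit_rate(hits, int(presented[emo]),
                                                   int(chosen.get(emo, 0)))})
    return pd.DataFrame(rows)
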