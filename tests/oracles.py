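"""Independent brute-force oracles, coded loop-wise from the procedure text,
kept deliberately separate from the package implementation."""

from __future__ import annotations

import math


def recursive_outliers_bruteforce(values, multiplier=3.0, min_n=3):
    """Literal transcription of the recursive baseline-outlier procedure.

    Working on a plain list: temporarily remove the minimum and the maximum
    (one instance each), take mean and sample SD of what is left, permanently
    remove min/max (with all tied duplicates) if they deviate by more than
    ``multiplier`` SDs, repeat until an iteration removes nothing.
    """
    flagged = [False] * len(values)
    while True:
        active = [i for i, f in enumerate(flagged) if not f]
        if len(active) < min_n:
            break
        vals = [values[i] for i in active]
        lo, hi = min(vals), max(vals)
        if lo == hi:
            break
        rest = list(vals)
        rest.remove(lo)
        rest.remove(hi)
        if len(rest) < 2:
            break
        m = sum(rest) / len(rest)
        sd = math.sqrt(sum((v - m) ** 2 for v in rest) / (len(rest) - 1))
        removed_any = False
        if abs(lo - m) > multiplier * sd:
            for i in active:
                if values[i] == lo:
                    flagged[i] = True
            removed_any = True
        if abs(hi - m) > multiplier * sd:
            for i in active:
                if values[i] == hi:
                    flagged[i] = True
            removed_any = True
        if not removed_any:
            break
    return flagged
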