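"""Within-subject (repeated-measures) statistics.

``RepeatedMeasuresAnova`` is a statsmodels-style model object: build it from
a long-format DataFrame, call :meth:`fit`, and get an
:class:`RMAnovaResults` carrying F ratios, Greenhouse-Geisser epsilons,
corrected p values and partial eta squared for every main effect and
interaction of the within-subject factors.

The decomposition works on the n x K wide matrix of one score per subject
and cell.  For each effect, cells are projected onto the Kronecker product
of orthonormal (Helmert) contrasts of the involved factors and the
normalized mean vector of the others; the projected scores give

    SS_effect = n * ||mean||^2,   SS_error = sum of squared deviations,
    F = (SS_effect/df1) / (SS_error/df2),  df1 = prod(k_f - 1), df2 = (n-1) df1,

and the sphericity correction

    eps_GG = tr(Sigma)^2 / (df1 * tr(Sigma^2)),

with Sigma the sample covariance of the projected scores.  Corrected p
values use an F distribution with both dfs multiplied by eps.  Partial eta
squared is SS_effect / (SS_effect + SS_error).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.linalg import helmert

__all__ = [
    "RepeatedMeasuresAnova",
    "RMAnovaResults",
    "EffectResult",
    "PosthocResult",
    "paired_posthocs",
    "holm_adjust",
    "PowerSpec",
    "PowerResult",
    "simulate_power",
]


class IncompleteDesignError(ValueError):
    """The subject x cell table has missing or duplicated cells."""


# ---------------------------------------------------------------------------
# core decomposition on the wide matrix
# ---------------------------------------------------------------------------

def _effect_stats(Y: np.ndarray, levels: Sequence[int], subset: Sequence[bool]):
    """F, dfs, eps, SS for one within-subject effect.

    ``Y`` is subjects x cells with cells ordered by the factor product
    (last factor fastest); ``subset`` flags the factors in the effect.
    """
    n = Y.shape[0]
    M = np.ones((1, 1))
    for k, inc in zip(levels, subset):
        M = np.kron(M, helmert(k, full=False) if inc else np.full((1, k), 1.0 / math.sqrt(k)))
    Z = Y @ M.T                                   # n x d projected scores
    d = Z.shape[1]
    zbar = Z.mean(axis=0)
    ss_eff = n * float(zbar @ zbar)
    R = Z - zbar
    ss_err = float((R * R).sum())
    df1 = d
    df2 = (n - 1) * d
    ms_err = ss_err / df2
    F = (ss_eff / df1) / ms_err if ms_err > 0 else math.inf
    if d == 1:
        eps = 1.0
    else:
        sigma = (R.T @ R) / (n - 1)
        tr = float(np.trace(sigma))
        tr2 = float((sigma * sigma.T).sum())      # tr(Sigma^2), Sigma symmetric
        eps = tr * tr / (d * tr2) if tr2 > 0 else 1.0
        eps = min(1.0, max(eps, 1.0 / d))
    p_unc = float(sps.f.sf(F, df1, df2))
    p_gg = float(sps.f.sf(F, eps * df1, eps * df2))
    return F, df1, df2, eps, p_unc, p_gg, ss_eff, ss_err


@dataclass(frozen=True)
class EffectResult:
    effect: str
    F: float
    df_num: float
    df_den: float
    gg_epsilon: float
    p_uncorrected: float
    p_gg: float
    partial_eta_sq: float
    ss_effect: float
    ss_error: float


class RepeatedMeasuresAnova:
    """Fully within-subject factorial ANOVA model.

    Parameters
    ----------
    data : long DataFrame with one row per subject x cell.
    dv : name of the dependent-variable column.
    within : names of the within-subject factor columns.
    subject : name of the subject identifier column.
    """

    def __init__(self, data: pd.DataFrame, dv: str, within: Sequence[str], subject: str):
        self.dv = dv
        self.within = list(within)
        self.subject = subject

        df = data.loc[:, [subject, *self.within, dv]].copy()
        if df[dv].isna().any():
            bad = df.loc[df[dv].isna(), [subject, *self.within]]
            raise IncompleteDesignError(
                f"missing {dv} values for cells:\n{bad.to_string(index=False)}")
        self.levels = {f: list(pd.unique(df[f])) for f in self.within}
        cells = list(itertools.product(*[self.levels[f] for f in self.within]))

        wide = df.pivot_table(index=subject, columns=self.within, values=dv,
                              aggfunc="mean", observed=True)
        counts = df.groupby([subject, *self.within], observed=True).size()
        if (counts != 1).any():
            raise IncompleteDesignError("duplicated subject x cell rows")
        want = cells if len(self.within) > 1 else [c[0] for c in cells]
        missing = [c for c in want if c not in wide.columns]
        if missing:
            raise IncompleteDesignError(f"missing cells: {missing}")
        wide = wide.loc[:, want]
        if wide.isna().any().any():
            bad = wide.columns[wide.isna().any()].tolist()
            raise IncompleteDesignError(f"cells missing for some subjects: {bad}")
        if wide.shape[0] < 2:
            raise IncompleteDesignError("need at least 2 subjects")
        self.subjects = wide.index.tolist()
        self.endog = wide.to_numpy(dtype=float)

    def fit(self) -> "RMAnovaResults":
        ks = [len(self.levels[f]) for f in self.within]
        effects = []
        for r in range(1, len(self.within) + 1):
            for combo in itertools.combinations(range(len(self.within)), r):
                subset = [i in combo for i in range(len(self.within))]
                F, df1, df2, eps, p_unc, p_gg, ss_e, ss_r = _effect_stats(
                    self.endog, ks, subset)
                effects.append(EffectResult(
                    " * ".join(self.within[i] for i in combo),
                    F, df1, df2, eps, p_unc, p_gg,
                    ss_e / (ss_e + ss_r) if ss_e + ss_r > 0 else 0.0,
                    ss_e, ss_r))
        return RMAnovaResults(self, effects)


@dataclass
class RMAnovaResults:
    """Fitted within-subject ANOVA; effects in main-effects-first order."""

    model: RepeatedMeasuresAnova
    effects: list[EffectResult]

    @property
    def table(self) -> pd.DataFrame:
        return pd.DataFrame([e.__dict__ for e in self.effects])

    def effect(self, name: str) -> EffectResult:
        for e in self.effects:
            if e.effect == name:
                return e
        raise KeyError(f"no effect named {name!r}; have "
                       f"{[e.effect for e in self.effects]}")

    def ss_total_check(self) -> tuple[float, float]:
        """(sum of decomposed SS, total SS about the grand mean).

        The two agree because the between-subject stratum plus every
        effect/error pair tile the orthogonal complement of the grand mean.
        """
        Y = self.model.endog
        grand = Y.mean()
        total = float(((Y - grand) ** 2).sum())
        subj = Y.shape[1] * float(((Y.mean(axis=1) - grand) ** 2).sum())
        return subj + sum(e.ss_effect + e.ss_error for e in self.effects), total

    def apa(self, name: str) -> str:
        e = self.effect(name)
        p = "< .001" if e.p_gg < 0.001 else f"= {e.p_gg:.3f}"
        s = f"F({e.df_num:g}, {e.df_den:g}) = {e.F:.2f}, "
        if e.gg_epsilon < 1.0:
            s += f"eps = {e.gg_epsilon:.2f}, "
        return s + f"p {p}, eta_p^2 = {e.partial_eta_sq:.2f}"

    def summary(self) -> str:
        lines = [f"Repeated-measures ANOVA: {self.model.dv} ~ "
                 f"{' x '.join(self.model.within)}  (n = {len(self.model.subjects)})",
                 "-" * 78,
                 f"{'effect':<38}{'F':>8}{'df':>12}{'eps':>6}{'p(GG)':>9}{'eta_p^2':>8}"]
        for e in self.effects:
            lines.append(f"{e.effect:<38}{e.F:>8.2f}"
                         f"{f'({e.df_num:g},{e.df_den:g})':>12}{e.gg_epsilon:>6.2f}"
                         f"{e.p_gg:>9.4f}{e.partial_eta_sq:>8.3f}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# posthoc paired comparisons
# ---------------------------------------------------------------------------

def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Step-down Holm adjustment (monotone, clipped at 1)."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj


@dataclass(frozen=True)
class PosthocResult:
    comparison: str
    t: float
    df: int
    p_raw: float
    p_holm: float
    cohen_d: float
    degenerate: bool = False


def paired_posthocs(data: pd.DataFrame, dv: str, subject: str, condition: str,
                    comparisons: Sequence[tuple] | None = None) -> pd.DataFrame:
    """Holm-corrected paired t tests between condition levels.

    ``comparisons`` lists (level_a, level_b) pairs forming one correction
    family; all pairwise comparisons by default.  Cohen's d uses the SD of
    the paired differences.  All-zero differences give t = 0, d = 0, p = 1;
    zero-variance nonzero differences are flagged degenerate with NaN t.
    """
    wide = data.pivot_table(index=subject, columns=condition, values=dv,
                            aggfunc="mean", observed=True)
    if comparisons is None:
        lev = list(wide.columns)
        comparisons = list(itertools.combinations(lev, 2))
    rows = []
    for a, b in comparisons:
        pair = wide[[a, b]].dropna()
        diff = (pair[a] - pair[b]).to_numpy()
        n = len(diff)
        sd = diff.std(ddof=1) if n > 1 else 0.0
        mean = diff.mean()
        if sd == 0.0:
            if mean == 0.0:
                t_val, p_raw, d, degen = 0.0, 1.0, 0.0, False
            else:
                t_val, p_raw, d, degen = math.nan, math.nan, math.nan, True
        else:
            t_val = mean / (sd / math.sqrt(n))
            p_raw = float(2.0 * sps.t.sf(abs(t_val), n - 1))
            d = mean / sd
            degen = False
        rows.append({"comparison": f"{a} vs {b}", "t": t_val, "df": n - 1,
                     "p_raw": p_raw, "cohen_d": d, "degenerate": degen})
    out = pd.DataFrame(rows)
    ok = out["p_raw"].notna()
    out["p_holm"] = np.nan
    out.loc[ok, "p_holm"] = holm_adjust(out.loc[ok, "p_raw"].to_numpy())
    return out[["comparison", "t", "df", "p_raw", "p_holm", "cohen_d", "degenerate"]]


# ---------------------------------------------------------------------------
# simulation-based power
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PowerSpec:
    """Multivariate-normal generating model for a within-subject design.

    ``within`` maps factor names to level tuples (cells ordered by their
    product, last factor fastest); ``means`` and ``sds`` are per-cell,
    ``correlation`` a common inter-cell correlation or a full matrix.
    """

    within: Mapping[str, tuple]
    means: Sequence[float]
    sds: Sequence[float] | float
    correlation: float | np.ndarray
    n_participants: int
    effect: str
    n_reps: int = 1000
    alpha: float = 0.05
    seed: int = 0

    def covariance(self) -> np.ndarray:
        k = len(self.means)
        sds = np.broadcast_to(np.asarray(self.sds, dtype=float), (k,))
        if np.isscalar(self.correlation):
            R = np.full((k, k), float(self.correlation))
            np.fill_diagonal(R, 1.0)
        else:
            R = np.asarray(self.correlation, dtype=float)
        cov = np.outer(sds, sds) * R
        if np.linalg.eigvalsh(cov).min() < -1e-10:
            raise ValueError("covariance matrix is not positive semi-definite")
        return cov

    def __post_init__(self) -> None:
        k = int(np.prod([len(v) for v in self.within.values()]))
        if len(self.means) != k:
            raise ValueError(f"means has {len(self.means)} entries; design has {k} cells")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")


@dataclass(frozen=True)
class PowerResult:
    power: float
    ci_low: float
    ci_high: float
    n_reps: int
    alpha: float

    def __str__(self) -> str:
        return (f"power = {self.power:.3f} "
                f"(95% MC CI [{self.ci_low:.3f}, {self.ci_high:.3f}], "
                f"{self.n_reps} replicates, alpha = {self.alpha})")


def simulate_power(spec: PowerSpec) -> PowerResult:
    """Monte-Carlo power of the GG-corrected test for one effect."""
    rng = np.random.default_rng(spec.seed)
    cov = spec.covariance()
    chol = np.linalg.cholesky(cov + 1e-12 * np.eye(len(cov)))
    means = np.asarray(spec.means, dtype=float)
    names = list(spec.within)
    ks = [len(spec.within[f]) for f in names]
    target = [f.strip() for f in spec.effect.split("*")]
    subset = [f in target for f in names]
    unknown = set(target) - set(names)
    if unknown:
        raise ValueError(f"effect names unknown factors {sorted(unknown)}")

    hits = 0
    for _ in range(spec.n_reps):
        Y = means + rng.standard_normal((spec.n_participants, len(means))) @ chol.T
        F, d1, d2, eps, p_unc, p_gg, *_ = _effect_stats(Y, ks, subset)
        hits += p_gg < spec.alpha
    p_hat = hits / spec.n_reps
    se = math.sqrt(max(p_hat * (1 - p_hat), 1e-12) / spec.n_reps)
    return PowerResult(p_hat, max(0.0, p_hat - 1.96 * se),
                       min(1.0, p_hat + 1.96 * se), spec.n_reps, spec.alpha)
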