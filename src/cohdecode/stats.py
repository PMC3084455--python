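"""Voxel-bias maps and group-level inference.

Bias maps are descriptive: the absolute two-sample t per voxel comparing
clockwise and anticlockwise blocks across *all* runs (no cross-validation),
separately per context, with the fraction of voxels significant at p<0.05
as the summary. Group inference is a one-tailed one-sample t test of
per-participant accuracies against chance (df = n−1), a classical
repeated-measures ANOVA for the univariate control analyses, and an exact
binomial test on pooled cross-validated outcomes per participant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as st
from statsmodels.stats.anova import AnovaRM

from .decoding import pooled_t, select_context
from .preprocess import SampleSet
from .stimulus import parse_condition


@dataclass
class BiasMap:
    abs_t: np.ndarray
    df: int
    p_per_voxel: np.ndarray
    context: str


@dataclass
class GroupTestResult:
    statistic: float
    df: int
    p: float
    n_subjects: int
    tail: str
    effect_direction: str
    degenerate: bool = False
    note: str = ""

    def report(self) -> str:
        return f"t({self.df}) = {self.statistic:.2f}, p = {self.p:.3f} ({self.tail})"


def voxel_bias_map(samples: SampleSet, context: str) -> BiasMap:
    """Per-voxel |t| for clockwise vs. anticlockwise within one context,
    using all runs (descriptive, deliberately not cross-validated)."""
    ss = select_context(samples, context)
    signs = np.array([parse_condition(l)[1] for l in ss.labels])
    a = ss.patterns[signs > 0]   # anticlockwise
    b = ss.patterns[signs < 0]   # clockwise
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 samples per direction")
    t = pooled_t(a, b)
    df = len(a) + len(b) - 2
    with np.errstate(invalid="ignore"):
        p = 2.0 * st.t.sf(np.abs(t), df)
    p = np.where(np.isinf(t), np.finfo(float).tiny, p)
    return BiasMap(abs_t=np.abs(t), df=df, p_per_voxel=p, context=context)


def proportion_biased(bias_map: BiasMap, alpha: float = 0.05) -> float:
    """Fraction of voxels with a significant direction bias (p < alpha)."""
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    if bias_map.p_per_voxel.size == 0:
        raise ValueError("empty bias map")
    return float(np.mean(bias_map.p_per_voxel < alpha))


def one_sample_t_vs_chance(accuracies, chance: float = 0.5,
                           tail: str = "greater") -> GroupTestResult:
    """One-sample t of per-participant accuracies vs. chance, df = n − 1."""
    x = np.asarray(accuracies, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 participants")
    mean = x.mean()
    sd = x.std(ddof=1)
    direction = "above" if mean > chance else ("below" if mean < chance else "at")
    if sd == 0:
        return GroupTestResult(statistic=np.nan, df=n - 1, p=np.nan, n_subjects=n,
                               tail=tail, effect_direction=direction, degenerate=True,
                               note="zero variance across participants; t undefined")
    t = (mean - chance) / (sd / np.sqrt(n))
    df = n - 1
    if tail == "greater":
        p = st.t.sf(t, df)
    elif tail == "less":
        p = st.t.cdf(t, df)
    elif tail == "two-sided":
        p = 2.0 * st.t.sf(abs(t), df)
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return GroupTestResult(statistic=float(t), df=df, p=float(p), n_subjects=n,
                           tail=tail, effect_direction=direction)


def within_subject_anova(cell_table: pd.DataFrame, factors,
                         subject: str = "subject",
                         value: str = "value") -> pd.DataFrame:
    """Classical repeated-measures ANOVA on a complete balanced design.

    Error term for each effect is its interaction with subjects; no
    sphericity correction (uncorrected dfs are reported). Returns one row
    per main effect / interaction with F, df_num, df_den and p.
    """
    factors = list(factors)
    counts = cell_table.groupby([subject] + factors, observed=True).size()
    if (counts != 1).any():
        raise ValueError("design must be complete and balanced (one value per cell)")
    if (cell_table.groupby(subject)[value].nunique() == 1).all():
        # all cells equal within every subject: every effect and its error
        # term are exactly zero, so F is 0/0; report F = 0 by convention
        n_sub = cell_table[subject].nunique()
        levels = {f: cell_table[f].nunique() for f in factors}
        rows = []
        import itertools as _it
        for k in range(1, len(factors) + 1):
            for eff in _it.combinations(factors, k):
                df_num = int(np.prod([levels[f] - 1 for f in eff]))
                rows.append({"effect": ":".join(eff), "F": 0.0, "df_num": df_num,
                             "df_den": df_num * (n_sub - 1), "p": 1.0})
        return pd.DataFrame(rows)
    res = AnovaRM(cell_table, depvar=value, subject=subject, within=factors).fit()
    tab = res.anova_table.rename(columns={
        "F Value": "F", "Num DF": "df_num", "Den DF": "df_den", "Pr > F": "p"})
    tab.index.name = "effect"
    return tab.reset_index()


def participant_binomial_test(per_sample_outcomes, chance: float = 0.5) -> float:
    """Exact one-tailed binomial p for a participant's pooled CV outcomes.

    CV folds are not strictly independent; this is a pragmatic
    per-participant significance summary (see docs).
    """
    outcomes = np.asarray(per_sample_outcomes, dtype=bool)
    n = outcomes.size
    if n == 0:
        raise ValueError("no outcomes")
    k = int(outcomes.sum())
    return float(st.binomtest(k, n, chance, alternative="greater").pvalue)


def accuracy_report(name: str, result: GroupTestResult) -> str:
    return f"{name}: {result.report()}, n = {result.n_subjects}"
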