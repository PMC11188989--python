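"""Inferential tests applied to the derived summary statistics.

Group comparisons use pooled-variance (Student) two-sample t-tests — with
3 participants x 5 phrases per cohort the samples are the 15 per-cohort
participant-phrase summaries and the pooled df is 28 — plus one-way ANOVA
with post-hoc Tukey HSD for the six-band comparison.  Welch's correction
is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .core_io import ValidationError

__all__ = ["TestResult", "TukeyComparison", "two_sample_t", "one_way_anova", "tukey_hsd"]


@dataclass
class GroupSummary:
    n: int
    mean: float
    sd: float


@dataclass
class TestResult:
    statistic: float
    df: float | tuple[float, float]
    p: float
    sided: str
    groups: list[GroupSummary] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "df": self.df,
            "p": self.p,
            "sided": self.sided,
            "groups": [vars(g) for g in self.groups],
        }


def _summaries(*samples: np.ndarray) -> list[GroupSummary]:
    return [GroupSummary(len(s), float(np.mean(s)), float(np.std(s, ddof=1))) for s in samples]


def two_sample_t(
    x: Sequence[float],
    y: Sequence[float],
    sided: str = "two",
    welch: bool = False,
) -> TestResult:
    """Two-sample t-test of mean(x) vs mean(y).

    ``sided``: "greater" tests mean(x) > mean(y), "less" the reverse,
    "two" is two-sided.  Pooled-variance Student t by default
    (df = n_x + n_y - 2); set ``welch`` for unequal variances.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValidationError("two_sample_t: need >= 2 observations per group")
    alternative = {"two": "two-sided", "greater": "greater", "less": "less"}.get(sided)
    if alternative is None:
        raise ValidationError(f"sided must be 'two', 'greater' or 'less', got {sided!r}")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        raise ValidationError("two_sample_t: zero pooled variance")
    res = sps.ttest_ind(x, y, equal_var=not welch, alternative=alternative)
    df = float(res.df) if welch else len(x) + len(y) - 2
    return TestResult(
        statistic=float(res.statistic),
        df=df,
        p=float(res.pvalue),
        sided=sided,
        groups=_summaries(x, y),
    )


def one_way_anova(groups: Sequence[Sequence[float]]) -> TestResult:
    """One-way fixed-effects ANOVA; F with (k - 1, N - k) df."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(len(g) < 2 for g in arrays):
        raise ValidationError("one_way_anova: need >= 2 groups with >= 2 observations each")
    if all(np.var(g, ddof=1) == 0 for g in arrays) and len({g.mean() for g in arrays}) <= 1:
        raise ValidationError("one_way_anova: all observations identical")
    stat, p = sps.f_oneway(*arrays)
    k = len(arrays)
    n_total = sum(len(g) for g in arrays)
    return TestResult(
        statistic=float(stat),
        df=(k - 1, n_total - k),
        p=float(p),
        sided="two",
        groups=_summaries(*arrays),
    )


@dataclass
class TukeyComparison:
    group_a: int
    group_b: int
    difference: float
    p_adj: float
    reject: bool


def tukey_hsd(groups: Sequence[Sequence[float]], alpha: float = 0.05) -> list[TukeyComparison]:
    """All-pairs Tukey HSD (studentized range) comparisons."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(len(g) < 2 for g in arrays):
        raise ValidationError("tukey_hsd: need >= 2 groups with >= 2 observations each")
    res = sps.tukey_hsd(*arrays)
    out = []
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            p = float(res.pvalue[i, j])
            out.append(
                TukeyComparison(
                    group_a=i,
                    group_b=j,
                    difference=float(np.mean(arrays[i]) - np.mean(arrays[j])),
                    p_adj=p,
                    reject=p < alpha,
                )
            )
    return out
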