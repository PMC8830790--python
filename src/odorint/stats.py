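"""Normality-branched group comparisons with star annotation.

The decision tree mirrors common practice in behavioral assays analyzed in
GraphPad Prism: every group is first checked for normality (D'Agostino-
Pearson omnibus test, with Shapiro-Wilk for very small samples).  If all
groups pass, the parametric branch is used — unpaired two-tailed t-test for
two groups, one-way ANOVA with Dunnett's multiple-comparisons test against
the control for three or more.  If any group fails, the nonparametric
branch is used — two-tailed Mann-Whitney U for two groups, Kruskal-Wallis
with Dunn's multiple-comparisons test for three or more.  Adjusted p-values
for the vs-control family are reported with significance stars at the
conventional thresholds (**** p<0.0001, *** p<0.001, ** p<0.01, * p<0.05).

Dunn's test is implemented directly (pairwise z statistics on the pooled
mid-ranks with tie correction, Bonferroni-adjusted over the vs-control
comparisons); Dunnett's test is delegated to :func:`scipy.stats.dunnett`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "SampleGroup",
    "ComparisonResult",
    "normality_check",
    "compare_two",
    "compare_many_vs_control",
    "star_annotation",
    "STAR_THRESHOLDS",
]

#: significance thresholds (strict inequality), most significant first
STAR_THRESHOLDS: tuple[tuple[float, str], ...] = (
    (0.0001, "****"),
    (0.001, "***"),
    (0.01, "**"),
    (0.05, "*"),
)

#: below this sample size the omnibus normality test is unreliable and
#: Shapiro-Wilk is used instead
_OMNIBUS_MIN_N = 8


@dataclass(frozen=True)
class SampleGroup:
    label: str
    values: np.ndarray
    is_control: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"group {self.label!r} contains non-finite values")

    @property
    def n(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class ComparisonResult:
    comparison: str
    test_name: str
    branch: str  # "parametric" or "nonparametric"
    statistic: float
    p_value: float
    adjusted: bool
    stars: str


def star_annotation(p: float) -> str:
    """Significance stars for a p-value (strict-inequality thresholds)."""
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p-value must lie in [0, 1], got {p}")
    for threshold, stars in STAR_THRESHOLDS:
        if p < threshold:
            return stars
    return "ns"


def _group_is_normal(g: SampleGroup, alpha: float) -> bool:
    if g.n < 3:
        raise ValueError(f"group {g.label!r}: need n >= 3 for a normality test")
    if np.ptp(g.values) == 0.0:
        return False  # constant sample: zero variance cannot be normal-tested
    if g.n < _OMNIBUS_MIN_N:
        p = sps.shapiro(g.values).pvalue
    else:
        with np.errstate(all="ignore"):
            p = sps.normaltest(g.values).pvalue
    return bool(p > alpha)


def normality_check(groups: Sequence[SampleGroup], alpha: float = 0.05) -> bool:
    """True iff every group individually passes the normality test at alpha."""
    if not groups:
        raise ValueError("no groups given")
    return all(_group_is_normal(g, alpha) for g in groups)


def compare_two(a: SampleGroup, b: SampleGroup, alpha: float = 0.05) -> ComparisonResult:
    """Two-group comparison: unpaired two-tailed t-test if both samples are
    normally distributed, otherwise two-tailed Mann-Whitney U."""
    for g in (a, b):
        if g.n < 3:
            raise ValueError(f"group {g.label!r}: need n >= 3")
    if np.ptp(a.values) == 0.0 and np.ptp(b.values) == 0.0:
        raise ValueError("both samples are constant; comparison is degenerate")
    if normality_check([a, b], alpha):
        res = sps.ttest_ind(a.values, b.values, alternative="two-sided")
        name, branch = "unpaired t-test", "parametric"
    else:
        res = sps.mannwhitneyu(a.values, b.values, alternative="two-sided")
        name, branch = "Mann-Whitney U", "nonparametric"
    p = float(res.pvalue)
    return ComparisonResult(
        comparison=f"{a.label} vs {b.label}",
        test_name=name,
        branch=branch,
        statistic=float(res.statistic),
        p_value=p,
        adjusted=False,
        stars=star_annotation(p),
    )


def _dunn_vs_control(
    groups: Sequence[SampleGroup], control_idx: int
) -> list[tuple[int, float, float]]:
    """Dunn's pairwise rank tests of each group against the control.

    Returns (group index, z statistic, Bonferroni-adjusted two-sided p) for
    every non-control group.  Uses pooled mid-ranks with the standard tie
    correction; the family for the adjustment is the k-1 vs-control
    comparisons.
    """
    values = np.concatenate([g.values for g in groups])
    sizes = [g.n for g in groups]
    ranks = sps.rankdata(values)
    big_n = len(values)
    # tie correction term
    _, counts = np.unique(values, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (12.0 * (big_n - 1))
    var_unit = big_n * (big_n + 1) / 12.0 - tie_term
    mean_ranks = []
    start = 0
    for n_i in sizes:
        mean_ranks.append(ranks[start : start + n_i].mean())
        start += n_i
    k = len(groups)
    m = k - 1  # comparisons in the family
    out = []
    for i in range(k):
        if i == control_idx:
            continue
        se = math.sqrt(var_unit * (1.0 / sizes[i] + 1.0 / sizes[control_idx]))
        z = (mean_ranks[i] - mean_ranks[control_idx]) / se
        p = 2.0 * sps.norm.sf(abs(z))
        out.append((i, z, min(1.0, p * m)))
    return out


def compare_many_vs_control(
    groups: Sequence[SampleGroup],
    control_label: str | None = None,
    alpha: float = 0.05,
) -> list[ComparisonResult]:
    """Each group against the control, with multiplicity adjustment.

    Parametric branch (all groups normal): one-way ANOVA followed by
    Dunnett's test.  Nonparametric branch: Kruskal-Wallis followed by Dunn's
    test with Bonferroni adjustment over the vs-control family.
    """
    if len(groups) < 3:
        raise ValueError("need at least 3 groups; use compare_two for 2")
    if control_label is None:
        controls = [i for i, g in enumerate(groups) if g.is_control]
    else:
        controls = [i for i, g in enumerate(groups) if g.label == control_label]
    if len(controls) != 1:
        raise ValueError(
            f"exactly one control group required, found {len(controls)}"
        )
    ctrl = controls[0]
    samples = [g.values for g in groups]
    others = [i for i in range(len(groups)) if i != ctrl]

    results: list[ComparisonResult] = []
    if normality_check(groups, alpha):
        dunnett_res = sps.dunnett(
            *[samples[i] for i in others], control=samples[ctrl]
        )
        for j, i in enumerate(others):
            p = float(dunnett_res.pvalue[j])
            results.append(
                ComparisonResult(
                    comparison=f"{groups[i].label} vs {groups[ctrl].label}",
                    test_name="ANOVA + Dunnett",
                    branch="parametric",
                    statistic=float(dunnett_res.statistic[j]),
                    p_value=p,
                    adjusted=True,
                    stars=star_annotation(p),
                )
            )
    else:
        sps.kruskal(*samples)  # omnibus; per-comparison inference is Dunn's
        for i, z, p in _dunn_vs_control(groups, ctrl):
            results.append(
                ComparisonResult(
                    comparison=f"{groups[i].label} vs {groups[ctrl].label}",
                    test_name="Kruskal-Wallis + Dunn",
                    branch="nonparametric",
                    statistic=z,
                    p_value=p,
                    adjusted=True,
                    stars=star_annotation(p),
                )
            )
    return results
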