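"""Group statistics: one-way ANOVA with Tukey post-hoc comparisons.

Measurements (EdU volumes or intensities) from treatment groups — e.g.
control and 1-, 3-, 7-days post lesion — are compared by one-way ANOVA;
pairwise differences are assessed with Tukey's HSD (the Tukey-Kramer
standard error for unequal group sizes), with significance at p < alpha
(default 0.05).  Pairwise records are emitted even when the omnibus test
is non-significant, flagged with the omnibus outcome, so consumers can
filter by their preferred convention.  Data are summarised as mean + SEM.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupSummary",
    "PairwiseResult",
    "GroupComparison",
    "mean_sem",
    "compare_groups",
]


def mean_sem(values: Sequence[float]) -> Tuple[float, float]:
    """Arithmetic mean and standard error of the mean.

    SEM uses the n-1 sample standard deviation; a single observation has
    SEM 0 by convention.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("mean_sem needs at least one value")
    mean = float(arr.mean())
    sem = float(arr.std(ddof=1) / math.sqrt(arr.size)) if arr.size > 1 else 0.0
    return mean, sem


@dataclass(frozen=True)
class GroupSummary:
    name: str
    n: int
    mean: float
    sem: float


@dataclass(frozen=True)
class PairwiseResult:
    group_a: str
    group_b: str
    mean_diff: float  # mean(group_b) - mean(group_a)
    p_adj: float
    significant: bool


@dataclass
class GroupComparison:
    """Outcome of a one-way ANOVA plus Tukey pairwise comparisons."""

    groups: List[GroupSummary]
    anova_f: float
    anova_p: float
    anova_significant: bool
    alpha: float
    pairwise: List[PairwiseResult] = field(default_factory=list)
    degenerate: bool = False  # zero variance everywhere: no test possible

    def pair(self, a: str, b: str) -> PairwiseResult:
        for rec in self.pairwise:
            if {rec.group_a, rec.group_b} == {a, b}:
                return rec
        raise KeyError(f"no pairwise record for ({a!r}, {b!r})")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group_a": [r.group_a for r in self.pairwise],
                "group_b": [r.group_b for r in self.pairwise],
                "mean_diff": [r.mean_diff for r in self.pairwise],
                "p_adj": [r.p_adj for r in self.pairwise],
                "significant": [r.significant for r in self.pairwise],
                "anova_F": self.anova_f,
                "anova_p": self.anova_p,
            }
        )


def compare_groups(
    data: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
) -> GroupComparison:
    """One-way ANOVA across groups with Tukey-Kramer pairwise comparisons.

    Requires at least two groups with n >= 2 each.  Adjusted p-values come
    from the studentized-range distribution with the Kramer correction for
    unequal n.  Constant data across all groups yields a defined
    "no test" outcome (F undefined, nothing significant) rather than an
    exception.
    """
    if len(data) < 2:
        raise ValueError(f"need at least 2 groups, got {len(data)}")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    names = list(data)
    arrays = {name: np.asarray(data[name], dtype=float) for name in names}
    for name, arr in arrays.items():
        if arr.size < 2:
            raise ValueError(f"group {name!r} has n={arr.size}; need n >= 2")

    summaries = [
        GroupSummary(name, int(arr.size), *mean_sem(arr)) for name, arr in arrays.items()
    ]
    means = {s.name: s.mean for s in summaries}
    ns = {s.name: s.n for s in summaries}

    k = len(names)
    n_total = sum(ns.values())
    df_within = n_total - k
    sse = sum(float(((arr - arr.mean()) ** 2).sum()) for arr in arrays.values())
    mse = sse / df_within

    pairwise: List[PairwiseResult] = []
    if mse == 0.0:
        if len({means[n] for n in names}) == 1:
            # all observations identical: F is 0/0, report "no test"
            for a, b in itertools.combinations(names, 2):
                pairwise.append(PairwiseResult(a, b, 0.0, 1.0, False))
            return GroupComparison(
                groups=summaries,
                anova_f=float("nan"),
                anova_p=float("nan"),
                anova_significant=False,
                alpha=alpha,
                pairwise=pairwise,
                degenerate=True,
            )
        # zero within-group variance but distinct means: perfect separation
        for a, b in itertools.combinations(names, 2):
            diff = means[b] - means[a]
            sig = diff != 0.0
            pairwise.append(PairwiseResult(a, b, diff, 0.0 if sig else 1.0, sig))
        return GroupComparison(
            groups=summaries,
            anova_f=float("inf"),
            anova_p=0.0,
            anova_significant=True,
            alpha=alpha,
            pairwise=pairwise,
        )

    f_stat, p_value = stats.f_oneway(*arrays.values())
    anova_significant = bool(p_value < alpha)

    for a, b in itertools.combinations(names, 2):
        diff = means[b] - means[a]
        se = math.sqrt(mse / 2.0 * (1.0 / ns[a] + 1.0 / ns[b]))
        q = abs(diff) / se
        p_adj = float(np.clip(stats.studentized_range.sf(q, k, df_within), 0.0, 1.0))
        pairwise.append(PairwiseResult(a, b, diff, p_adj, bool(p_adj < alpha)))

    return GroupComparison(
        groups=summaries,
        anova_f=float(f_stat),
        anova_p=float(p_value),
        anova_significant=anova_significant,
        alpha=alpha,
        pairwise=pairwise,
    )
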