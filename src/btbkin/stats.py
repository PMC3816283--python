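"""Group comparisons: two-sample t-test and one-way ANOVA with Dunnett's test.

Dunnett's many-to-one procedure compares each treatment group against a
single control while controlling the family-wise error rate. The critical
value is the (1 - alpha) quantile of the null distribution of
max_i |t_i|, where t_i is the pooled-variance t statistic of treatment i
vs control. Rather than interpolating classical tables, the quantile is
obtained by seeded Monte-Carlo simulation of that null distribution
(default 100,000 draws), which is exact in the limit for any number of
groups and any unbalanced sample sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "ComparisonDecision",
    "GroupComparison",
    "two_sample_t",
    "dunnett_critical_value",
    "anova_dunnett",
]


@dataclass(frozen=True)
class ComparisonDecision:
    """One treatment-vs-control comparison with its family-wise decision."""

    label: str
    t_statistic: float
    significant: bool


@dataclass
class GroupComparison:
    """Result of a group comparison procedure."""

    method: str  # "t_test" | "anova_dunnett"
    statistic: float
    p_value: float
    alpha: float = 0.05
    group_sizes: dict[str, int] = field(default_factory=dict)
    comparisons: list[ComparisonDecision] = field(default_factory=list)
    critical_value: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value out of [0, 1]: {self.p_value}")


def two_sample_t(
    a: Sequence[float],
    b: Sequence[float],
    paired: bool = False,
    equal_var: bool = True,
    alpha: float = 0.05,
) -> GroupComparison:
    """Two-sided two-sample t-test (equal-variance default; Welch optional)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if paired:
        if a.size != b.size:
            raise ValueError("paired test needs equal group sizes")
        res = sps.ttest_rel(a, b)
    else:
        res = sps.ttest_ind(a, b, equal_var=equal_var)
    stat = float(res.statistic)
    p = float(res.pvalue)
    if np.isnan(stat):  # identical constant samples: no evidence of difference
        stat, p = 0.0, 1.0
    return GroupComparison(
        method="t_test",
        statistic=stat,
        p_value=p,
        alpha=alpha,
        group_sizes={"a": int(a.size), "b": int(b.size)},
    )


@lru_cache(maxsize=64)
def dunnett_critical_value(
    n_control: int,
    n_treatments: tuple[int, ...],
    alpha: float = 0.05,
    n_draws: int = 100_000,
    seed: int = 12345,
) -> float:
    """Monte-Carlo critical value for Dunnett's two-sided many-to-one test.

    Simulates ``n_draws`` null experiments (all groups standard normal with
    the given sizes), computes each treatment's pooled-variance t statistic
    against control, and returns the (1 - alpha) quantile of max |t|.
    Cached per configuration; deterministic for a given seed.
    """
    if not n_treatments:
        raise ValueError("need at least one treatment group")
    sizes = (n_control, *n_treatments)
    if any(n < 2 for n in sizes):
        raise ValueError("each group needs n >= 2")
    rng = np.random.default_rng(seed)
    k = len(n_treatments)
    N = sum(sizes)
    df = N - len(sizes)

    # chunk to bound memory at large n_draws
    maxabs = np.empty(n_draws)
    chunk = 20_000
    for lo in range(0, n_draws, chunk):
        m = min(chunk, n_draws - lo)
        means = np.empty((m, len(sizes)))
        ss = np.zeros(m)
        for gi, n in enumerate(sizes):
            x = rng.standard_normal((m, n))
            mu = x.mean(axis=1)
            means[:, gi] = mu
            ss += ((x - mu[:, None]) ** 2).sum(axis=1)
        s2 = ss / df
        t = np.empty((m, k))
        for gi, n in enumerate(n_treatments, start=1):
            t[:, gi - 1] = (means[:, gi] - means[:, 0]) / np.sqrt(
                s2 * (1.0 / n + 1.0 / n_control)
            )
        maxabs[lo : lo + m] = np.abs(t).max(axis=1)
    return float(np.quantile(maxabs, 1.0 - alpha))


def anova_dunnett(
    control: Sequence[float],
    treatments: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
    alpha: float = 0.05,
    n_draws: int = 100_000,
    seed: int = 12345,
) -> GroupComparison:
    """One-way ANOVA followed by Dunnett many-to-one comparisons vs control.

    The ANOVA F and p describe the omnibus hypothesis; the per-treatment
    decisions use pooled-variance t statistics against the Monte-Carlo
    family-wise critical value of :func:`dunnett_critical_value`.
    """
    control = np.asarray(control, float)
    groups = [np.asarray(t, float) for t in treatments]
    if not groups:
        raise ValueError("need at least one treatment group")
    if control.size < 2 or any(g.size < 2 for g in groups):
        raise ValueError("each group needs n >= 2")
    if labels is None:
        labels = [f"treatment_{i + 1}" for i in range(len(groups))]

    f_stat, p = sps.f_oneway(control, *groups)

    all_groups = [control, *groups]
    N = sum(g.size for g in all_groups)
    df = N - len(all_groups)
    s2 = sum(((g - g.mean()) ** 2).sum() for g in all_groups) / df
    crit = dunnett_critical_value(
        int(control.size), tuple(int(g.size) for g in groups), alpha, n_draws, seed
    )
    comps = []
    for lab, g in zip(labels, groups):
        t = (g.mean() - control.mean()) / np.sqrt(s2 * (1.0 / g.size + 1.0 / control.size))
        comps.append(ComparisonDecision(label=str(lab), t_statistic=float(t), significant=bool(abs(t) > crit)))

    sizes = {"control": int(control.size)}
    sizes.update({str(lab): int(g.size) for lab, g in zip(labels, groups)})
    return GroupComparison(
        method="anova_dunnett",
        statistic=float(f_stat),
        p_value=float(p),
        alpha=alpha,
        group_sizes=sizes,
        comparisons=comps,
        critical_value=crit,
    )
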