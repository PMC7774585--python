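"""Between-group statistics: Welch t, Fisher's exact, one-way ANOVA with
Tukey HSD, and Pearson correlation."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "GroupSummary",
    "ContingencyTable2x2",
    "ComparisonResult",
    "welch_t",
    "welch_t_from_data",
    "fisher_exact",
    "one_way_anova_tukey",
    "pearson_correlation",
]


@dataclass(frozen=True)
class GroupSummary:
    """Sufficient statistics for one group: size, mean, SD."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"group size must be >= 2, got {self.n}")
        if self.sd < 0:
            raise ValueError(f"sd must be non-negative, got {self.sd}")

    @classmethod
    def from_data(cls, x: Sequence[float]) -> "GroupSummary":
        x = np.asarray(x, dtype=float)
        return cls(n=int(x.size), mean=float(x.mean()), sd=float(x.std(ddof=1)))


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 counts: rows are groups, columns exposed/unexposed."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or int(v) != v:
                raise ValueError("cell counts must be non-negative integers")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("all-zero table")

    @property
    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


@dataclass
class ComparisonResult:
    statistic: float
    p: float
    df: Optional[float | tuple] = None
    pairwise: Optional[dict] = None
    note: Optional[str] = None

    def to_dict(self) -> dict:
        out = {"statistic": self.statistic, "p": self.p}
        if self.df is not None:
            out["df"] = list(self.df) if isinstance(self.df, tuple) else self.df
        if self.pairwise is not None:
            out["pairwise"] = {f"{i}-{j}": p for (i, j), p in self.pairwise.items()}
        if self.note:
            out["note"] = self.note
        return out


def welch_t(summary1: GroupSummary, summary2: GroupSummary) -> ComparisonResult:
    """Two-sample Welch t-test from summary statistics.

    t = (m1 - m2) / sqrt(s1^2/n1 + s2^2/n2) with Welch-Satterthwaite
    degrees of freedom; two-sided p.  Works directly from printed
    (n, mean, SD) triplets.
    """
    v1 = summary1.sd**2 / summary1.n
    v2 = summary2.sd**2 / summary2.n
    if v1 + v2 == 0.0:
        # both groups constant
        if summary1.mean == summary2.mean:
            return ComparisonResult(
                statistic=0.0, p=1.0, df=float("nan"), note="degenerate: zero variance"
            )
        return ComparisonResult(
            statistic=float("inf") if summary1.mean > summary2.mean else float("-inf"),
            p=0.0,
            df=float("nan"),
            note="degenerate: zero variance, unequal means",
        )
    t = (summary1.mean - summary2.mean) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (
        v1**2 / (summary1.n - 1) + v2**2 / (summary2.n - 1)
    )
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return ComparisonResult(statistic=float(t), p=p, df=float(df))


def welch_t_from_data(x: Sequence[float], y: Sequence[float]) -> ComparisonResult:
    """Welch t on raw samples; identical to the summary form applied to the
    samples' own moments."""
    return welch_t(GroupSummary.from_data(x), GroupSummary.from_data(y))


def fisher_exact(table: ContingencyTable2x2) -> ComparisonResult:
    """Two-sided Fisher's exact test on a 2x2 table.

    Uses the probability-mass rule: p is the sum of hypergeometric
    probabilities of all tables (with the observed margins) no more likely
    than the observed one.  Invariant under transposition.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    # a ~ Hypergeometric(N=n, K=col1, n=row1)
    rv = stats.hypergeom(n, col1, row1)
    support = np.arange(max(0, row1 + col1 - n), min(row1, col1) + 1)
    pmf = rv.pmf(support)
    p_obs = rv.pmf(a)
    # relative tolerance guards against fp noise when masses tie
    p = float(np.sum(pmf[pmf <= p_obs * (1.0 + 1e-7)]))
    p = min(p, 1.0)
    odds = (a * d) / (b * c) if b * c > 0 else float("inf")
    return ComparisonResult(statistic=float(odds), p=p)


def one_way_anova_tukey(
    groups: Sequence[Sequence[float]], compute_pairwise: bool = True
) -> ComparisonResult:
    """One-way ANOVA with Tukey HSD post-hoc pairwise comparisons.

    The Tukey-Kramer form is used, so unbalanced group sizes are handled.
    Pairwise adjusted p-values are keyed by group index pairs (i, j).
    ``compute_pairwise=False`` skips the post-hoc step (the studentized
    range distribution is costly) and leaves ``pairwise`` as ``None``.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    k = len(arrays)
    if k < 2:
        raise ValueError("need at least 2 groups")
    for i, g in enumerate(arrays):
        if g.size < 2:
            raise ValueError(f"group {i} has fewer than 2 observations")
    ns = np.array([g.size for g in arrays])
    means = np.array([g.mean() for g in arrays])
    n_total = int(ns.sum())
    grand = float(np.concatenate(arrays).mean())
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(sum(np.sum((g - g.mean()) ** 2) for g in arrays))
    df_between = k - 1
    df_within = n_total - k
    if ss_within == 0.0 and ss_between == 0.0:
        return ComparisonResult(
            statistic=0.0,
            p=1.0,
            df=(float(df_between), float(df_within)),
            note="degenerate: all observations identical",
        )
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    if ms_within == 0.0:
        f_stat, p = float("inf"), 0.0
    else:
        f_stat = ms_between / ms_within
        p = float(stats.f.sf(f_stat, df_between, df_within))
    if not compute_pairwise:
        return ComparisonResult(
            statistic=float(f_stat), p=p, df=(float(df_between), float(df_within))
        )
    # Tukey-Kramer studentized-range pairwise comparisons
    pairwise: dict[tuple[int, int], float] = {}
    for i in range(k):
        for j in range(i + 1, k):
            if ms_within == 0.0:
                pairwise[(i, j)] = 0.0 if means[i] != means[j] else 1.0
                continue
            se = np.sqrt(ms_within / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
            q = abs(means[i] - means[j]) / se
            pairwise[(i, j)] = float(
                stats.studentized_range.sf(q, k, df_within)
            )
    return ComparisonResult(
        statistic=float(f_stat),
        p=p,
        df=(float(df_between), float(df_within)),
        pairwise=pairwise,
    )


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> ComparisonResult:
    """Pearson product-moment correlation with two-sided p via the
    t transform on n - 2 degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    sx = x.std(ddof=1)
    sy = y.std(ddof=1)
    if sx == 0.0 or sy == 0.0:
        raise ValueError("constant input: correlation undefined")
    r = float(np.sum((x - x.mean()) * (y - y.mean())) / ((n - 1) * sx * sy))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return ComparisonResult(statistic=r, p=0.0, df=float(n - 2))
    t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * float(stats.t.sf(abs(t), n - 2))
    return ComparisonResult(statistic=r, p=p, df=float(n - 2))
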