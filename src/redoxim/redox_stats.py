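"""Unequal-variance statistics for group comparison.

The battery used throughout the pipeline:

* Welch's t-test (raw samples or summary statistics), with Cohen's d;
* Brown–Forsythe one-way ANOVA (the F* statistic on means that does not
  assume equal group variances, with a Satterthwaite denominator df);
* Dunnett's T3 all-pairwise comparisons based on the studentized maximum
  modulus (SMM) distribution, with a Šidák fallback;
* ordinary least-squares regression of one per-cell index on another;
* comparison of two regression slopes by a Welch-type t-test on the slope
  estimates (ANCOVA-style, unequal variances).

All tests are two-sided.  Significance tiers follow the usual star
convention: p < 0.05 (*), 0.01 (**), 0.001 (***), 0.0001 (****).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Literal, NamedTuple, Sequence

import numpy as np
from scipy import integrate, stats

from .errors import ContractError

DEFAULT_ALPHA = 0.05


class SummaryStats(NamedTuple):
    """Sufficient statistics of one group: mean, SD (n-1 denominator), n."""

    mean: float
    sd: float
    n: int


@dataclass(frozen=True)
class StatResult:
    """Outcome of one hypothesis test."""

    test: str
    statistic: float
    df: float
    p_value: float
    effect_size: float | None = None
    p_adjusted: float | None = None
    labels: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ContractError(f"p-value {self.p_value} outside [0, 1]")

    @property
    def significant(self) -> bool:
        p = self.p_adjusted if self.p_adjusted is not None else self.p_value
        return p < DEFAULT_ALPHA


@dataclass(frozen=True)
class RegressionResult:
    """Ordinary least-squares line fit y = slope * x + intercept."""

    slope: float
    intercept: float
    slope_se: float
    r_squared: float
    p_value: float
    n: int


def significance_tier(p: float) -> str:
    """Map a p-value to its star label ('ns' when p >= 0.05)."""
    for stars, cut in (("****", 1e-4), ("***", 1e-3), ("**", 1e-2), ("*", 5e-2)):
        if p < cut:
            return stars
    return "ns"


def _as_summary(group) -> SummaryStats:
    if isinstance(group, SummaryStats):
        return group
    if isinstance(group, tuple) and len(group) == 3 and np.isscalar(group[0]):
        return SummaryStats(float(group[0]), float(group[1]), int(group[2]))
    arr = np.asarray(group, dtype=float)
    if arr.ndim != 1:
        raise ContractError("samples must be 1-D")
    if arr.size < 2:
        raise ContractError(f"need n >= 2 per group, got {arr.size}")
    return SummaryStats(float(arr.mean()), float(arr.std(ddof=1)), int(arr.size))


def cohens_d(a: SummaryStats, b: SummaryStats) -> float:
    """Cohen's d with the pooled (n-1 weighted) standard deviation."""
    pooled_var = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / (a.n + b.n - 2)
    if pooled_var == 0:
        return 0.0 if a.mean == b.mean else math.inf
    return (a.mean - b.mean) / math.sqrt(pooled_var)


def welch_t(group_a, group_b, labels: tuple[str, str] | None = None) -> StatResult:
    """Welch's two-sided t-test for two groups with unequal variances.

    Accepts raw 1-D samples or ``(mean, sd, n)`` summaries for either group.
    The degenerate case of two zero-variance groups with equal means returns
    t = 0, p = 1.
    """
    a, b = _as_summary(group_a), _as_summary(group_b)
    if a.n < 2 or b.n < 2:
        raise ContractError("welch_t requires n >= 2 in each group")
    va, vb = a.sd**2 / a.n, b.sd**2 / b.n
    se2 = va + vb
    if se2 == 0:
        if a.mean == b.mean:
            return StatResult("welch_t", 0.0, float(a.n + b.n - 2), 1.0, 0.0, labels=labels)
        raise ContractError("welch_t: zero variance in both groups with unequal means")
    t = (a.mean - b.mean) / math.sqrt(se2)
    df = se2**2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return StatResult("welch_t", t, df, min(p, 1.0), cohens_d(a, b), labels=labels)


def brown_forsythe_anova(groups: Sequence) -> StatResult:
    """Brown–Forsythe one-way ANOVA on group means (unequal variances).

    F* = sum n_j (ybar_j - ybar)^2 / sum (1 - n_j/N) s_j^2, with numerator
    df = k - 1 and a Satterthwaite denominator df.  Reduces exactly to the
    classical one-way F when all group variances are equal in a balanced
    design.  All-degenerate input (every group zero-variance, equal means)
    returns p = 1.
    """
    if len(groups) < 3:
        raise ContractError("brown_forsythe_anova needs >= 3 groups (use welch_t for 2)")
    ss = [_as_summary(g) for g in groups]
    if any(s.n < 2 for s in ss):
        raise ContractError("each group needs n >= 2")
    N = sum(s.n for s in ss)
    grand = sum(s.n * s.mean for s in ss) / N
    numer = sum(s.n * (s.mean - grand) ** 2 for s in ss)
    terms = [(1.0 - s.n / N) * s.sd**2 for s in ss]
    denom = sum(terms)
    k = len(ss)
    if denom == 0:
        if numer == 0:
            return StatResult("brown_forsythe_anova", 0.0, float(k - 1), 1.0)
        raise ContractError("all groups have zero variance but unequal means")
    f_star = numer / denom
    # Satterthwaite df on the denominator mixture of chi-squares.
    c = [t / denom for t in terms]
    df_denom = 1.0 / sum(c_j**2 / (s.n - 1) for c_j, s in zip(c, ss))
    p = float(stats.f.sf(f_star, k - 1, df_denom))
    return StatResult("brown_forsythe_anova", f_star, df_denom, p)


def smm_sf(t: float, n_comparisons: int, df: float) -> float:
    """Survival function of the studentized maximum modulus distribution.

    P(max_i |T_i| > t) for ``n_comparisons`` independent standard normals
    studentized by one shared chi(df) denominator, evaluated by numerical
    integration over the denominator's density.  With one comparison this
    reduces to the two-sided t-tail.
    """
    if t <= 0:
        return 1.0
    if not np.isfinite(t):
        return 0.0
    s_dist = stats.chi(df, scale=1.0 / math.sqrt(df))

    def integrand(s: float) -> float:
        return (2.0 * stats.norm.cdf(t * s) - 1.0) ** n_comparisons * s_dist.pdf(s)

    cdf, _ = integrate.quad(integrand, 0.0, np.inf, limit=200)
    return float(min(max(1.0 - cdf, 0.0), 1.0))


def dunnett_t3(
    groups: Sequence,
    labels: Sequence[str] | None = None,
    method: Literal["smm", "sidak"] = "smm",
) -> list[StatResult]:
    """Dunnett's T3 all-pairwise comparisons for unequal variances.

    Each pair gets a Welch-type t statistic with pairwise Welch–Satterthwaite
    df; the adjusted p comes from the SMM distribution with parameter equal
    to the number of comparisons (or from the more conservative Šidák
    correction ``1 - (1 - p_raw)^m`` with ``method="sidak"``).  Adjusted
    p-values never fall below the raw Welch p.
    """
    if len(groups) < 3:
        raise ContractError("dunnett_t3 needs >= 3 groups (use welch_t for 2)")
    ss = [_as_summary(g) for g in groups]
    if labels is None:
        labels = [f"group{i}" for i in range(len(ss))]
    m = len(ss) * (len(ss) - 1) // 2
    results = []
    for i, j in itertools.combinations(range(len(ss)), 2):
        raw = welch_t(ss[i], ss[j], labels=(str(labels[i]), str(labels[j])))
        if method == "smm":
            p_adj = smm_sf(abs(raw.statistic), m, raw.df) if raw.df > 0 else 1.0
        else:
            p_adj = 1.0 - (1.0 - raw.p_value) ** m
        p_adj = float(min(max(p_adj, raw.p_value), 1.0))
        results.append(
            StatResult(
                test=f"dunnett_t3[{method}]",
                statistic=raw.statistic,
                df=raw.df,
                p_value=raw.p_value,
                effect_size=raw.effect_size,
                p_adjusted=p_adj,
                labels=raw.labels,
            )
        )
    return results


def fit_line(x, y) -> RegressionResult:
    """Ordinary least-squares fit of y on x with slope inference.

    Returns slope, intercept, the slope's standard error, R², and the
    two-sided p-value for slope != 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ContractError("x and y must be 1-D samples of equal length")
    if x.size < 3:
        raise ContractError("fit_line needs n >= 3")
    if np.all(x == x[0]):
        raise ContractError("fit_line: x is constant")
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        slope_se=float(res.stderr),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=int(x.size),
    )


def compare_slopes(fit_a: RegressionResult, fit_b: RegressionResult) -> StatResult:
    """Welch-type t-test for the difference of two regression slopes.

    t = (b_a - b_b) / sqrt(SE_a² + SE_b²), with Welch–Satterthwaite df built
    from the two slope variances with component df (n_a - 2) and (n_b - 2).
    Antisymmetric in its arguments: swapping negates t and preserves p.
    """
    va, vb = fit_a.slope_se**2, fit_b.slope_se**2
    se2 = va + vb
    if se2 == 0:
        if fit_a.slope == fit_b.slope:
            return StatResult("compare_slopes", 0.0, float(fit_a.n + fit_b.n - 4), 1.0)
        import warnings

        warnings.warn("compare_slopes: both fits exact with unequal slopes", stacklevel=2)
        return StatResult("compare_slopes", math.inf if fit_a.slope > fit_b.slope else -math.inf,
                          float(fit_a.n + fit_b.n - 4), 0.0)
    t = (fit_a.slope - fit_b.slope) / math.sqrt(se2)
    df = se2**2 / (va**2 / (fit_a.n - 2) + vb**2 / (fit_b.n - 2))
    p = float(min(2.0 * stats.t.sf(abs(t), df), 1.0))
    return StatResult("compare_slopes", t, df, p)
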