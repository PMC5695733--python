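"""Two-group comparison workflow: normality, variance homogeneity, t-test.

Mirrors the standard small-study analysis sequence: Shapiro–Wilk normality
per group and a median-centered Levene (Brown–Forsythe) variance check,
followed by an independent two-sample t-test (pooled variance by default,
Welch behind a flag) and Pearson correlation where two variables are
compared.  Significance level α = 0.05 throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "t_test_independent",
    "pearson_correlation",
    "normality_check",
    "variance_check",
    "percent_reduction",
    "compare_groups",
]


def _as_group(x, name: str, min_n: int = 2) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size < min_n:
        raise ValueError(f"{name} needs at least {min_n} observations, got {arr.size}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def t_test_independent(g1, g2, *, pooled: bool = True) -> tuple[float, float, float]:
    """Independent two-sample t-test; returns (t, df, p_two_sided).

    Pooled variance (df = n1 + n2 − 2) by default; ``pooled=False`` gives
    the Welch variant with Satterthwaite df.  The sign convention is
    t > 0 when mean(g1) > mean(g2).
    """
    a = _as_group(g1, "group 1")
    b = _as_group(g2, "group 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0 and a.mean() == b.mean():
        raise ValueError("both groups constant and equal: t undefined")
    n1, n2 = a.size, b.size
    if pooled:
        df = n1 + n2 - 2
        sp2 = ((n1 - 1) * va + (n2 - 1) * vb) / df
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    else:
        se2_1, se2_2 = va / n1, vb / n2
        se = np.sqrt(se2_1 + se2_2)
        df = (se2_1 + se2_2) ** 2 / (
            se2_1**2 / (n1 - 1) + se2_2**2 / (n2 - 1)
        )
    if se == 0:
        raise ValueError("zero standard error: t undefined")
    t = (a.mean() - b.mean()) / se
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def pearson_correlation(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation; returns (r, p_two_sided)."""
    xv = _as_group(x, "x", min_n=3)
    yv = _as_group(y, "y", min_n=3)
    if xv.size != yv.size:
        raise ValueError("x and y must have equal length")
    if xv.std() == 0 or yv.std() == 0:
        raise ValueError("constant input: correlation undefined")
    res = sps.pearsonr(xv, yv)
    return float(res.statistic), float(res.pvalue)


def normality_check(samples) -> tuple[float, float]:
    """Shapiro–Wilk test; returns (W, p).  Valid for 3 ≤ n ≤ 5000."""
    arr = _as_group(samples, "samples", min_n=3)
    if arr.size > 5000:
        raise ValueError("Shapiro-Wilk approximation not valid above n = 5000")
    res = sps.shapiro(arr)
    return float(res.statistic), float(res.pvalue)


def variance_check(g1, g2, *, center: str = "median") -> tuple[float, float]:
    """Levene variance-homogeneity test on absolute deviations from the
    group center (median by default = Brown–Forsythe); returns (stat, p)."""
    a = _as_group(g1, "group 1")
    b = _as_group(g2, "group 2")
    res = sps.levene(a, b, center=center)
    return float(res.statistic), float(res.pvalue)


def percent_reduction(a: float, b: float) -> float:
    """Percent reduction of a relative to the reference b: 100·(1 − a/b)."""
    if b == 0:
        raise ValueError("reference value must be nonzero")
    return 100.0 * (1.0 - a / b)


@dataclass(frozen=True)
class GroupComparison:
    """Full two-group report in the order the checks are run."""

    labels: tuple[str, str]
    n: tuple[int, int]
    means: tuple[float, float]
    sds: tuple[float, float]
    shapiro: tuple[tuple[float, float], tuple[float, float]]  # (W, p) per group
    levene: tuple[float, float]
    t: float
    df: float
    p_two_sided: float
    pooled: bool
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_two_sided <= 1.0:
            raise ValueError("p must lie in [0, 1]")
        if self.pooled and self.df != self.n[0] + self.n[1] - 2:
            raise ValueError("pooled test must have df = n1 + n2 - 2")

    @property
    def significant(self) -> bool:
        return self.p_two_sided < self.alpha

    def to_dict(self) -> dict:
        d = asdict(self)
        d["significant"] = self.significant
        return d


def compare_groups(
    g1, g2, labels: tuple[str, str] = ("group1", "group2"), *, pooled: bool = True
) -> GroupComparison:
    """Run the full workflow (normality, variance, t-test) on two groups."""
    a = _as_group(g1, labels[0], min_n=3)
    b = _as_group(g2, labels[1], min_n=3)
    sw = (normality_check(a), normality_check(b))
    lev = variance_check(a, b)
    t, df, p = t_test_independent(a, b, pooled=pooled)
    return GroupComparison(
        labels=tuple(labels),
        n=(a.size, b.size),
        means=(float(a.mean()), float(b.mean())),
        sds=(float(a.std(ddof=1)), float(b.std(ddof=1))),
        shapiro=sw,
        levene=lev,
        t=t,
        df=df,
        p_two_sided=p,
        pooled=pooled,
    )
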