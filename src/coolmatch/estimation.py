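"""Effect estimation on replicated matched cohorts.

Each replicate yields a contrast between its matched fed and unfed groups —
a risk difference and an odds ratio for binary outcomes (the odds-ratio SE
is the classical log-scale Morris–Gardner form sqrt(1/a+1/b+1/c+1/d)), and a
two-sample mean difference for continuous outcomes.  Replicate estimates are
then averaged, with the combined variance W-bar + (1 + 1/R) * B (within-
replication mean variance plus inflated between-replication variance, the
Rubin combination rule).  Two-sided p-values use the standard normal
reference; Bonferroni correction flags p < 0.05/m.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TwoByTwo",
    "ORResult",
    "RDResult",
    "MDResult",
    "EffectEstimate",
    "two_by_two",
    "odds_ratio",
    "risk_difference",
    "mean_difference",
    "combine_replicates",
    "bonferroni",
    "sample_size_two_proportions",
]

Z975 = 1.959963984540054


@dataclass(frozen=True)
class TwoByTwo:
    """Counts: a fed-with-event, b fed-without, c unfed-with-event, d unfed-without."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for name in "abcd":
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"cell {name} must be a non-negative integer, got {v}")

    @property
    def n_fed(self) -> int:
        return self.a + self.b

    @property
    def n_unfed(self) -> int:
        return self.c + self.d


@dataclass(frozen=True)
class ORResult:
    oddsratio: float
    log_or: float
    se_log: float
    ci: tuple[float, float]
    corrected: bool = False  # 0.5 added to every cell


@dataclass(frozen=True)
class RDResult:
    difference: float
    se: float
    ci: tuple[float, float]
    p_fed: float
    p_unfed: float


@dataclass(frozen=True)
class MDResult:
    difference: float
    se: float
    ci: tuple[float, float]
    welch_df: float
    mean_fed: float
    mean_unfed: float


def two_by_two(df: pd.DataFrame, pairs: pd.DataFrame, outcome: str) -> TwoByTwo:
    """Tabulate a binary outcome over one replicate's matched babies.

    Babies with a missing outcome value are dropped from their group's
    marginals.
    """
    if len(pairs) == 0:
        raise ValueError("empty replicate")
    col = outcome if outcome in df.columns else f"out__{outcome}"
    vals = df.set_index("infant_id")[col]
    fed = vals.loc[pairs["fed_id"]].dropna()
    unfed = vals.loc[pairs["unfed_id"]].dropna()
    return TwoByTwo(
        a=int((fed == 1).sum()),
        b=int((fed != 1).sum()),
        c=int((unfed == 1).sum()),
        d=int((unfed != 1).sum()),
    )


def odds_ratio(t: TwoByTwo) -> ORResult:
    """OR = ad/bc with log-scale SE sqrt(1/a+1/b+1/c+1/d) and 95% CI.

    A zero margin (no events at all, or events in everyone) leaves the OR
    undefined; a zero cell with non-zero margins gets the Haldane-Anscombe
    0.5 correction on all four cells.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    if a + c == 0 or b + d == 0 or a + b == 0 or c + d == 0:
        raise ValueError("odds ratio undefined: zero margin in the 2x2 table")
    corrected = 0 in (a, b, c, d)
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    log_or = math.log(a * d) - math.log(b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    ci = (math.exp(log_or - Z975 * se), math.exp(log_or + Z975 * se))
    return ORResult(math.exp(log_or), log_or, se, ci, corrected)


def risk_difference(t: TwoByTwo) -> RDResult:
    """Difference of event proportions fed minus unfed, with binomial SE."""
    if t.n_fed == 0 or t.n_unfed == 0:
        raise ValueError("risk difference undefined: empty group")
    p1 = t.a / t.n_fed
    p2 = t.c / t.n_unfed
    se = math.sqrt(p1 * (1 - p1) / t.n_fed + p2 * (1 - p2) / t.n_unfed)
    diff = p1 - p2
    return RDResult(diff, se, (diff - Z975 * se, diff + Z975 * se), p1, p2)


def mean_difference(x_fed, x_unfed) -> MDResult:
    """Two-sample (Welch) mean difference fed minus unfed."""
    x1 = np.asarray(pd.Series(x_fed).dropna(), float)
    x2 = np.asarray(pd.Series(x_unfed).dropna(), float)
    if len(x1) < 2 or len(x2) < 2:
        raise ValueError("mean difference needs >=2 non-missing values per group")
    v1, v2 = x1.var(ddof=1), x2.var(ddof=1)
    n1, n2 = len(x1), len(x2)
    se = math.sqrt(v1 / n1 + v2 / n2)
    if se > 0:
        df_w = (v1 / n1 + v2 / n2) ** 2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    else:
        df_w = float(n1 + n2 - 2)
    diff = x1.mean() - x2.mean()
    return MDResult(diff, se, (diff - Z975 * se, diff + Z975 * se), df_w, x1.mean(), x2.mean())


@dataclass
class EffectEstimate:
    """Replication-averaged effect for one outcome on one estimation scale."""

    outcome: str
    scale: str  # risk_difference | odds_ratio | mean_difference
    replicate_points: list[float] = field(default_factory=list)
    replicate_variances: list[float] = field(default_factory=list)
    point: float = float("nan")  # on estimation scale (log for OR)
    within_variance: float = float("nan")
    between_variance: float = float("nan")
    se: float = float("nan")
    ci: tuple[float, float] = (float("nan"), float("nan"))
    p: float = float("nan")
    bonferroni_significant: bool | None = None

    @property
    def display_point(self) -> float:
        return math.exp(self.point) if self.scale == "odds_ratio" else self.point

    @property
    def display_ci(self) -> tuple[float, float]:
        if self.scale == "odds_ratio":
            return (math.exp(self.ci[0]), math.exp(self.ci[1]))
        return self.ci


def combine_replicates(points, within_variances, outcome: str = "", scale: str = "") -> EffectEstimate:
    """Average replicate estimates; SE^2 = W-bar + (1 + 1/R) * B.

    Points must already be on the estimation scale (log scale for odds
    ratios).  For R = 1 the between-replication variance B is 0 and the
    estimate reduces to the single replicate's.
    """
    points = np.asarray(points, float)
    wvars = np.asarray(within_variances, float)
    if len(points) < 1 or len(points) != len(wvars):
        raise ValueError("need >=1 replicate with matching point and variance arrays")
    R = len(points)
    point = float(points.mean())
    wbar = float(wvars.mean())
    B = float(points.var(ddof=1)) if R > 1 else 0.0
    se = math.sqrt(wbar + (1 + 1 / R) * B)
    if se > 0:
        p = 2 * stats.norm.sf(abs(point) / se)
    else:
        p = 1.0 if point == 0 else 0.0
    return EffectEstimate(
        outcome=outcome,
        scale=scale,
        replicate_points=points.tolist(),
        replicate_variances=wvars.tolist(),
        point=point,
        within_variance=wbar,
        between_variance=B,
        se=se,
        ci=(point - Z975 * se, point + Z975 * se),
        p=float(p),
    )


def bonferroni(p_values, m: int | None = None) -> list[bool]:
    """Significance flags at family-wise 0.05 over m tests (default: len(p))."""
    p_values = list(p_values)
    if m is None:
        m = len(p_values)
    if m < 1:
        raise ValueError("m must be >= 1")
    return [p < 0.05 / m for p in p_values]


def sample_size_two_proportions(
    p0: float, p1: float, alpha: float = 0.05, power: float = 0.90
) -> tuple[float, float]:
    """Pairs per group to detect p1 vs p0 (two-sided alpha, given power).

    Classical normal approximation n = (z_{a/2} + z_b)^2 (p1 q1 + p0 q0) / (p1-p0)^2,
    returned both plain and with the continuity correction
    n_c = n/4 * (1 + sqrt(1 + 4 / (n |p1 - p0|)))^2.
    """
    for name, p in (("p0", p0), ("p1", p1)):
        if not (0 <= p <= 1):
            raise ValueError(f"{name} must be in [0, 1]")
    if p0 == p1:
        raise ValueError("p0 and p1 must differ")
    z = stats.norm.ppf(1 - alpha / 2) + stats.norm.ppf(power)
    n = z**2 * (p1 * (1 - p1) + p0 * (1 - p0)) / (p1 - p0) ** 2
    n_corr = n / 4 * (1 + math.sqrt(1 + 4 / (n * abs(p1 - p0)))) ** 2
    return float(n), float(n_corr)
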