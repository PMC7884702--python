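"""Statistics linking neural adaptation to behavior, plus standard group tests.

The central analysis pairs the 10-point adaptation profile of a neural
population (per-stimulus evoked rates normalized to the first stimulus) with a
behavioral time course — the cumulative distribution of escape latencies or
the probability of freezing over time — sampled at the 10 stimulus-window
midpoints, and quantifies the coupling with Pearson's r.

Fisher's exact test is two-sided by the point-probability rule: the p-value
sums the hypergeometric probabilities of all tables with the observed margins
whose probability does not exceed that of the observed table.  Conventions
differ across software (mid-p, twice-one-sided); this one matches the common
default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "CorrelationResult",
    "TestResult",
    "FitResult",
    "EcdfResult",
    "escape_latency_cdf",
    "freezing_probability_curve",
    "pearson_corr",
    "fisher_exact",
    "group_tests",
    "fit_and_compare",
]


@dataclass
class CorrelationResult:
    r: float
    p_value: float
    n: int


@dataclass
class TestResult:
    statistic: float
    p_value: float
    df: float
    comparison: str
    correction: str = "none"
    posthoc: list["TestResult"] = field(default_factory=list)


@dataclass
class FitResult:
    degree: int
    coefficients: np.ndarray  # highest power first
    r_squared: float


@dataclass
class EcdfResult:
    time_grid_s: np.ndarray
    cdf: np.ndarray
    n: int
    n_censored: int


def escape_latency_cdf(latencies_s: Sequence[float | None],
                       time_grid_s: Sequence[float]) -> EcdfResult:
    """Empirical CDF of escape latencies on a time grid.

    Non-escaping animals are passed as ``None``/NaN and excluded; their count
    is reported in ``n_censored``.  The CDF is non-decreasing with final
    value <= 1.
    """
    vals = np.array([np.nan if v is None else float(v) for v in latencies_s])
    censored = int(np.isnan(vals).sum())
    lat = np.sort(vals[~np.isnan(vals)])
    if lat.size == 0:
        raise ValueError("no uncensored latencies")
    if np.any(lat < 0):
        raise ValueError("latencies must be >= 0")
    grid = np.asarray(time_grid_s, dtype=float)
    cdf = np.searchsorted(lat, grid, side="right") / lat.size
    return EcdfResult(time_grid_s=grid, cdf=cdf, n=int(lat.size), n_censored=censored)


def freezing_probability_curve(episode_lists: Sequence[Sequence[tuple[float, float]]],
                               time_grid_s: Sequence[float]) -> np.ndarray:
    """Fraction of animals with an active freezing episode at each grid time.

    Episodes are half-open ``[onset, offset)`` intervals per animal.
    """
    grid = np.asarray(time_grid_s, dtype=float)
    n = len(episode_lists)
    if n == 0:
        return np.zeros_like(grid)
    counts = np.zeros_like(grid)
    for episodes in episode_lists:
        active = np.zeros_like(grid, dtype=bool)
        for on, off in episodes:
            active |= (grid >= on) & (grid < off)
        counts += active
    return counts / n


def pearson_corr(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Product-moment correlation with a two-sided p from the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("undefined correlation: zero variance input")
    res = sps.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p_value=float(res.pvalue), n=int(x.size))


def fisher_exact(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher's exact p for a 2x2 table, by hypergeometric enumeration.

    With fixed margins the table is indexed by its top-left cell ``x``; the
    p-value sums ``P(x')`` over all admissible ``x'`` with
    ``P(x') <= P(x_obs)`` (point-probability rule).
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0):
        raise ValueError("counts must be non-negative")
    a, b = t[0]
    c, d = t[1]
    n = a + b + c + d
    if n == 0:
        raise ValueError("at least one margin must be positive")
    r1, c1 = a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    xs = np.arange(lo, hi + 1)
    pmf = sps.hypergeom.pmf(xs, n, r1, c1)
    p_obs = pmf[a - lo]
    return float(min(1.0, pmf[pmf <= p_obs * (1.0 + 1e-9)].sum()))


def _paired_t(x: np.ndarray, y: np.ndarray) -> TestResult:
    if x.size != y.size:
        raise ValueError("paired test requires equal-length samples")
    if np.all(x - y == (x - y)[0]) and (x - y)[0] == 0:
        # identical pairs: no effect and no variance; report t=0, p=1
        return TestResult(0.0, 1.0, float(x.size - 1), comparison="paired_t")
    res = sps.ttest_rel(x, y)
    return TestResult(float(res.statistic), float(res.pvalue), float(x.size - 1),
                      comparison="paired_t")


def _two_sample_t(x: np.ndarray, y: np.ndarray) -> TestResult:
    # Welch by default: no equal-variance assumption
    res = sps.ttest_ind(x, y, equal_var=False)
    return TestResult(float(res.statistic), float(res.pvalue), float(res.df),
                      comparison="two_sample_t(welch)")


def _anova_bonferroni(groups: Sequence[np.ndarray]) -> TestResult:
    f, p = sps.f_oneway(*groups)
    k = len(groups)
    df = (k - 1, sum(g.size for g in groups) - k)
    out = TestResult(float(f), float(p), float(df[0]), comparison="oneway_anova",
                     correction=f"bonferroni({k * (k - 1) // 2} pairwise)")
    m = k * (k - 1) // 2
    for i in range(k):
        for j in range(i + 1, k):
            res = sps.ttest_ind(groups[i], groups[j], equal_var=False)
            out.posthoc.append(TestResult(
                float(res.statistic), float(min(1.0, res.pvalue * m)), float(res.df),
                comparison=f"group{i}_vs_group{j}", correction="bonferroni"))
    return out


def group_tests(data: Sequence[Sequence[float]], design: str) -> TestResult:
    """Paired t, Welch two-sample t, or one-way ANOVA with Bonferroni post hoc.

    ``design`` in ``{"paired_t", "two_sample_t", "oneway_anova_bonferroni"}``.
    All p-values are two-sided; Bonferroni multiplies each pairwise p by the
    number of comparisons (capped at 1).
    """
    groups = [np.asarray(g, dtype=float) for g in data]
    if any(g.size < 2 for g in groups):
        raise ValueError("each group needs >= 2 observations")
    if design == "paired_t":
        if len(groups) != 2:
            raise ValueError("paired_t needs exactly 2 groups")
        return _paired_t(*groups)
    if design == "two_sample_t":
        if len(groups) != 2:
            raise ValueError("two_sample_t needs exactly 2 groups")
        return _two_sample_t(*groups)
    if design == "oneway_anova_bonferroni":
        if len(groups) < 2:
            raise ValueError("ANOVA needs >= 2 groups")
        return _anova_bonferroni(groups)
    raise ValueError(f"unknown design {design!r}")


def fit_and_compare(x: Sequence[float], y: Sequence[float],
                    degrees: Sequence[int] = (1, 2, 3)) -> tuple[FitResult, list[FitResult]]:
    """Least-squares polynomial fits per degree; select the best by R².

    Ties (within 1e-12) go to the lowest degree.  Returns
    ``(selected, all_fits)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size <= max(degrees) + 1:
        raise ValueError("need n > max degree + 1")
    if np.unique(x).size <= max(degrees):
        raise ValueError("rank-deficient design: too few distinct x values")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    fits = []
    for deg in sorted(degrees):
        coef = np.polyfit(x, y, deg)
        resid = y - np.polyval(coef, x)
        r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 1.0
        fits.append(FitResult(degree=deg, coefficients=coef, r_squared=r2))
    best = fits[0]
    for f in fits[1:]:
        if f.r_squared > best.r_squared + 1e-12:
            best = f
    return best, fits
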