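"""Protocol statistics: normality routing, paired tests, Bonferroni, regression.

Regional tidal impedance data are typically non-normal, so comparisons are
routed through a Shapiro-Wilk gate: any rejection sends the comparison to a
nonparametric test (Wilcoxon signed-rank when paired, Mann-Whitney U
otherwise), and normal data use Student's t.  All tests are two-sided.
Family-wise error over the PEEP-pair comparisons is controlled by a
Bonferroni-adjusted threshold alpha/m; with six PEEP levels the default
family is the m = 15 unordered pairs, giving 0.05/15 ~ 0.0033.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import DegenerateDesignError, RoutingError, UndefinedTestError

#: number of unordered pairs among six PEEP levels
DEFAULT_FAMILY_SIZE = 15

#: sample size at/below which the exact signed-rank null is enumerated
EXACT_WILCOXON_MAX_N = 25


@dataclass(frozen=True)
class ComparisonResult:
    test_name: str       # wilcoxon-signed-rank | mann-whitney | t-paired | t-unpaired
    statistic: float
    p_value: float
    n: int               # pairs (paired) or per-group sizes summed
    alpha_adjusted: float
    significant: bool


def route_test(
    sample_a,
    sample_b,
    paired: bool,
    alpha_normality: float = 0.05,
    on_constant: str = "nonparametric",
) -> str:
    """Choose the test by Shapiro-Wilk normality screening.

    Paired data are screened on the differences; unpaired data on each
    sample.  Any rejection at ``alpha_normality`` routes to the
    nonparametric test.  Constant input makes Shapiro-Wilk undefined; the
    ``on_constant`` policy either forces the nonparametric branch (default)
    or raises a :class:`RoutingError`.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise RoutingError("normality routing needs at least 3 values per sample")
    if paired and a.size != b.size:
        raise RoutingError("paired samples must have equal length")
    screens = [a - b] if paired else [a, b]
    nonparametric = "wilcoxon-signed-rank" if paired else "mann-whitney"
    for s in screens:
        if np.ptp(s) == 0:
            if on_constant == "nonparametric":
                return nonparametric
            raise RoutingError("constant sample: normality test undefined")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if sps.shapiro(s).pvalue <= alpha_normality:
                return nonparametric
    return "t-paired" if paired else "t-unpaired"


def wilcoxon_signed_rank(
    sample_a,
    sample_b=None,
    mode: str = "auto",
    alpha_adjusted: float = 0.05,
) -> ComparisonResult:
    """Two-sided Wilcoxon signed-rank test on paired data (or differences).

    Zero differences are dropped before ranking (Wilcoxon's original
    treatment).  ``mode='exact'`` evaluates the exact sign-enumeration null
    distribution (used automatically for n <= 25); ``mode='normal-approx'``
    uses the tie-corrected normal approximation.
    """
    d = np.asarray(sample_a, dtype=float)
    if sample_b is not None:
        d = d - np.asarray(sample_b, dtype=float)
    d = d[d != 0.0]
    if d.size == 0:
        raise UndefinedTestError("all paired differences are zero")
    if mode == "auto":
        mode = "exact" if d.size <= EXACT_WILCOXON_MAX_N else "normal-approx"
    if mode == "exact":
        res = sps.wilcoxon(d, zero_method="wilcox", method="exact")
    elif mode == "normal-approx":
        res = sps.wilcoxon(d, zero_method="wilcox", method="approx", correction=False)
    else:
        raise ValueError("mode must be 'auto', 'exact' or 'normal-approx'")
    p = float(res.pvalue)
    return ComparisonResult(
        test_name="wilcoxon-signed-rank", statistic=float(res.statistic),
        p_value=p, n=int(d.size), alpha_adjusted=alpha_adjusted,
        significant=p <= alpha_adjusted,
    )


def mann_whitney(sample_a, sample_b, alpha_adjusted: float = 0.05) -> ComparisonResult:
    """Two-sided Mann-Whitney U test for unpaired samples."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    res = sps.mannwhitneyu(a, b, alternative="two-sided")
    p = float(res.pvalue)
    return ComparisonResult(
        test_name="mann-whitney", statistic=float(res.statistic), p_value=p,
        n=int(a.size + b.size), alpha_adjusted=alpha_adjusted,
        significant=p <= alpha_adjusted,
    )


def t_test(
    sample_a, sample_b, paired: bool, alpha_adjusted: float = 0.05
) -> ComparisonResult:
    """Two-sided Student's t-test (paired or unpaired)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    res = sps.ttest_rel(a, b) if paired else sps.ttest_ind(a, b)
    p = float(res.pvalue)
    return ComparisonResult(
        test_name="t-paired" if paired else "t-unpaired",
        statistic=float(res.statistic), p_value=p,
        n=int(a.size if paired else a.size + b.size),
        alpha_adjusted=alpha_adjusted, significant=p <= alpha_adjusted,
    )


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Adjusted per-comparison significance threshold alpha/m."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if m < 1:
        raise ValueError("family size m must be >= 1")
    return alpha / m


def compare(
    sample_a,
    sample_b,
    paired: bool,
    alpha: float = 0.05,
    family_size: int = 1,
    alpha_normality: float = 0.05,
) -> ComparisonResult:
    """Route, test and threshold one comparison in a Bonferroni family."""
    threshold = bonferroni_threshold(alpha, family_size)
    name = route_test(sample_a, sample_b, paired, alpha_normality=alpha_normality)
    if name == "wilcoxon-signed-rank":
        return wilcoxon_signed_rank(sample_a, sample_b, alpha_adjusted=threshold)
    if name == "mann-whitney":
        return mann_whitney(sample_a, sample_b, alpha_adjusted=threshold)
    return t_test(sample_a, sample_b, paired=paired, alpha_adjusted=threshold)


def regress_on_peep(peep, response) -> tuple[float, float, float]:
    """OLS line of a response on PEEP: ``(slope, intercept, r_squared)``."""
    x = np.asarray(peep, dtype=float)
    y = np.asarray(response, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need matching vectors with at least 2 points")
    if np.ptp(x) == 0:
        raise DegenerateDesignError("all PEEP values identical")
    if np.ptp(y) == 0:
        return 0.0, float(y[0]), 0.0
    res = sps.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)
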