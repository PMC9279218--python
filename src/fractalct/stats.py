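"""Agreement and group-comparison statistics for size and FD measurements.

Covers the comparisons used when validating a new size-measurement method
against a reference standard: Bland–Altman limits of agreement with
proportional-bias regression, linear correlation with confidence
intervals, nonparametric group tests (Kruskal–Wallis omnibus, pairwise
Mann–Whitney U / Wilcoxon signed-rank with Bonferroni correction), the
F-test on difference variances, and inter-reader relative discrepancy
with Spearman's ρ.

Sign convention for method agreement: differences are *reference minus
test*, so a method that underestimates has a positive mean difference.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass
class RegressionLine:
    """Slope/intercept with normal-theory 95% confidence intervals."""

    slope: float
    slope_ci: tuple[float, float]
    intercept: float
    intercept_ci: tuple[float, float]
    r2: float


@dataclass
class AgreementStats:
    """Bland–Altman agreement plus linear correlation with the reference.

    ``mean_diff`` and the limits are in the input units; ``proportional``
    regresses the difference on the pairwise mean (slope ≠ 0 indicates
    size-dependent bias); ``correlation`` regresses test on reference.
    """

    mean_diff: float
    lower_limit: float
    upper_limit: float
    proportional: RegressionLine
    correlation: RegressionLine
    n: int


@dataclass
class TestReport:
    """One hypothesis test, with Bonferroni-adjusted p-value."""

    name: str
    statistic: float
    p_raw: float
    p_adjusted: float
    method: str
    n_comparisons: int


@dataclass
class InterReaderAgreement:
    """Relative size discrepancy between two readers, in percent."""

    median_discrepancy_pct: float
    iqr_pct: tuple[float, float]
    spearman_rho: float
    discrepancies_pct: np.ndarray


def _ols_line(x: np.ndarray, y: np.ndarray) -> RegressionLine:
    """Simple least-squares line with t-based 95% CIs on both coefficients."""
    n = len(x)
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx == 0:
        raise ValueError("regressor has zero variance")
    slope = float(xc @ y) / sxx
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (intercept + slope * x)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    dof = n - 2
    if dof > 0:
        s2 = ss_res / dof
        se_slope = np.sqrt(s2 / sxx)
        se_icept = np.sqrt(s2 * (1.0 / n + x.mean() ** 2 / sxx))
        tq = sps.t.ppf(0.975, dof)
    else:
        se_slope = se_icept = tq = 0.0
    return RegressionLine(
        slope=slope,
        slope_ci=(slope - tq * se_slope, slope + tq * se_slope),
        intercept=intercept,
        intercept_ci=(intercept - tq * se_icept, intercept + tq * se_icept),
        r2=float(max(0.0, min(1.0, r2))),
    )


def bland_altman(reference, test) -> AgreementStats:
    """Bland–Altman agreement of a test method against a reference.

    Differences are ``reference − test``; limits of agreement are
    ``mean ± 1.96 · SD`` of the differences (classical form, not
    t-quantiles).  Proportional bias is the regression of difference on
    pairwise mean; the correlation line regresses test on reference.
    """
    reference = np.asarray(reference, dtype=np.float64)
    test = np.asarray(test, dtype=np.float64)
    if reference.shape != test.shape:
        raise ValueError("reference and test must have equal length")
    n = len(reference)
    if n < 3:
        raise ValueError("need at least 3 paired measurements")

    diff = reference - test
    mean_pair = (reference + test) / 2.0
    md = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return AgreementStats(
        mean_diff=md,
        lower_limit=md - 1.96 * sd,
        upper_limit=md + 1.96 * sd,
        proportional=_ols_line(mean_pair, diff),
        correlation=_ols_line(reference, test),
        n=n,
    )


def _pairwise_method(n1: int, n2: int, values) -> str:
    has_ties = len(np.unique(values)) < len(values)
    return "exact" if (n1 <= 10 and n2 <= 10 and not has_ties) else "asymptotic"


def rank_tests(
    groups: dict[str, "np.ndarray | list"],
    paired: bool = False,
    alternative: str = "two-sided",
) -> list[TestReport]:
    """Omnibus Kruskal–Wallis plus all pairwise rank tests, Bonferroni-adjusted.

    Pairwise comparisons use the Mann–Whitney U test (``paired=False``) or
    the Wilcoxon signed-rank test (``paired=True``, equal lengths
    required).  Exact p-values are used for ≤ 10 observations per group
    without ties, the tie-corrected normal approximation otherwise.  The
    Bonferroni factor is the number of pairwise comparisons; the omnibus
    test is reported unadjusted.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = {k: np.asarray(v, dtype=np.float64) for k, v in groups.items()}
    for k, v in arrays.items():
        if v.size == 0:
            raise ValueError(f"group {k!r} is empty")

    pairs = list(itertools.combinations(arrays, 2))
    m = len(pairs)
    reports = []

    if len(arrays) > 2:
        kw_stat, kw_p = sps.kruskal(*arrays.values())
        reports.append(
            TestReport("kruskal_wallis", float(kw_stat), float(kw_p), float(kw_p), "kruskal-wallis", 1)
        )

    for a, b in pairs:
        va, vb = arrays[a], arrays[b]
        if paired:
            if len(va) != len(vb):
                raise ValueError("paired tests require equal lengths")
            d = va - vb
            if np.all(d == 0):
                raise ValueError(f"all paired differences tied at zero for {a} vs {b}")
            method = _pairwise_method(len(va), len(vb), np.abs(d[d != 0]))
            res = sps.wilcoxon(
                va,
                vb,
                alternative=alternative,
                method=("exact" if method == "exact" else "approx"),
                correction=False,
            )
            name, label = f"wilcoxon[{a} vs {b}]", "wilcoxon-signed-rank"
        else:
            method = _pairwise_method(len(va), len(vb), np.concatenate([va, vb]))
            res = sps.mannwhitneyu(va, vb, alternative=alternative, method=method)
            name, label = f"mannwhitney[{a} vs {b}]", "mann-whitney-u"
        p_raw = float(res.pvalue)
        reports.append(
            TestReport(name, float(res.statistic), p_raw, min(1.0, p_raw * m), f"{label}-{method}", m)
        )
    return reports


def inter_reader_agreement(reader1, reader2) -> InterReaderAgreement:
    """Relative discrepancy between readers: ``|r1 − r2| / mean × 100``.

    The denominator is the pairwise mean (symmetric in the readers).
    Reported as median and interquartile range over cases, with
    Spearman's ρ of the two readers' measurements.
    """
    r1 = np.asarray(reader1, dtype=np.float64)
    r2 = np.asarray(reader2, dtype=np.float64)
    if r1.shape != r2.shape or len(r1) < 3:
        raise ValueError("need equal-length reader series of at least 3 cases")
    if np.any(r1 <= 0) or np.any(r2 <= 0):
        raise ValueError("sizes must be positive")
    disc = np.abs(r1 - r2) / ((r1 + r2) / 2.0) * 100.0
    rho = sps.spearmanr(r1, r2).statistic
    return InterReaderAgreement(
        median_discrepancy_pct=float(np.median(disc)),
        iqr_pct=(float(np.percentile(disc, 25)), float(np.percentile(disc, 75))),
        spearman_rho=float(rho),
        discrepancies_pct=disc,
    )


def variance_f_test(diffs_a, diffs_b) -> TestReport:
    """Two-sided F-test comparing the variances of two difference series.

    ``F`` is the larger sample variance over the smaller (so F ≥ 1), with
    numerator/denominator degrees of freedom matched accordingly.
    """
    a = np.asarray(diffs_a, dtype=np.float64)
    b = np.asarray(diffs_b, dtype=np.float64)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise ValueError("both samples have zero variance")
    if va >= vb:
        num, den, dfn, dfd = va, vb, len(a) - 1, len(b) - 1
    else:
        num, den, dfn, dfd = vb, va, len(b) - 1, len(a) - 1
    f = np.inf if den == 0 else num / den
    p = 0.0 if den == 0 else min(1.0, 2.0 * float(sps.f.sf(f, dfn, dfd)))
    return TestReport("variance_f_test", float(f), p, p, f"f-test({dfn},{dfd})", 1)


def bonferroni(p_values, n_comparisons: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: ``min(1, p × m)``."""
    p = np.asarray(p_values, dtype=np.float64)
    m = n_comparisons if n_comparisons is not None else p.size
    return np.minimum(1.0, p * m)
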