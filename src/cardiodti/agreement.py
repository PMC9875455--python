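"""Two-condition agreement statistics: normality-gated paired comparison,
ICC(2,1) with 95% CI, and Bland–Altman bias with 95% limits of agreement.

The comparison gate mirrors common radiology practice: Shapiro–Wilk on each
condition's values; if both pass at alpha = 0.05 a paired Student's t-test
compares means, otherwise a Wilcoxon signed-rank test compares the paired
differences. The ICC is the two-way random-effects, absolute-agreement,
single-measurement form (ICC(2,1), Shrout & Fleiss case 2), computed from
the two-way ANOVA mean squares, with the F-distribution confidence
interval; it may be negative. No multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import ParameterError

__all__ = [
    "PairedSample",
    "NormalityResult",
    "ComparisonResult",
    "ICCResult",
    "BlandAltmanResult",
    "AgreementResult",
    "normality_test",
    "compare_conditions",
    "icc",
    "bland_altman",
    "agreement_analysis",
]


@dataclass
class PairedSample:
    """Two aligned measurement vectors (condition A vs condition B).

    Subjects with a missing value in either condition are dropped at
    construction (and recorded in ``dropped``).
    """

    a: np.ndarray
    b: np.ndarray
    subjects: tuple = ()
    name: str = ""
    bvalue: float | None = None
    units: str = ""
    dropped: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        a = np.asarray(self.a, float)
        b = np.asarray(self.b, float)
        if a.shape != b.shape or a.ndim != 1:
            raise ParameterError("paired sample requires two equal-length 1D vectors")
        subjects = tuple(self.subjects) if self.subjects else tuple(range(a.size))
        if len(subjects) != a.size:
            raise ParameterError("one subject ID per pair required")
        keep = np.isfinite(a) & np.isfinite(b)
        self.dropped = tuple(s for s, k in zip(subjects, keep) if not k)
        self.a, self.b = a[keep], b[keep]
        self.subjects = tuple(s for s, k in zip(subjects, keep) if k)
        if self.a.size < 3:
            raise ParameterError("need >= 3 complete pairs")

    @property
    def n(self) -> int:
        return self.a.size

    def swapped(self) -> "PairedSample":
        return PairedSample(self.b.copy(), self.a.copy(), self.subjects, self.name, self.bvalue, self.units)


@dataclass
class NormalityResult:
    p: float
    degenerate: bool = False


@dataclass
class ComparisonResult:
    test: str
    p: float
    degenerate: bool = False


@dataclass
class ICCResult:
    value: float
    ci_low: float
    ci_high: float
    degenerate: bool = False


@dataclass
class BlandAltmanResult:
    bias: float
    loa_low: float
    loa_high: float
    means: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    diffs: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]


@dataclass
class AgreementResult:
    """Everything the study tables report for one index at one b-value."""

    name: str
    bvalue: float | None
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    normality_a: NormalityResult
    normality_b: NormalityResult
    comparison: ComparisonResult
    icc: ICCResult
    bland_altman: BlandAltmanResult


def normality_test(x: np.ndarray) -> NormalityResult:
    """Shapiro–Wilk p-value; degenerate (p = 1) for a constant vector."""
    x = np.asarray(x, float)
    if x.size < 3:
        raise ParameterError("Shapiro-Wilk requires n >= 3")
    if np.ptp(x) == 0:
        return NormalityResult(p=1.0, degenerate=True)
    return NormalityResult(p=float(stats.shapiro(x).pvalue))


def compare_conditions(s: PairedSample, *, alpha: float = 0.05, paired: bool = True) -> ComparisonResult:
    """Normality-gated two-sided comparison of the two conditions.

    Both vectors normal (Shapiro-Wilk p > alpha) -> Student's t-test
    (paired by default); otherwise Wilcoxon signed-rank on the paired
    differences (Mann-Whitney U if ``paired=False``). All differences zero
    -> degenerate, p = 1.
    """
    na, nb = normality_test(s.a), normality_test(s.b)
    normal = na.p > alpha and nb.p > alpha
    d = s.a - s.b
    if paired and np.all(d == 0):
        return ComparisonResult(test="degenerate", p=1.0, degenerate=True)
    if normal:
        if paired:
            res = stats.ttest_rel(s.a, s.b)
            return ComparisonResult(test="paired t-test", p=float(res.pvalue))
        res = stats.ttest_ind(s.a, s.b)
        return ComparisonResult(test="t-test", p=float(res.pvalue))
    if paired:
        res = stats.wilcoxon(s.a, s.b)
        return ComparisonResult(test="wilcoxon", p=float(res.pvalue))
    res = stats.mannwhitneyu(s.a, s.b)
    return ComparisonResult(test="mann-whitney", p=float(res.pvalue))


def _anova_mean_squares(data: np.ndarray) -> tuple[float, float, float]:
    """Two-way (subjects x raters) ANOVA mean squares for an n x k table."""
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((data - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return msr, msc, mse


def icc(s: PairedSample, *, confidence: float = 0.95) -> ICCResult:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE)) with k = 2,
    from the two-way ANOVA mean squares; the CI uses the Shrout & Fleiss
    F-distribution method. Degenerate (ICC = 1 by convention of identical
    data, flagged) when the table has zero total variance.
    """
    data = np.column_stack([s.a, s.b])
    n, k = data.shape
    if np.ptp(data) == 0 or np.array_equal(s.a, s.b):
        # identical measurements: perfect agreement by construction
        return ICCResult(value=1.0, ci_low=1.0, ci_high=1.0, degenerate=True)
    msr, msc, mse = _anova_mean_squares(data)
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0:
        return ICCResult(value=np.nan, ci_low=np.nan, ci_high=np.nan, degenerate=True)
    value = (msr - mse) / denom

    alpha = 1.0 - confidence
    if mse == 0:
        # perfect agreement up to row/column effects; CI collapses
        return ICCResult(value=float(value), ci_low=float(value), ci_high=float(value), degenerate=True)
    fj = msc / mse
    vn = (
        (k - 1) * (n - 1)
        * (k * value * fj + n * (1 + (k - 1) * value) - k * value) ** 2
        / (
            (n - 1) * k**2 * value**2 * fj**2
            + (n * (1 + (k - 1) * value) - k * value) ** 2
        )
    )
    f1 = stats.f.ppf(1 - alpha / 2, n - 1, vn)
    f2 = stats.f.ppf(1 - alpha / 2, vn, n - 1)
    lower = n * (msr - f1 * mse) / (f1 * (k * msc + (k * n - k - n) * mse) + n * msr)
    upper = n * (f2 * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f2 * msr)
    return ICCResult(value=float(value), ci_low=float(lower), ci_high=float(upper))


def bland_altman(s: PairedSample) -> BlandAltmanResult:
    """Bias (mean of A - B) and 95% limits of agreement bias +/- 1.96 SD.

    SD uses the n-1 denominator; per-pair means are returned for plotting.
    """
    d = s.a - s.b
    m = (s.a + s.b) / 2.0
    bias = float(d.mean())
    sd = float(d.std(ddof=1)) if d.size > 1 else 0.0
    return BlandAltmanResult(
        bias=bias, loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd, means=m, diffs=d
    )


def agreement_analysis(s: PairedSample, *, alpha: float = 0.05, paired: bool = True) -> AgreementResult:
    """Full agreement panel for one paired sample (one table row)."""
    return AgreementResult(
        name=s.name,
        bvalue=s.bvalue,
        mean_a=float(s.a.mean()),
        sd_a=float(s.a.std(ddof=1)),
        mean_b=float(s.b.mean()),
        sd_b=float(s.b.std(ddof=1)),
        normality_a=normality_test(s.a),
        normality_b=normality_test(s.b),
        comparison=compare_conditions(s, alpha=alpha, paired=paired),
        icc=icc(s),
        bland_altman=bland_altman(s),
    )
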