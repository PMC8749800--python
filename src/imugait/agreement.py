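"""Method-comparison statistics for paired gait measurements.

Implements the full gated pipeline used to compare a wearable estimate
against a reference system, on differences ``D = test - ref`` and
pairwise averages ``A = (test + ref)/2``:

* Kolmogorov–Smirnov normality gates (against a normal law with
  estimated mean/SD; a Lilliefors variant is selectable);
* accuracy/precision as mean/SD when normal, median/quartile deviation
  (``QD = (Q3 - Q1)/2``) otherwise;
* fixed bias: one-sample t-test, or Wilcoxon signed-rank with the
  zero-inclusive (Pratt) treatment;
* proportional bias: Pearson (both D and A normal) or Spearman
  correlation of D against A;
* Bland–Altman 95% limits of agreement — classic (mean ± 1.96 SD, or the
  2.5th/97.5th percentiles), corrected to lines when a proportional bias
  is present: parametrically via least squares
  (``ULoA/LLoA = D_hat ± 1.96 sqrt(pi/2) mean|R|``, which reduces to
  1.96 σ for normal residuals) or nonparametrically via linear quantile
  regression at τ = 0.025/0.50/0.975;
* agreement coefficient: ICC(2,1)/(2,k) (two-way random effects,
  absolute agreement) when both series are normal, else the tie-corrected
  Kendall coefficient of concordance for two raters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats

__all__ = [
    "PairedMeasurements",
    "AgreementReport",
    "normality_test",
    "fixed_bias_test",
    "proportional_bias_test",
    "loa_classic",
    "loa_parametric_corrected",
    "loa_quantile_corrected",
    "icc",
    "kendalls_w",
    "interpret_icc",
    "interpret_w",
    "run_agreement_pipeline",
    "plot_bland_altman",
]

ALPHA = 0.05

Line = Tuple[float, float]  # (intercept, slope) over the pairwise average A


@dataclass
class PairedMeasurements:
    """Two aligned series of the same quantity from different systems."""

    x_ref: np.ndarray
    x_test: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.x_ref = np.asarray(self.x_ref, dtype=float)
        self.x_test = np.asarray(self.x_test, dtype=float)
        if self.x_ref.shape != self.x_test.shape or self.x_ref.ndim != 1:
            raise ValueError("x_ref and x_test must be equal-length 1-D arrays")
        if self.x_ref.size < 3:
            raise ValueError("need at least 3 pairs")

    @property
    def D(self) -> np.ndarray:
        """Differences, test system minus reference."""
        return self.x_test - self.x_ref

    @property
    def A(self) -> np.ndarray:
        """Pairwise averages of the two systems."""
        return 0.5 * (self.x_test + self.x_ref)


@dataclass
class AgreementReport:
    """Everything the statistics pipeline decides and estimates."""

    label: str
    n: int
    normal_d: bool
    normal_both: bool
    accuracy: float
    precision: float
    fixed_bias_p: float
    prop_bias_r: float
    prop_bias_p: float
    loa_lower: float | Line
    loa_upper: float | Line
    pa_line: Line
    loa_method: str               # "classic" | "parametric" | "quantile"
    coefficient: float
    coefficient_type: str         # "ICC(2,1)" | "ICC(2,k)" | "KendallW"
    interpretation: str

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("loa_lower", "loa_upper", "pa_line"):
            v = d[key]
            if isinstance(v, tuple):
                d[key] = {"intercept": v[0], "slope": v[1]}
        return d


def _qd(x: np.ndarray) -> float:
    q1, q3 = np.quantile(x, [0.25, 0.75])
    return float(0.5 * (q3 - q1))


def normality_test(values: Sequence[float],
                   method: str = "ks") -> Tuple[bool, float]:
    """Normality gate: one-sample KS against a fitted normal law.

    ``method="lilliefors"`` switches to the Lilliefors correction for
    estimated parameters. Constant samples are reported non-normal with a
    degenerate (NaN) p-value.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 values")
    sd = x.std(ddof=1)
    if sd == 0:
        return False, float("nan")
    if method == "lilliefors":
        from statsmodels.stats.diagnostic import lilliefors as _lf
        _, p = _lf(x, dist="norm")
    elif method == "ks":
        _, p = stats.kstest(x, "norm", args=(x.mean(), sd))
    else:
        raise ValueError("method must be 'ks' or 'lilliefors'")
    return bool(p >= ALPHA), float(p)


def fixed_bias_test(D: Sequence[float], normal: bool) -> float:
    """p-value for a fixed bias between the systems.

    One-sample t-test of zero mean when the differences are normal,
    otherwise Wilcoxon signed-rank of zero median with zeros retained
    (Pratt). All-zero differences give p = 1.
    """
    d = np.asarray(D, dtype=float)
    if np.all(d == 0):
        return 1.0
    if normal:
        return float(stats.ttest_1samp(d, 0.0).pvalue)
    return float(stats.wilcoxon(d, zero_method="pratt").pvalue)


def proportional_bias_test(D: Sequence[float], A: Sequence[float],
                           normal_both: bool) -> Tuple[float, float]:
    """Correlation of differences against averages (Pearson or Spearman).

    A constant series yields ``r = 0`` by convention (p = 1).
    """
    d = np.asarray(D, dtype=float)
    a = np.asarray(A, dtype=float)
    if np.ptp(d) == 0 or np.ptp(a) == 0:
        return 0.0, 1.0
    if normal_both:
        res = stats.pearsonr(a, d)
    else:
        res = stats.spearmanr(a, d)
    return float(res.statistic), float(res.pvalue)


def loa_classic(D: Sequence[float], normal: bool) -> Tuple[float, float]:
    """Constant 95% limits of agreement.

    ``mean ± 1.96 SD`` for normal differences, else the empirical
    2.5th/97.5th percentiles (linear-interpolation quantiles).
    """
    d = np.asarray(D, dtype=float)
    if normal:
        m, s = d.mean(), d.std(ddof=1)
        return float(m - 1.96 * s), float(m + 1.96 * s)
    lo, hi = np.quantile(d, [0.025, 0.975])
    return float(lo), float(hi)


def loa_parametric_corrected(
    D: Sequence[float], A: Sequence[float],
) -> Tuple[Line, Tuple[Line, Line]]:
    """LoA lines corrected for proportional bias via least squares.

    Regresses D on A for the perfect-agreement line ``D_hat = b1 A + b0``;
    the limits run parallel at ``± 1.96 sqrt(pi/2) mean|R|`` where R are
    the residuals (for normal residuals ``E|R| = σ sqrt(2/π)``, so the
    half-width equals 1.96 σ).
    """
    import statsmodels.api as sm

    d = np.asarray(D, dtype=float)
    a = np.asarray(A, dtype=float)
    if d.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(a) == 0:
        raise ValueError("averages are constant; regression undefined")
    fit = sm.OLS(d, sm.add_constant(a)).fit()
    b0, b1 = float(fit.params[0]), float(fit.params[1])
    half = 1.96 * np.sqrt(np.pi / 2.0) * float(np.mean(np.abs(fit.resid)))
    pa = (b0, b1)
    return pa, ((b0 - half, b1), (b0 + half, b1))


def loa_quantile_corrected(
    D: Sequence[float], A: Sequence[float],
    taus: Tuple[float, float, float] = (0.025, 0.50, 0.975),
) -> Tuple[Line, Tuple[Line, Line]]:
    """LoA lines corrected for proportional bias via quantile regression.

    Fits linear quantile regressions of D on A at τ = 0.025, 0.50 and
    0.975 (pinball-loss minimisation); the τ = 0.50 line is the
    perfect-agreement line, the outer lines the LLoA/ULoA.
    """
    import statsmodels.api as sm

    d = np.asarray(D, dtype=float)
    a = np.asarray(A, dtype=float)
    if d.size < 10:
        warnings.warn("fewer than 10 pairs: quantile LoA lines are unstable",
                      stacklevel=2)
    if np.ptp(d) == 0:
        c = float(d[0])
        return (c, 0.0), ((c, 0.0), (c, 0.0))
    X = sm.add_constant(a)
    lines = []
    for tau in taus:
        fit = sm.QuantReg(d, X).fit(q=tau)
        lines.append((float(fit.params[0]), float(fit.params[1])))
    lower, pa, upper = lines
    return pa, (lower, upper)


def icc(x_ref: Sequence[float], x_test: Sequence[float],
        form: str = "2,1") -> float:
    """Intraclass correlation, two-way random effects, absolute agreement.

    ``form="2,1"`` scores single measurements, ``form="2,k"`` the average
    over the k raters (k = 2 here). Computed from the two-way ANOVA mean
    squares (rows = targets, columns = raters).
    """
    x = np.column_stack([np.asarray(x_ref, float), np.asarray(x_test, float)])
    n, k = x.shape
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if form == "2,1":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
    elif form == "2,k":
        denom = msr + (msc - mse) / n
    else:
        raise ValueError("form must be '2,1' or '2,k'")
    if denom == 0:
        return 1.0
    return float((msr - mse) / denom)


def kendalls_w(x_ref: Sequence[float], x_test: Sequence[float]) -> float:
    """Kendall's coefficient of concordance for two raters, tie-corrected.

    Average ranks are assigned within each rater and the standard tie
    term is subtracted in the denominator, so identical series (however
    tied) score W = 1 and exactly reversed untied rankings score W = 0.
    """
    ratings = np.vstack([np.asarray(x_ref, float), np.asarray(x_test, float)])
    m, n = ratings.shape
    ranks = np.apply_along_axis(stats.rankdata, 1, ratings)
    rank_sums = ranks.sum(axis=0)
    s = np.sum((rank_sums - rank_sums.mean()) ** 2)
    tie_term = 0.0
    for row in ratings:
        _, counts = np.unique(row, return_counts=True)
        tie_term += np.sum(counts ** 3 - counts)
    denom = m * m * (n ** 3 - n) - m * tie_term
    if denom <= 0:
        return 1.0  # fully tied in every rater: trivial perfect concordance
    return float(12.0 * s / denom)


def interpret_icc(value: float) -> str:
    """Agreement band for an intraclass correlation."""
    if value > 0.750:
        return "excellent"
    if value >= 0.600:
        return "good"
    if value >= 0.400:
        return "fair"
    return "poor"


def interpret_w(value: float) -> str:
    """Agreement band for Kendall's W."""
    if value > 0.600:
        return "strong"
    if value >= 0.300:
        return "moderate"
    if value >= 0.100:
        return "weak"
    return "almost none"


def run_agreement_pipeline(
    pairs: PairedMeasurements,
    multi_stride: bool = False,
    normality_method: str = "ks",
) -> AgreementReport:
    """Execute the full gated statistics flow on one paired quantity.

    ``multi_stride=True`` reports the average-measure ICC(2,k) instead of
    the single-measure ICC(2,1) when the normal branch is taken.
    """
    D, A = pairs.D, pairs.A
    normal_d, _ = normality_test(D, normality_method)
    normal_a, _ = normality_test(A, normality_method)
    normal_ref, _ = normality_test(pairs.x_ref, normality_method)
    normal_test_, _ = normality_test(pairs.x_test, normality_method)
    normal_both = normal_ref and normal_test_

    if normal_d:
        accuracy, precision = float(D.mean()), float(D.std(ddof=1))
    else:
        accuracy, precision = float(np.median(D)), _qd(D)

    fb_p = fixed_bias_test(D, normal_d)
    pb_r, pb_p = proportional_bias_test(D, A, normal_d and normal_a)

    lo_c, hi_c = loa_classic(D, normal_d)
    if pb_p < ALPHA and np.ptp(A) > 0:
        if normal_d and normal_a:
            pa, (lo, hi) = loa_parametric_corrected(D, A)
            method = "parametric"
        else:
            pa, (lo, hi) = loa_quantile_corrected(D, A)
            method = "quantile"
        loa_lower, loa_upper = lo, hi
    else:
        loa_lower, loa_upper = lo_c, hi_c
        pa = (accuracy, 0.0)
        method = "classic"

    if normal_both:
        form = "2,k" if multi_stride else "2,1"
        coef = icc(pairs.x_ref, pairs.x_test, form=form)
        ctype = f"ICC({form})"
        band = interpret_icc(coef)
    else:
        coef = kendalls_w(pairs.x_ref, pairs.x_test)
        ctype = "KendallW"
        band = interpret_w(coef)

    return AgreementReport(
        label=pairs.label, n=int(D.size),
        normal_d=normal_d, normal_both=normal_both,
        accuracy=accuracy, precision=precision,
        fixed_bias_p=fb_p, prop_bias_r=pb_r, prop_bias_p=pb_p,
        loa_lower=loa_lower, loa_upper=loa_upper, pa_line=pa,
        loa_method=method,
        coefficient=coef, coefficient_type=ctype, interpretation=band,
    )


def plot_bland_altman(pairs: PairedMeasurements, report: AgreementReport,
                      path: Optional[str] = None):
    """Bland–Altman scatter with the PA line and the limits of agreement."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    D, A = pairs.D, pairs.A
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(A, D, "o", ms=3, alpha=0.5)
    xs = np.linspace(A.min(), A.max(), 50)

    def as_line(v):
        return (v[0] + v[1] * xs) if isinstance(v, tuple) else np.full_like(xs, v)

    ax.plot(xs, as_line(report.pa_line), "k--", label="PA")
    ax.plot(xs, as_line(report.loa_lower), "k:", label="LLoA")
    ax.plot(xs, as_line(report.loa_upper), "k:", label="ULoA")
    ax.set_xlabel(f"average of systems ({pairs.label})")
    ax.set_ylabel("difference (test - ref)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
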