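"""Method-comparison validity statistics for paired body-fat estimates.

Given paired predicted vs criterion BF% series this module computes the
standard agreement battery used to validate body-composition methods:

* constant error CE — mean(predicted − criterion), the systematic bias;
* dependent (paired) t-test on the differences, two-sided, judged at a
  Bonferroni-adjusted alpha (0.05 / comparisons per group = 0.025);
* Cohen's d with pooled SD sqrt((sd₁² + sd₂²)/2), magnitude-labelled on
  Hopkins' scale (≤0.2 trivial, ≤0.6 small, ≤1.2 moderate, ≤2.0 large,
  >2.0 very large; exact boundaries go to the lower bin);
* Pearson r with the companion magnitude scale (<0.31 small, <0.50
  moderate, <0.70 large, <0.90 very large, ≥0.90 near perfect, binned
  on |r|);
* SEE — residual standard error sqrt(SS_res/(n−2)) from regressing the
  criterion on the predicted values; equivalently
  sd_crit·sqrt(1−r²)·sqrt((n−1)/(n−2));
* TE — root-mean-square of the individual differences (denominator n);
* Bland-Altman 95% limits of agreement CE ± 1.96·SD_diff (sample SD,
  denominator n−1), with per-subject points for plotting;
* proportional bias — least-squares slope of the differences on the mean
  of the two methods (or on the criterion), with its two-sided p.

CE, SD_diff and TE satisfy TE² = CE² + ((n−1)/n)·SD_diff² identically,
and TE ≥ |CE| always; both are exploited as self-checks in the test
suite.  Degenerate inputs (zero-variance differences, zero pooled SD)
are reported with an explicit flag instead of NaN surprises.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class PairedSeries:
    """Paired predicted / criterion values for one group × method."""

    predicted: np.ndarray
    criterion: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "predicted", np.asarray(self.predicted, dtype=float))
        object.__setattr__(self, "criterion", np.asarray(self.criterion, dtype=float))
        if self.predicted.ndim != 1 or self.criterion.ndim != 1:
            raise ValueError("series must be one-dimensional")
        if self.predicted.shape != self.criterion.shape:
            raise ValueError(
                f"length mismatch: {self.predicted.size} predicted vs "
                f"{self.criterion.size} criterion values"
            )
        if self.predicted.size == 0:
            raise ValueError("series must be non-empty")

    @property
    def n(self) -> int:
        return int(self.predicted.size)

    @property
    def differences(self) -> np.ndarray:
        return self.predicted - self.criterion


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs of the agreement battery.

    ``adjusted_alpha`` is derived as alpha_base / comparisons_per_group
    (Bonferroni); significance is inclusive, p ≤ adjusted_alpha.
    """

    alpha_base: float = 0.05
    comparisons_per_group: int = 2
    loa_z: float = 1.96
    bias_regressor_mode: str = "mean_of_methods"  # or "criterion"

    @property
    def adjusted_alpha(self) -> float:
        return self.alpha_base / self.comparisons_per_group


DEFAULT_ANALYSIS = AnalysisConfig()

_D_BINS = [(0.2, "trivial"), (0.6, "small"), (1.2, "moderate"), (2.0, "large")]
_R_BINS = [(0.31, "small"), (0.50, "moderate"), (0.70, "large"), (0.90, "very large")]


def d_magnitude(d: float) -> str:
    """Hopkins effect-size label; boundary values fall in the lower bin."""
    a = abs(d)
    for upper, label in _D_BINS:
        if a <= upper:
            return label
    return "very large"


def r_magnitude(r: float) -> str:
    """Correlation magnitude label, binned on |r|."""
    a = abs(r)
    for upper, label in _R_BINS:
        if a < upper:
            return label
    return "near perfect"


def constant_error(s: PairedSeries) -> float:
    """Mean predicted-minus-criterion difference (systematic bias), %."""
    return float(np.mean(s.differences))


def dependent_t_test(
    s: PairedSeries, cfg: AnalysisConfig = DEFAULT_ANALYSIS
) -> tuple[float, int, float, bool, tuple[str, ...]]:
    """Paired t-test on the differences.

    Returns ``(t, df, p, significant, flags)`` with df = n − 1 and a
    two-sided p.  Zero-variance differences are degenerate: p = 0 for a
    nonzero mean difference, p = 1 when every difference is zero; both
    are flagged rather than raised.
    """
    if s.n < 2:
        raise ValueError("paired t-test requires n >= 2")
    d = s.differences
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    df = s.n - 1
    flags: tuple[str, ...] = ()
    if sd == 0.0:
        flags = ("degenerate_zero_variance",)
        t = math.inf if mean > 0 else (-math.inf if mean < 0 else 0.0)
        p = 0.0 if mean != 0 else 1.0
    else:
        t = mean / (sd / math.sqrt(s.n))
        p = float(2.0 * sps.t.sf(abs(t), df))
    return t, df, p, p <= cfg.adjusted_alpha, flags


def cohens_d(s: PairedSeries) -> tuple[float, str, tuple[str, ...]]:
    """Effect size |mean_pred − mean_crit| / sqrt((sd_pred² + sd_crit²)/2)."""
    if s.n < 2:
        raise ValueError("Cohen's d requires n >= 2")
    sd_p = float(np.std(s.predicted, ddof=1))
    sd_c = float(np.std(s.criterion, ddof=1))
    pooled = math.sqrt((sd_p * sd_p + sd_c * sd_c) / 2.0)
    if pooled == 0.0:
        return math.nan, "undefined", ("degenerate_zero_pooled_sd",)
    d = abs(float(np.mean(s.predicted)) - float(np.mean(s.criterion))) / pooled
    return d, d_magnitude(d), ()


def pearson_r(s: PairedSeries) -> tuple[float, str, tuple[str, ...]]:
    """Sample Pearson correlation with magnitude label (binned on |r|)."""
    if s.n < 3:
        raise ValueError("Pearson r requires n >= 3")
    if np.std(s.predicted) == 0.0 or np.std(s.criterion) == 0.0:
        return math.nan, "undefined", ("degenerate_zero_variance",)
    r = float(sps.pearsonr(s.predicted, s.criterion).statistic)
    return r, r_magnitude(r), ()


def standard_error_of_estimate(s: PairedSeries) -> float:
    """SEE: residual SD from regressing criterion on predicted, %.

    sqrt(Σ residual² / (n − 2)); equals sd_crit·sqrt(1−r²)·sqrt((n−1)/(n−2)).
    """
    if s.n < 3:
        raise ValueError("SEE requires n >= 3")
    if np.std(s.predicted) == 0.0:
        raise ValueError("SEE undefined: predicted series has zero variance")
    slope, intercept = np.polyfit(s.predicted, s.criterion, 1)
    residuals = s.criterion - (slope * s.predicted + intercept)
    return float(math.sqrt(np.sum(residuals**2) / (s.n - 2)))


def total_error(s: PairedSeries) -> float:
    """TE: root-mean-square individual difference (denominator n), %."""
    d = s.differences
    return float(math.sqrt(np.mean(d * d)))


@dataclass(frozen=True)
class BlandAltman:
    ce: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    mean_of_methods: np.ndarray
    differences: np.ndarray


def bland_altman(s: PairedSeries, cfg: AnalysisConfig = DEFAULT_ANALYSIS) -> BlandAltman:
    """95% limits of agreement CE ± z·SD_diff with per-subject points."""
    if s.n < 2:
        raise ValueError("Bland-Altman requires n >= 2")
    d = s.differences
    ce = float(np.mean(d))
    sd_diff = float(np.std(d, ddof=1))
    half = cfg.loa_z * sd_diff
    return BlandAltman(
        ce=ce,
        sd_diff=sd_diff,
        loa_lower=ce - half,
        loa_upper=ce + half,
        mean_of_methods=(s.predicted + s.criterion) / 2.0,
        differences=d,
    )


def proportional_bias(
    s: PairedSeries, cfg: AnalysisConfig = DEFAULT_ANALYSIS
) -> tuple[float, float, float, tuple[str, ...]]:
    """Least-squares fit of differences on measurement magnitude.

    The regressor defaults to the mean of the two methods (standard
    Bland-Altman practice); ``bias_regressor_mode="criterion"`` regresses
    on the criterion instead.  Returns ``(slope, intercept, p, flags)``
    with a two-sided p for slope = 0.  A nonzero slope means the
    disagreement grows (or shrinks) with body-fat level.
    """
    if s.n < 3:
        raise ValueError("proportional-bias regression requires n >= 3")
    if cfg.bias_regressor_mode == "criterion":
        x = s.criterion
    elif cfg.bias_regressor_mode == "mean_of_methods":
        x = (s.predicted + s.criterion) / 2.0
    else:
        raise ValueError(f"unknown bias_regressor_mode {cfg.bias_regressor_mode!r}")
    if np.std(x) == 0.0:
        return math.nan, math.nan, math.nan, ("degenerate_zero_regressor_variance",)
    fit = sps.linregress(x, s.differences)
    return float(fit.slope), float(fit.intercept), float(fit.pvalue), ()


@dataclass(frozen=True)
class ValidityReport:
    """One prediction model vs the criterion within one group.

    Collects every column of the standard agreement table plus the
    Bland-Altman scatter.  Satisfies loa_upper = ce + loa_halfwidth,
    loa_lower = ce − loa_halfwidth, and te² = ce² + ((n−1)/n)·sd_diff².
    """

    group: str
    method: str
    n: int
    mean_pred: float
    sd_pred: float
    mean_crit: float
    sd_crit: float
    ce: float
    t_stat: float
    df: int
    p_value: float
    significant: bool
    cohens_d: float
    d_magnitude: str
    r: float
    r_magnitude: str
    see: float
    te: float
    sd_diff: float
    loa_halfwidth: float
    loa_upper: float
    loa_lower: float
    bias_slope: float
    bias_intercept: float
    bias_p: float
    ba_mean_of_methods: np.ndarray = field(repr=False)
    ba_differences: np.ndarray = field(repr=False)
    flags: tuple[str, ...] = ()


#: Display rounding applied only at report serialization.
ROUNDING = {
    "mean_pred": 1, "sd_pred": 1, "mean_crit": 1, "sd_crit": 1,
    "ce": 1, "loa_halfwidth": 1, "loa_upper": 1, "loa_lower": 1,
    "cohens_d": 2, "see": 2, "te": 2,
    "r": 3, "bias_slope": 3, "bias_intercept": 3, "bias_p": 3, "p_value": 3,
}


def build_validity_report(
    group: str,
    method: str,
    s: PairedSeries,
    cfg: AnalysisConfig = DEFAULT_ANALYSIS,
) -> ValidityReport:
    """Assemble the full agreement table row for one group × method."""
    try:
        t, df, p, sig, t_flags = dependent_t_test(s, cfg)
        d, d_mag, d_flags = cohens_d(s)
        r, r_mag, r_flags = pearson_r(s)
        see = standard_error_of_estimate(s)
        te = total_error(s)
        ba = bland_altman(s, cfg)
        slope, intercept, bias_p, b_flags = proportional_bias(s, cfg)
    except ValueError as exc:
        raise ValueError(f"group {group}, method {method}: {exc}") from exc
    return ValidityReport(
        group=str(group),
        method=str(method),
        n=s.n,
        mean_pred=float(np.mean(s.predicted)),
        sd_pred=float(np.std(s.predicted, ddof=1)),
        mean_crit=float(np.mean(s.criterion)),
        sd_crit=float(np.std(s.criterion, ddof=1)),
        ce=ba.ce,
        t_stat=t,
        df=df,
        p_value=p,
        significant=sig,
        cohens_d=d,
        d_magnitude=d_mag,
        r=r,
        r_magnitude=r_mag,
        see=see,
        te=te,
        sd_diff=ba.sd_diff,
        loa_halfwidth=cfg.loa_z * ba.sd_diff,
        loa_upper=ba.loa_upper,
        loa_lower=ba.loa_lower,
        bias_slope=slope,
        bias_intercept=intercept,
        bias_p=bias_p,
        ba_mean_of_methods=ba.mean_of_methods,
        ba_differences=ba.differences,
        flags=t_flags + d_flags + r_flags + b_flags,
    )


def report_row(report: ValidityReport) -> dict:
    """Serialize one report to a flat dict with display rounding applied.

    Rounding (1 dp for BF% means/CE/LOA, 2 for d/SEE/TE, 3 for r and the
    regression block) happens only here; in-memory reports stay exact.
    """
    row = {
        "group": report.group,
        "method": report.method,
        "n": report.n,
    }
    for name in (
        "mean_pred", "sd_pred", "mean_crit", "sd_crit", "p_value", "cohens_d",
        "d_magnitude", "r", "r_magnitude", "see", "te", "ce", "loa_halfwidth",
        "loa_upper", "loa_lower", "bias_slope", "bias_p",
    ):
        value = getattr(report, name)
        if name in ROUNDING and isinstance(value, float) and math.isfinite(value):
            value = round(value, ROUNDING[name])
        row[name] = value
    row["significant"] = bool(report.significant)
    row["flags"] = ";".join(report.flags)
    return row
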