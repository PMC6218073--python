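"""Agreement-statistics battery: worked examples, oracles, identities."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fourc import (
    AnalysisConfig,
    PairedSeries,
    bland_altman,
    build_validity_report,
    cohens_d,
    constant_error,
    dependent_t_test,
    pearson_r,
    proportional_bias,
    report_row,
    standard_error_of_estimate,
    total_error,
)
from fourc.validity import d_magnitude, r_magnitude


def series(pred, crit):
    return PairedSeries(np.asarray(pred, float), np.asarray(crit, float))


def random_series(rng, n=None):
    n = n or int(rng.integers(3, 60))
    crit = rng.normal(25, 8, n)
    pred = crit + rng.normal(1, 3, n)
    return series(pred, crit)


# --- constant error -------------------------------------------------------

def test_constant_error_examples(rng):
    x = rng.normal(size=10)
    assert constant_error(series(x, x)) == 0.0
    assert constant_error(series(x + 1.0, x)) == pytest.approx(1.0)
    # difference of the group means, independent of the spread
    assert constant_error(series([42.7] * 35, [40.5] * 35)) == pytest.approx(2.2)


# --- dependent t ----------------------------------------------------------

def test_t_test_symmetric_differences():
    t, df, p, sig, flags = dependent_t_test(series([1.0, 3.0], [2.0, 2.0]))
    assert t == pytest.approx(0.0)
    assert p == pytest.approx(1.0)
    assert not sig and not flags


def test_t_test_closed_form():
    # diffs {1,2,3}: mean 2, sd 1, t = 2/(1/sqrt(3)) = 2*sqrt(3)
    t, df, p, sig, flags = dependent_t_test(series([1.0, 2.0, 3.0], [0.0, 0.0, 0.0]))
    assert t == pytest.approx(2 * math.sqrt(3), rel=1e-12)
    assert df == 2
    assert p == pytest.approx(2 * 0.0371, abs=2e-3)  # 2-sided tail of t_2


def test_significance_threshold_inclusive():
    cfg = AnalysisConfig()
    assert cfg.adjusted_alpha == pytest.approx(0.025)
    # p just above the adjusted alpha must not be declared significant
    rng = np.random.default_rng(3)
    for _ in range(50):
        s = random_series(rng)
        _, _, p, sig, _ = dependent_t_test(s, cfg)
        assert sig == (p <= 0.025)


def test_t_test_degenerate_differences():
    t, df, p, sig, flags = dependent_t_test(series([2.0, 2.0], [1.0, 1.0]))
    assert p == 0.0 and flags
    t, df, p, sig, flags = dependent_t_test(series([1.0, 1.0], [1.0, 1.0]))
    assert p == 1.0 and flags and not sig


# --- Cohen's d ------------------------------------------------------------

def test_cohens_d_identical_series(rng):
    x = rng.normal(size=12)
    d, mag, flags = cohens_d(series(x, x))
    assert d == 0.0 and mag == "trivial"


def test_cohens_d_printed_summary_case(rng):
    """Means 42.7 vs 40.5 with SDs 9.1/8.7 give d = 0.247 ('small')."""
    z = np.r_[np.ones(17), -np.ones(17), 0.0]  # mean 0, sum of squares n-1
    pred = 42.7 + 9.1 * z
    crit = 40.5 + 8.7 * z
    d, mag, flags = cohens_d(series(pred, crit))
    assert d == pytest.approx(0.2471, abs=5e-4)
    assert round(d, 2) == 0.25
    assert mag == "small"


def test_cohens_d_unit_case(rng):
    """Means one pooled SD apart give exactly d = 1 ('moderate')."""
    z = np.r_[np.ones(8), -np.ones(8), 0.0]
    sd = 4.0
    d, mag, _ = cohens_d(series(30.0 + sd * z, 26.0 + sd * z))
    assert d == pytest.approx(1.0, rel=1e-12)
    assert mag == "moderate"


def test_cohens_d_zero_spread_flagged():
    d, mag, flags = cohens_d(series([3.0, 3.0], [1.0, 1.0]))
    assert math.isnan(d) and mag == "undefined" and flags


def test_magnitude_bins_are_total_and_boundary_goes_low():
    assert [d_magnitude(v) for v in (0.0, 0.2, 0.21, 0.6, 1.2, 2.0, 2.01)] == [
        "trivial", "trivial", "small", "small", "moderate", "large", "very large",
    ]
    assert [r_magnitude(v) for v in (0.0, 0.30, 0.31, 0.49, 0.50, 0.89, 0.90, 1.0)] == [
        "small", "small", "moderate", "moderate", "large", "very large",
        "near perfect", "near perfect",
    ]
    for v in np.linspace(-3, 3, 601):
        assert d_magnitude(v) in {"trivial", "small", "moderate", "large", "very large"}
    for v in np.linspace(-1, 1, 401):
        assert r_magnitude(v) in {"small", "moderate", "large", "very large", "near perfect"}


# --- Pearson r ------------------------------------------------------------

def test_pearson_r_examples(rng):
    x = rng.normal(size=20)
    r, mag, _ = pearson_r(series(x, x))
    assert r == pytest.approx(1.0) and mag == "near perfect"
    r, mag, _ = pearson_r(series(-x + 3.0, x))
    assert r == pytest.approx(-1.0) and mag == "near perfect"  # binned on |r|
    r, mag, _ = pearson_r(series([1, 2, 3, 4], [1, 3, 2, 4]))
    assert r == pytest.approx(0.8, rel=1e-12)
    assert mag == "very large"


def test_pearson_r_zero_variance_flagged():
    r, mag, flags = pearson_r(series([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))
    assert math.isnan(r) and mag == "undefined" and flags


# --- SEE ------------------------------------------------------------------

def brute_force_see(pred, crit):
    """Explicit normal-equations least squares of criterion on predicted."""
    X = np.c_[np.ones_like(pred), pred]
    beta = np.linalg.solve(X.T @ X, X.T @ crit)
    resid = crit - X @ beta
    return math.sqrt(resid @ resid / (len(pred) - 2))


def test_see_zero_for_exact_linear_relation():
    pred = np.array([1.0, 2.0, 3.0, 4.0])
    assert standard_error_of_estimate(series(pred, 2 * pred - 1)) == pytest.approx(
        0.0, abs=1e-10
    )


def test_see_matches_brute_force_least_squares(rng):
    for _ in range(50):
        s = random_series(rng)
        assert standard_error_of_estimate(s) == pytest.approx(
            brute_force_see(s.predicted, s.criterion), rel=1e-9
        )


def test_see_closed_form_identity(rng):
    """SEE == sd_crit*sqrt(1-r^2)*sqrt((n-1)/(n-2))."""
    for _ in range(50):
        s = random_series(rng)
        n = s.n
        sd_c = np.std(s.criterion, ddof=1)
        r, _, _ = pearson_r(s)
        closed = sd_c * math.sqrt(1 - r * r) * math.sqrt((n - 1) / (n - 2))
        assert standard_error_of_estimate(s) == pytest.approx(closed, rel=1e-9)
        # consequently SEE can never exceed sd_crit * sqrt((n-1)/(n-2))
        assert standard_error_of_estimate(s) <= sd_c * math.sqrt((n - 1) / (n - 2)) + 1e-12


def test_see_requires_three_points():
    with pytest.raises(ValueError):
        standard_error_of_estimate(series([1.0, 2.0], [1.0, 2.0]))


# --- TE -------------------------------------------------------------------

def test_total_error_examples(rng):
    x = rng.normal(size=9)
    assert total_error(series(x, x)) == 0.0
    assert total_error(series([0.0, 2.0], [0.0, 0.0])) == pytest.approx(math.sqrt(2))
    s = series([2.0, 3.0, 4.0, 5.0], [1.0, 2.0, 3.0, 4.0])
    assert total_error(s) == pytest.approx(1.0)  # TE = |CE| when diffs constant
    assert total_error(s) == pytest.approx(abs(constant_error(s)))


# --- Bland-Altman ---------------------------------------------------------

def test_bland_altman_printed_summary_closure():
    """CE 2.3 with halfwidth 2.5 closes to limits 4.8 / -0.2."""
    sd = 2.5 / 1.96
    z = np.r_[np.ones(17), -np.ones(17), 0.0]
    crit = 40.5 + 8.1 * np.linspace(-1, 1, 35)
    pred = crit + 2.3 + sd * z
    ba = bland_altman(series(pred, crit))
    assert ba.ce == pytest.approx(2.3)
    assert ba.loa_upper == pytest.approx(4.8)
    assert ba.loa_lower == pytest.approx(-0.2)


def test_bland_altman_constant_difference(rng):
    x = rng.normal(25, 5, 10)
    ba = bland_altman(series(x + 3.0, x))
    assert ba.loa_upper == ba.loa_lower == pytest.approx(3.0)


def test_bland_altman_hand_example():
    ba = bland_altman(series([0.0, 2.0], [1.0, 1.0]))  # diffs {-1, +1}
    assert ba.ce == pytest.approx(0.0)
    assert ba.sd_diff == pytest.approx(math.sqrt(2))
    assert ba.loa_upper == pytest.approx(1.96 * math.sqrt(2))
    assert ba.loa_lower == pytest.approx(-1.96 * math.sqrt(2))
    np.testing.assert_allclose(ba.mean_of_methods, [0.5, 1.5])


# --- proportional bias ----------------------------------------------------

def test_proportional_bias_constant_difference(rng):
    x = rng.normal(30, 6, 20)
    slope, intercept, p, flags = proportional_bias(series(x + 2.0, x))
    assert slope == pytest.approx(0.0, abs=1e-12)


def test_proportional_bias_constructed_slope():
    """difference = 0.1 * mean-of-methods exactly -> slope 0.1."""
    mean = np.linspace(10, 50, 12)
    diff = 0.1 * mean
    s = series(mean + diff / 2, mean - diff / 2)
    slope, intercept, p, flags = proportional_bias(s)
    assert slope == pytest.approx(0.1, rel=1e-9)
    assert intercept == pytest.approx(0.0, abs=1e-9)
    assert p < 1e-10


def test_proportional_bias_matches_normal_equations(rng):
    for _ in range(20):
        s = random_series(rng, n=6)
        x = (s.predicted + s.criterion) / 2
        X = np.c_[np.ones(6), x]
        beta = np.linalg.solve(X.T @ X, X.T @ s.differences)
        resid = s.differences - X @ beta
        se = math.sqrt(resid @ resid / 4 / ((x - x.mean()) ** 2).sum())
        from scipy.stats import t as tdist

        p_oracle = 2 * tdist.sf(abs(beta[1] / se), 4)
        slope, _, p, _ = proportional_bias(s)
        assert slope == pytest.approx(beta[1], rel=1e-9)
        assert p == pytest.approx(p_oracle, rel=1e-9)


def test_proportional_bias_criterion_regressor(rng):
    crit = np.linspace(10, 50, 15)
    pred = crit + 0.2 * crit
    cfg = AnalysisConfig(bias_regressor_mode="criterion")
    slope, _, _, _ = proportional_bias(series(pred, crit), cfg)
    assert slope == pytest.approx(0.2, rel=1e-9)


# --- algebraic identities (property suite) --------------------------------

@given(st.integers(0, 10_000))
@settings(deadline=None, max_examples=60)
def test_te_ce_sd_identity(seed):
    """TE^2 = CE^2 + ((n-1)/n) SD_diff^2 for any paired series."""
    rng = np.random.default_rng(seed)
    s = random_series(rng)
    ce = constant_error(s)
    te = total_error(s)
    sd = np.std(s.differences, ddof=1)
    assert te**2 == pytest.approx(ce**2 + (s.n - 1) / s.n * sd**2, rel=1e-9)
    assert te >= abs(ce) - 1e-12


@given(st.integers(0, 10_000), st.floats(-30, 30, allow_nan=False))
@settings(deadline=None, max_examples=60)
def test_shift_invariance(seed, c):
    """Adding a common constant to both series leaves CE/TE/LOA unchanged;
    shifting only one series leaves r, SEE and the bias slope unchanged."""
    rng = np.random.default_rng(seed)
    s = random_series(rng)
    shifted_both = series(s.predicted + c, s.criterion + c)
    assert constant_error(shifted_both) == pytest.approx(constant_error(s), abs=1e-9)
    assert total_error(shifted_both) == pytest.approx(total_error(s), abs=1e-9)
    ba, ba2 = bland_altman(s), bland_altman(shifted_both)
    assert ba2.loa_upper == pytest.approx(ba.loa_upper, abs=1e-9)
    assert ba2.loa_lower == pytest.approx(ba.loa_lower, abs=1e-9)

    shifted_one = series(s.predicted + c, s.criterion)
    assert pearson_r(shifted_one)[0] == pytest.approx(pearson_r(s)[0], rel=1e-9)
    assert standard_error_of_estimate(shifted_one) == pytest.approx(
        standard_error_of_estimate(s), rel=1e-9
    )
    assert proportional_bias(shifted_one)[0] == pytest.approx(
        proportional_bias(s)[0], rel=1e-9
    )


def test_loa_width_identity(rng):
    for _ in range(30):
        s = random_series(rng)
        ba = bland_altman(s)
        assert ba.loa_upper - ba.loa_lower == pytest.approx(
            2 * 1.96 * ba.sd_diff, rel=1e-12
        )


# --- full report ----------------------------------------------------------

def test_perfect_prediction_report(rng):
    x = rng.normal(25, 6, 20)
    report = build_validity_report("NW", "4C-DXA1", series(x, x))
    assert report.ce == 0.0
    assert report.te == 0.0
    assert report.see == pytest.approx(0.0, abs=1e-9)
    assert report.loa_upper == report.loa_lower == 0.0
    assert report.d_magnitude == "trivial"
    assert "degenerate_zero_variance" in report.flags  # zero-variance diffs


def test_report_invariants_and_serialization(rng):
    s = random_series(rng, n=40)
    report = build_validity_report("OW_BMI", "4C-DXA2", s)
    assert report.loa_upper == pytest.approx(report.ce + report.loa_halfwidth)
    assert report.loa_lower == pytest.approx(report.ce - report.loa_halfwidth)
    assert report.te >= abs(report.ce)
    assert report.te**2 == pytest.approx(
        report.ce**2 + (report.n - 1) / report.n * report.sd_diff**2, rel=1e-9
    )

    row = report_row(report)
    # display rounding: 1 dp for means/CE/LOA, 2 for d/SEE/TE, 3 for r/regression
    assert row["ce"] == round(report.ce, 1)
    assert row["loa_upper"] == round(report.loa_upper, 1)
    assert row["see"] == round(report.see, 2)
    assert row["te"] == round(report.te, 2)
    assert row["cohens_d"] == round(report.cohens_d, 2)
    assert row["r"] == round(report.r, 3)
    assert row["bias_slope"] == round(report.bias_slope, 3)
    assert list(row)[:3] == ["group", "method", "n"]


def test_report_error_carries_context():
    with pytest.raises(ValueError, match="group NW, method 4C-DXA1"):
        build_validity_report("NW", "4C-DXA1", series([1.0, 2.0], [1.0, 2.0]))


def test_mismatched_series_rejected():
    with pytest.raises(ValueError):
        PairedSeries(np.array([1.0, 2.0]), np.array([1.0]))
    with pytest.raises(ValueError):
        PairedSeries(np.array([]), np.array([]))
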