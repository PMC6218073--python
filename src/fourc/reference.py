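"""Published summary statistics from the reference validation study.

The study that motivates this package compared two DXA-derived body-volume
equations inside a four-compartment model against an ADP-based criterion in
115 adults stratified by BMI and waist circumference.  Its raw subject data
were never deposited, but its printed group summaries are usable in two
ways: as the distributional targets of the default synthetic cohort, and as
inputs to internal-consistency worked examples (e.g. a constant error must
equal the difference of the printed group means; limits of agreement must
equal CE ± halfwidth).

``COHORT_SUMMARY`` holds the subject-characteristics table (mean, SD) per
group × sex cell.  ``AGREEMENT_SUMMARY`` holds the validity-statistics
table per group × prediction model.  Values are stored exactly as printed
(1 decimal for means/CE/LOA, 2 for d/SEE/TE, 3 for r and regression
coefficients).
"""

from __future__ import annotations

GROUPS = ("NW", "OW_BMI", "OW_BMI_WC")

#: (mean, sd) per variable, per (group, sex) cell; n per cell.
COHORT_SUMMARY: dict[tuple[str, str], dict] = {
    ("NW", "M"): {
        "n": 20,
        "age": (23.2, 2.9),
        "height_cm": (178.4, 5.8),
        "body_mass_kg": (74.1, 6.3),
        "bmi": (23.1, 1.5),
        "wc_cm": (76.8, 4.2),
        "ffm_kg": (65.9, 6.1),
        "fm_kg": (8.2, 3.2),
        "bf_percent": (11.0, 4.1),
    },
    ("OW_BMI", "M"): {
        "n": 20,
        "age": (26.5, 9.1),
        "height_cm": (178.6, 9.7),
        "body_mass_kg": (89.4, 11.9),
        "bmi": (28.1, 2.8),
        "wc_cm": (86.3, 6.6),
        "ffm_kg": (73.2, 8.2),
        "fm_kg": (16.2, 8.2),
        "bf_percent": (17.6, 7.3),
    },
    ("OW_BMI_WC", "M"): {
        "n": 14,
        "age": (34.6, 10.2),
        "height_cm": (179.1, 8.5),
        "body_mass_kg": (120.4, 20.4),
        "bmi": (37.5, 4.8),
        "wc_cm": (112.0, 10.8),
        "ffm_kg": (78.1, 12.0),
        "fm_kg": (42.3, 15.4),
        "bf_percent": (34.5, 8.5),
    },
    ("NW", "F"): {
        "n": 20,
        "age": (26.4, 8.2),
        "height_cm": (163.6, 6.5),
        "body_mass_kg": (57.2, 7.8),
        "bmi": (24.1, 1.7),
        "wc_cm": (67.2, 4.7),
        "ffm_kg": (45.2, 6.2),
        "fm_kg": (12.0, 3.6),
        "bf_percent": (20.8, 5.3),
    },
    ("OW_BMI", "F"): {
        "n": 20,
        "age": (22.0, 2.8),
        "height_cm": (162.6, 7.2),
        "body_mass_kg": (71.1, 6.6),
        "bmi": (26.9, 1.6),
        "wc_cm": (77.0, 5.1),
        "ffm_kg": (47.1, 6.3),
        "fm_kg": (24.0, 4.3),
        "bf_percent": (33.9, 5.7),
    },
    ("OW_BMI_WC", "F"): {
        "n": 21,
        "age": (36.9, 13.2),
        "height_cm": (165.4, 5.3),
        "body_mass_kg": (104.7, 20.7),
        "bmi": (38.4, 8.0),
        "wc_cm": (103.8, 14.7),
        "ffm_kg": (57.3, 7.9),
        "fm_kg": (47.4, 15.3),
        "bf_percent": (44.5, 6.2),
    },
}

#: Validity statistics per (group, prediction model), with the criterion
#: group BF% summary alongside.  loa_halfwidth is 1.96·SD of differences.
AGREEMENT_SUMMARY: dict[tuple[str, str], dict] = {
    ("NW", "4C-DXA1"): {
        "n": 40,
        "mean_crit": 15.9, "sd_crit": 6.8,
        "mean_pred": 13.0, "sd_pred": 6.0,
        "p_value": "<0.001", "cohens_d": 0.45, "r": 0.927,
        "see": 2.59, "te": 3.91,
        "ce": -3.0, "loa_halfwidth": 5.0, "loa_upper": 2.0, "loa_lower": -8.0,
        "bias_slope": -0.132, "bias_p": 0.042,
    },
    ("NW", "4C-DXA2"): {
        "n": 40,
        "mean_crit": 15.9, "sd_crit": 6.8,
        "mean_pred": 20.7, "sd_pred": 6.2,
        "p_value": "<0.001", "cohens_d": 0.74, "r": 0.984,
        "see": 1.24, "te": 4.99,
        "ce": 4.8, "loa_halfwidth": 2.5, "loa_upper": 7.4, "loa_lower": 2.3,
        "bias_slope": -0.097, "bias_p": 0.002,
    },
    ("OW_BMI", "4C-DXA1"): {
        "n": 40,
        "mean_crit": 25.8, "sd_crit": 10.5,
        "mean_pred": 25.2, "sd_pred": 9.6,
        "p_value": 0.112, "cohens_d": 0.17, "r": 0.983,
        "see": 1.92, "te": 2.05,
        "ce": -0.5, "loa_halfwidth": 3.9, "loa_upper": 3.4, "loa_lower": -4.5,
        "bias_slope": -0.085, "bias_p": 0.007,
    },
    ("OW_BMI", "4C-DXA2"): {
        "n": 40,
        "mean_crit": 25.8, "sd_crit": 10.5,
        "mean_pred": 29.7, "sd_pred": 9.4,
        "p_value": "<0.001", "cohens_d": 0.23, "r": 0.994,
        "see": 1.20, "te": 4.69,
        "ce": 4.5, "loa_halfwidth": 2.9, "loa_upper": 7.4, "loa_lower": 1.5,
        "bias_slope": -0.005, "bias_p": 0.832,
    },
    ("OW_BMI_WC", "4C-DXA1"): {
        "n": 35,
        "mean_crit": 40.5, "sd_crit": 8.7,
        "mean_pred": 42.7, "sd_pred": 9.1,
        "p_value": "<0.001", "cohens_d": 0.25, "r": 0.978,
        "see": 1.84, "te": 2.88,
        "ce": 2.2, "loa_halfwidth": 3.8, "loa_upper": 6.0, "loa_lower": -1.5,
        "bias_slope": 0.050, "bias_p": 0.183,
    },
    ("OW_BMI_WC", "4C-DXA2"): {
        "n": 35,
        "mean_crit": 40.5, "sd_crit": 8.7,
        "mean_pred": 42.8, "sd_pred": 8.1,
        "p_value": "<0.001", "cohens_d": 0.27, "r": 0.991,
        "see": 1.15, "te": 2.60,
        "ce": 2.3, "loa_halfwidth": 2.5, "loa_upper": 4.8, "loa_lower": -0.2,
        "bias_slope": -0.076, "bias_p": 0.020,
    },
}
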