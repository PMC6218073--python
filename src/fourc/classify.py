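"""BMI / waist-circumference risk-group classification.

Adults are assigned to one of three study groups: normal weight
(BMI < 25 kg/m² with waist circumference below the sex-specific at-risk
threshold), overweight by BMI only (BMI ≥ 25, waist below threshold), or
overweight by BMI with at-risk waist (BMI ≥ 25 and waist ≥ 88.0 cm for
women / 102.0 cm for men).  The BMI cut-off and both waist thresholds are
inclusive on the at-risk side.

The fourth cell of the (BMI, waist) plane — BMI below 25 with an at-risk
waist — has no defined group and is labelled UNCLASSIFIED; such subjects
are counted and dropped from group analyses.

By default the two overweight groups are mutually exclusive (the BMI-only
group requires a below-threshold waist).  ``group_mode="inclusive"``
instead places every BMI ≥ 25 subject in OW_BMI as well as, when the waist
qualifies, OW_BMI_WC; with that reading a subject may carry two labels and
:func:`classify_group` reports the more specific one.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .records import Sex


class Group(str, Enum):
    NW = "NW"
    OW_BMI = "OW_BMI"
    OW_BMI_WC = "OW_BMI_WC"
    UNCLASSIFIED = "UNCLASSIFIED"


@dataclass(frozen=True)
class ClassificationConfig:
    bmi_cutoff: float = 25.0
    wc_threshold_female: float = 88.0
    wc_threshold_male: float = 102.0
    group_mode: str = "exclusive"  # or "inclusive"

    def wc_threshold(self, sex: Sex) -> float:
        sex = Sex(sex)
        return self.wc_threshold_male if sex is Sex.MALE else self.wc_threshold_female


DEFAULT_CLASSIFICATION = ClassificationConfig()


@dataclass(frozen=True)
class GroupLabel:
    """Classification outcome with the inputs and threshold that drove it."""

    label: Group
    bmi_used: float
    wc_used: float
    wc_threshold_used: float


def classify_group(
    bmi: float,
    wc_cm: float,
    sex: Sex,
    config: ClassificationConfig = DEFAULT_CLASSIFICATION,
) -> GroupLabel:
    """Assign one subject to NW / OW_BMI / OW_BMI_WC / UNCLASSIFIED.

    The four outcomes partition the (BMI, waist) plane for each sex:
    exactly one label is returned for every positive input pair.
    """
    if bmi <= 0 or wc_cm <= 0:
        raise ValueError("BMI and waist circumference must be strictly positive")
    threshold = config.wc_threshold(sex)
    at_risk_wc = wc_cm >= threshold
    overweight = bmi >= config.bmi_cutoff

    if overweight:
        if at_risk_wc:
            label = Group.OW_BMI_WC
        else:
            label = Group.OW_BMI
    else:
        label = Group.UNCLASSIFIED if at_risk_wc else Group.NW
    return GroupLabel(label=label, bmi_used=bmi, wc_used=wc_cm, wc_threshold_used=threshold)


def group_memberships(
    bmi: float,
    wc_cm: float,
    sex: Sex,
    config: ClassificationConfig = DEFAULT_CLASSIFICATION,
) -> tuple[Group, ...]:
    """All groups a subject belongs to under the configured reading.

    Exclusive mode returns the single :func:`classify_group` label.
    Inclusive mode additionally lists OW_BMI for every overweight subject,
    so an at-risk-waist overweight subject appears in both overweight
    groups.
    """
    primary = classify_group(bmi, wc_cm, sex, config).label
    if config.group_mode == "inclusive" and primary is Group.OW_BMI_WC:
        return (Group.OW_BMI, Group.OW_BMI_WC)
    return (primary,)
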