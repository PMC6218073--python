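"""Subject records and the CSV schema they travel in.

A :class:`SubjectRecord` holds one participant's anthropometrics and the
device measurements a four-compartment (4C) body-composition model needs:
body mass and waist circumference from the scale/tape, fat mass, lean mass
and bone mineral content (BMC) from DXA, body volume from air-displacement
plethysmography (ADP), and total body water (TBW) from multi-frequency
bioimpedance.

The on-disk format is a plain UTF-8 CSV with a '.' decimal separator and
one row per subject (see :data:`CSV_COLUMNS`).  Sex is coded ``M``/``F``,
case-insensitive.  An optional trailing ``exclusion`` column may carry a
free-text exclusion reason (pregnancy, missing limb, pacemaker, ...); a
non-empty value excludes the row before any analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields
from enum import Enum
from typing import Iterable

import pandas as pd


class Sex(str, Enum):
    MALE = "M"
    FEMALE = "F"

    @classmethod
    def parse(cls, value: str) -> "Sex":
        v = str(value).strip().upper()
        if v in ("M", "MALE"):
            return cls.MALE
        if v in ("F", "FEMALE"):
            return cls.FEMALE
        raise ValueError(f"unknown sex code {value!r}; expected 'M' or 'F'")


#: Required CSV columns, in canonical order.
CSV_COLUMNS = [
    "subject_id",
    "sex",
    "age",
    "height_cm",
    "body_mass_kg",
    "waist_circumference_cm",
    "dxa_fat_mass_kg",
    "dxa_lean_mass_kg",
    "dxa_bmc_kg",
    "adp_body_volume_l",
    "tbw_l",
]

#: Optional columns tolerated by the reader.
OPTIONAL_COLUMNS = ["exclusion"]

_NUMERIC_FIELDS = CSV_COLUMNS[2:]

#: Study eligibility window for age, years.
AGE_RANGE = (18.0, 65.0)

#: DXA compartments (FM + LM + BMC) are allowed to miss body mass by this
#: relative fraction before a plausibility warning is raised.
MASS_CLOSURE_TOLERANCE = 0.05


class SchemaError(ValueError):
    """Raised for malformed subject CSV input."""


@dataclass(frozen=True)
class SubjectRecord:
    """One participant's raw measurements.

    Units: height cm, masses kg, waist circumference cm, body volume and
    total body water litres, age years.
    """

    subject_id: str
    sex: Sex
    age: float
    height_cm: float
    body_mass_kg: float
    waist_circumference_cm: float
    dxa_fat_mass_kg: float
    dxa_lean_mass_kg: float
    dxa_bmc_kg: float
    adp_body_volume_l: float
    tbw_l: float
    exclusion: str = ""

    def __post_init__(self) -> None:
        for name in (
            "height_cm",
            "body_mass_kg",
            "waist_circumference_cm",
            "adp_body_volume_l",
            "tbw_l",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive, got {getattr(self, name)}")
        for name in ("dxa_fat_mass_kg", "dxa_lean_mass_kg", "dxa_bmc_kg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative, got {getattr(self, name)}")
        if self.age <= 0:
            raise ValueError(f"age must be strictly positive, got {self.age}")

    @property
    def age_eligible(self) -> bool:
        return AGE_RANGE[0] <= self.age <= AGE_RANGE[1]

    @property
    def excluded(self) -> bool:
        return bool(self.exclusion.strip())

    def check_mass_closure(self, tolerance: float = MASS_CLOSURE_TOLERANCE) -> bool:
        """Warn (not fail) if DXA compartments disagree with scale mass.

        Returns True when FM + LM + BMC is within ``tolerance`` (relative)
        of body mass.
        """
        dxa_total = self.dxa_fat_mass_kg + self.dxa_lean_mass_kg + self.dxa_bmc_kg
        ok = abs(dxa_total - self.body_mass_kg) <= tolerance * self.body_mass_kg
        if not ok:
            warnings.warn(
                f"subject {self.subject_id}: DXA compartment sum {dxa_total:.2f} kg "
                f"differs from body mass {self.body_mass_kg:.2f} kg by more than "
                f"{100 * tolerance:.0f}%",
                stacklevel=2,
            )
        return ok


def records_to_frame(records: Iterable[SubjectRecord]) -> pd.DataFrame:
    """Tabulate records in the canonical CSV column order."""
    rows = []
    for r in records:
        row = {f.name: getattr(r, f.name) for f in fields(r)}
        row["sex"] = r.sex.value
        rows.append(row)
    return pd.DataFrame(rows, columns=CSV_COLUMNS + OPTIONAL_COLUMNS)


def read_subjects_csv(path) -> list[SubjectRecord]:
    """Parse a subject CSV strictly, reporting offending line numbers.

    Rows that fail validation raise :class:`SchemaError` naming the CSV
    line (header = line 1).  Missing required columns raise immediately.
    """
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty file, expected header {CSV_COLUMNS}") from None
    missing = [c for c in CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")

    records: list[SubjectRecord] = []
    for idx, row in frame.iterrows():
        line = idx + 2  # header occupies line 1
        try:
            values = {}
            for name in _NUMERIC_FIELDS:
                raw = row[name].strip()
                if raw == "":
                    raise ValueError(f"missing value for {name}")
                values[name] = float(raw)
            record = SubjectRecord(
                subject_id=row["subject_id"].strip(),
                sex=Sex.parse(row["sex"]),
                exclusion=row.get("exclusion", "").strip(),
                **values,
            )
        except ValueError as exc:
            raise SchemaError(f"{path}, line {line}: {exc}") from exc
        records.append(record)
    return records


def write_subjects_csv(records: Iterable[SubjectRecord], path) -> None:
    """Write records in the canonical schema; round-trips losslessly."""
    frame = records_to_frame(records)
    frame.to_csv(path, index=False, lineterminator="\n")
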