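"""Synthetic anthropometric cohorts with known body-composition truth.

The reference study's subject data were never deposited, so this module
generates cohorts with the same group × sex summary structure (six cells:
normal weight, overweight-by-BMI, overweight-with-at-risk-waist, by sex)
and a physiologically coherent latent truth per subject:

    BM   = BMI · (height/100)²            (height, BMI ~ truncated normal)
    FM*  = true BF%/100 · BM,   FFM* = BM − FM*
    TBW  = hydration · FFM* + device noise      (hydration ≈ 0.732 L/kg FFM)
    BMC  = bone_fraction · FFM* + device noise  (bone mineral ≈ 5% of FFM)
    BV   = (FM* + 0.699·TBW − 1.129·Mo + 2.051·BM)/2.748 + device noise

The ADP body volume inverts the Wang fat-mass equation around the stored
(noisy) TBW and BMC, so with zero ADP noise the criterion 4C model recovers
the latent BF% exactly — the basis of the parameter-recovery tests.  DXA
fat and lean mass are the latent FM*/(FFM* − BMC) plus their own noise.
Waist circumference is drawn uniformly on a band anchored to the cell's
published mean ± 2 SD, intersected with the side of the sex-specific
threshold consistent with the cell's intended group, so classification
reproduces the intended label for every subject.

Each cell draws from its own deterministically derived random stream, so
changing one cell's n never perturbs another cell's subjects, and a given
seed always yields byte-identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .classify import ClassificationConfig, DEFAULT_CLASSIFICATION
from .equations import BMC_TO_MO, WANG_BM, WANG_BV, WANG_MO, WANG_TBW
from .records import Sex, SubjectRecord, write_subjects_csv

#: Canonical cell order; fixed so per-cell substreams are stable.
CELL_ORDER = [
    ("NW", "M"), ("NW", "F"),
    ("OW_BMI", "M"), ("OW_BMI", "F"),
    ("OW_BMI_WC", "M"), ("OW_BMI_WC", "F"),
]

#: Latent BF% truncation bounds, % (physiological support).
BF_BOUNDS = (2.0, 60.0)
AGE_BOUNDS = (18.0, 65.0)
HEIGHT_BOUNDS = (120.0, 220.0)
_MAX_REJECTION_ROUNDS = 1000


class ConfigError(ValueError):
    """Raised for infeasible generator configuration."""


@dataclass(frozen=True)
class CellConfig:
    """Distributional targets for one group × sex cell (means ± SDs)."""

    group: str
    sex: str
    n: int
    height_cm: tuple[float, float]
    bmi: tuple[float, float]
    age: tuple[float, float]
    wc_cm: tuple[float, float]
    true_bf: tuple[float, float]


@dataclass(frozen=True)
class SyntheticConfig:
    """Full generator configuration.

    ``hydration`` is the TBW/FFM ratio (litres per kg of fat-free mass)
    and ``bone_fraction`` the BMC/FFM ratio; both vary between subjects
    with the given SDs.  The ``*_sd`` device-noise terms are additive
    measurement errors in the instrument's native unit.
    """

    cells: tuple[CellConfig, ...]
    hydration: float = 0.732
    hydration_sd: float = 0.01
    bone_fraction: float = 0.05
    bone_fraction_sd: float = 0.004
    adp_bv_sd: float = 0.3      # L
    dxa_fm_sd: float = 0.5      # kg
    dxa_lm_sd: float = 0.5      # kg
    dxa_bmc_sd: float = 0.05    # kg
    tbw_sd: float = 0.8         # L
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "hydration_sd", "bone_fraction_sd", "adp_bv_sd",
            "dxa_fm_sd", "dxa_lm_sd", "dxa_bmc_sd", "tbw_sd",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")

    def with_noise(self, **overrides) -> "SyntheticConfig":
        """Copy with selected noise SDs replaced (e.g. all zero)."""
        return dataclasses.replace(self, **overrides)

    def zero_noise(self) -> "SyntheticConfig":
        """Copy with every noise source silenced (latent truth exactly
        recoverable from the criterion model)."""
        return self.with_noise(
            hydration_sd=0.0, bone_fraction_sd=0.0, adp_bv_sd=0.0,
            dxa_fm_sd=0.0, dxa_lm_sd=0.0, dxa_bmc_sd=0.0, tbw_sd=0.0,
        )


def _cell_from_mapping(group: str, sex: str, m: dict) -> CellConfig:
    def pair(key: str) -> tuple[float, float]:
        mean, sd = m[key]
        if sd < 0:
            raise ConfigError(f"{group}/{sex}: SD of {key} must be non-negative")
        return float(mean), float(sd)

    return CellConfig(
        group=group, sex=sex, n=int(m["n"]),
        height_cm=pair("height_cm"), bmi=pair("bmi"), age=pair("age"),
        wc_cm=pair("wc_cm"), true_bf=pair("true_bf"),
    )


def load_config(path=None, seed: int | None = None) -> SyntheticConfig:
    """Load a generator config from YAML; default to the packaged config
    reproducing the reference study's six cells (n = 20/20/20/20/14/21)."""
    if path is None:
        text = resources.files("fourc").joinpath("data/default_cohort.yaml").read_text()
        raw = yaml.safe_load(text)
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    cells = []
    for group, sex in CELL_ORDER:
        key = f"{group}/{sex}"
        if key in raw.get("cells", {}):
            cells.append(_cell_from_mapping(group, sex, raw["cells"][key]))
    if not cells:
        raise ConfigError("config defines no cells")
    kwargs = {k: raw[k] for k in (
        "hydration", "hydration_sd", "bone_fraction", "bone_fraction_sd",
        "adp_bv_sd", "dxa_fm_sd", "dxa_lm_sd", "dxa_bmc_sd", "tbw_sd", "seed",
    ) if k in raw}
    if seed is not None:
        kwargs["seed"] = int(seed)
    return SyntheticConfig(cells=tuple(cells), **kwargs)


def default_config(seed: int = 0) -> SyntheticConfig:
    """The packaged six-cell study configuration."""
    return load_config(None, seed=seed)


def _truncated_normal(rng, mean, sd, bounds, size):
    """Rejection-sampled truncated normal (bounds are loose by design)."""
    lo, hi = bounds
    if not lo < hi:
        raise ConfigError(f"infeasible truncation bounds ({lo}, {hi})")
    if sd == 0.0:
        if not lo <= mean <= hi:
            raise ConfigError(f"degenerate mean {mean} outside bounds ({lo}, {hi})")
        return np.full(size, float(mean))
    out = np.empty(size)
    filled = 0
    for _ in range(_MAX_REJECTION_ROUNDS):
        draw = rng.normal(mean, sd, size=2 * (size - filled) + 8)
        keep = draw[(draw >= lo) & (draw <= hi)][: size - filled]
        out[filled : filled + keep.size] = keep
        filled += keep.size
        if filled == size:
            return out
    raise ConfigError(
        f"truncated-normal rejection did not converge for mean={mean}, sd={sd}, "
        f"bounds=({lo}, {hi}); acceptance probability too low"
    )


def _wc_band(cell: CellConfig, cls: ClassificationConfig) -> tuple[float, float]:
    """Uniform waist band: published mean ± 2 SD clipped to the side of
    the threshold consistent with the cell's intended group."""
    mean, sd = cell.wc_cm
    lo, hi = mean - 2.0 * sd, mean + 2.0 * sd
    thr = cls.wc_threshold(Sex.parse(cell.sex))
    if cell.group == "OW_BMI_WC":
        lo = max(lo, thr)
    else:
        hi = min(hi, np.nextafter(thr, -np.inf))
    lo = max(lo, 40.0)
    if not lo < hi:
        raise ConfigError(
            f"{cell.group}/{cell.sex}: waist band ({lo:.1f}, {hi:.1f}) is empty "
            f"against threshold {thr}"
        )
    return lo, hi


def _bmi_bounds(cell: CellConfig, cls: ClassificationConfig) -> tuple[float, float]:
    if cell.group == "NW":
        return 14.0, np.nextafter(cls.bmi_cutoff, -np.inf)
    return cls.bmi_cutoff, 65.0


def generate_cohort(
    cfg: SyntheticConfig,
    classification: ClassificationConfig = DEFAULT_CLASSIFICATION,
) -> tuple[list[SubjectRecord], pd.DataFrame]:
    """Draw a cohort; return records plus the hidden truth table.

    The truth table has one row per subject: intended group, sex, and the
    latent true_bf / true_fm / true_ffm the noisy measurements were built
    around.
    """
    records: list[SubjectRecord] = []
    truth_rows = []
    streams = {
        cell_key: np.random.default_rng(np.random.SeedSequence(int(cfg.seed), spawn_key=(k,)))
        for k, cell_key in enumerate(CELL_ORDER)
    }
    counter = 0
    for cell in cfg.cells:
        rng = streams[(cell.group, cell.sex)]
        n = cell.n
        height = _truncated_normal(rng, *cell.height_cm, HEIGHT_BOUNDS, n)
        bmi = _truncated_normal(rng, *cell.bmi, _bmi_bounds(cell, classification), n)
        age = _truncated_normal(rng, *cell.age, AGE_BOUNDS, n)
        bf = _truncated_normal(rng, *cell.true_bf, BF_BOUNDS, n)
        wc = rng.uniform(*_wc_band(cell, classification), size=n)

        bm = bmi * (height / 100.0) ** 2
        fm_true = bf / 100.0 * bm
        ffm_true = bm - fm_true

        hydration = cfg.hydration + (
            rng.normal(0.0, cfg.hydration_sd, n) if cfg.hydration_sd else 0.0
        )
        bone_frac = cfg.bone_fraction + (
            rng.normal(0.0, cfg.bone_fraction_sd, n) if cfg.bone_fraction_sd else 0.0
        )
        tbw = hydration * ffm_true + (
            rng.normal(0.0, cfg.tbw_sd, n) if cfg.tbw_sd else 0.0
        )
        bmc = bone_frac * ffm_true + (
            rng.normal(0.0, cfg.dxa_bmc_sd, n) if cfg.dxa_bmc_sd else 0.0
        )
        bmc = np.maximum(bmc, 0.1)  # floor: bone mineral never vanishes
        mo = BMC_TO_MO * bmc
        # Invert the Wang fat-mass equation around the stored TBW/BMC so the
        # criterion model recovers fm_true exactly when ADP noise is zero.
        bv_adp = (fm_true + WANG_TBW * tbw - WANG_MO * mo + WANG_BM * bm) / WANG_BV
        bv_adp = bv_adp + (rng.normal(0.0, cfg.adp_bv_sd, n) if cfg.adp_bv_sd else 0.0)
        dxa_fm = fm_true + (rng.normal(0.0, cfg.dxa_fm_sd, n) if cfg.dxa_fm_sd else 0.0)
        dxa_lm = (ffm_true - bmc) + (
            rng.normal(0.0, cfg.dxa_lm_sd, n) if cfg.dxa_lm_sd else 0.0
        )
        dxa_fm = np.maximum(dxa_fm, 0.0)
        dxa_lm = np.maximum(dxa_lm, 0.0)

        for i in range(n):
            counter += 1
            sid = f"S{counter:04d}"
            records.append(
                SubjectRecord(
                    subject_id=sid,
                    sex=Sex.parse(cell.sex),
                    age=float(age[i]),
                    height_cm=float(height[i]),
                    body_mass_kg=float(bm[i]),
                    waist_circumference_cm=float(wc[i]),
                    dxa_fat_mass_kg=float(dxa_fm[i]),
                    dxa_lean_mass_kg=float(dxa_lm[i]),
                    dxa_bmc_kg=float(bmc[i]),
                    adp_body_volume_l=float(bv_adp[i]),
                    tbw_l=float(tbw[i]),
                )
            )
            truth_rows.append(
                {
                    "subject_id": sid,
                    "group": cell.group,
                    "sex": cell.sex,
                    "true_bf": float(bf[i]),
                    "true_fm": float(fm_true[i]),
                    "true_ffm": float(ffm_true[i]),
                }
            )
    truth = pd.DataFrame(
        truth_rows,
        columns=["subject_id", "group", "sex", "true_bf", "true_fm", "true_ffm"],
    )
    return records, truth


def write_cohort(records, path) -> None:
    """Write a cohort CSV in the canonical subject schema."""
    write_subjects_csv(records, path)
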