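"""Deterministic body-composition arithmetic.

The four-compartment (4C) model partitions body mass into fat, water, bone
mineral and residual.  Operationally it needs four measurements — body
volume BV (litres), total body water TBW (litres), total body bone mineral
Mo (kg) and body mass BM (kg) — and combines them linearly:

    FM = 2.748 BV − 0.699 TBW + 1.129 Mo − 2.051 BM
    BF% = 100 FM / BM,     FFM = BM − FM

Mo is derived from DXA bone mineral content as Mo = 1.0436 BMC.  TBW is
stored in litres and enters the fat-mass equation as a mass equivalent at
water density 1 (1 L = 1 kg).

Body volume can come from air-displacement plethysmography (the criterion)
or be predicted from DXA tissue masses by one of two published regression
equations:

    BV_SR = FM/0.84 + LM/1.03 + BMC/11.63 − 3.12          (Smith-Ryan)
    BV_W  = 0.95 LM + 1.14 FM + 0.21 BMC + 0.01           (Wilson)

yielding the three model variants 4C-ADP (criterion), 4C-DXA1 (Smith-Ryan
BV) and 4C-DXA2 (Wilson BV).  All coefficients are stored as the exact
decimal literals of their sources; nothing is re-fitted.  Physiologically
incoherent inputs may produce negative fat mass or BF% above 100 — such
estimates are returned as computed and flagged, never clamped, so the
arithmetic stays auditable.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .records import SubjectRecord

#: Mo (total body bone mineral) per kg of DXA bone mineral content.
BMC_TO_MO = 1.0436

#: Wang 4C fat-mass coefficients for (BV, TBW, Mo, BM).
WANG_BV, WANG_TBW, WANG_MO, WANG_BM = 2.748, 0.699, 1.129, 2.051


class Method(str, Enum):
    """The three 4C variants, named by their body-volume source."""

    ADP = "4C-ADP"
    DXA1 = "4C-DXA1"  # Smith-Ryan DXA body volume
    DXA2 = "4C-DXA2"  # Wilson DXA body volume


def compute_bmi(height_cm: float, body_mass_kg: float) -> float:
    """Body mass index, kg/m², from height in cm and mass in kg."""
    if height_cm <= 0 or body_mass_kg <= 0:
        raise ValueError("height and body mass must be strictly positive")
    h_m = height_cm / 100.0
    return body_mass_kg / (h_m * h_m)


def bone_mineral_from_bmc(bmc_kg: float) -> float:
    """Total body bone mineral Mo (kg) from DXA bone mineral content."""
    if bmc_kg < 0:
        raise ValueError("BMC must be non-negative")
    return bmc_kg * BMC_TO_MO


def dxa_bv_smith_ryan(fm_kg: float, lm_kg: float, bmc_kg: float) -> float:
    """Smith-Ryan DXA body-volume prediction, litres."""
    if fm_kg < 0 or lm_kg < 0 or bmc_kg < 0:
        raise ValueError("tissue masses must be non-negative")
    return fm_kg / 0.84 + lm_kg / 1.03 + bmc_kg / 11.63 - 3.12


def dxa_bv_wilson(fm_kg: float, lm_kg: float, bmc_kg: float) -> float:
    """Wilson DXA body-volume prediction, litres."""
    if fm_kg < 0 or lm_kg < 0 or bmc_kg < 0:
        raise ValueError("tissue masses must be non-negative")
    return 0.95 * lm_kg + 1.14 * fm_kg + 0.21 * bmc_kg + 0.01


def four_compartment_fm(bv_l: float, tbw_l: float, mo_kg: float, bm_kg: float) -> float:
    """Wang 4C fat mass, kg.

    May return a negative value on incoherent inputs; callers flag, not
    clamp.
    """
    if bm_kg <= 0:
        raise ValueError("body mass must be strictly positive")
    if bv_l < 0 or tbw_l < 0 or mo_kg < 0:
        raise ValueError("BV, TBW and Mo must be non-negative")
    return WANG_BV * bv_l - WANG_TBW * tbw_l + WANG_MO * mo_kg - WANG_BM * bm_kg


def bf_percent(fm_kg: float, bm_kg: float) -> float:
    """Body-fat percentage, 100·FM/BM."""
    if bm_kg <= 0:
        raise ValueError("body mass must be strictly positive")
    return 100.0 * fm_kg / bm_kg


@dataclass(frozen=True)
class CompositionEstimate:
    """FM/FFM/BF% for one subject under one 4C variant.

    ``fat_free_mass_kg`` is defined as BM − FM, so FM + FFM = BM exactly
    and ``bf_percent`` is the exact arithmetic ratio.  ``flags`` carries
    quality warnings (negative FM, BF% outside [0, 100]).
    """

    method: Method
    body_volume_used_l: float
    fat_mass_kg: float
    fat_free_mass_kg: float
    bf_percent: float
    flags: tuple[str, ...] = ()


def estimate_composition(subject: SubjectRecord, method: Method) -> CompositionEstimate:
    """Run one 4C variant for one subject.

    All three variants share the subject's TBW, Mo and body mass; they
    differ only in the body-volume source (measured ADP volume, or one of
    the two DXA predictions).
    """
    method = Method(method)
    if method is Method.ADP:
        bv = subject.adp_body_volume_l
    elif method is Method.DXA1:
        bv = dxa_bv_smith_ryan(
            subject.dxa_fat_mass_kg, subject.dxa_lean_mass_kg, subject.dxa_bmc_kg
        )
    else:
        bv = dxa_bv_wilson(
            subject.dxa_fat_mass_kg, subject.dxa_lean_mass_kg, subject.dxa_bmc_kg
        )
    mo = bone_mineral_from_bmc(subject.dxa_bmc_kg)
    fm = four_compartment_fm(bv, subject.tbw_l, mo, subject.body_mass_kg)
    bm = subject.body_mass_kg
    bf = bf_percent(fm, bm)
    flags = []
    if fm < 0:
        flags.append("negative_fat_mass")
    if not 0.0 <= bf <= 100.0:
        flags.append("bf_percent_out_of_range")
    return CompositionEstimate(
        method=method,
        body_volume_used_l=bv,
        fat_mass_kg=fm,
        fat_free_mass_kg=bm - fm,
        bf_percent=bf,
        flags=tuple(flags),
    )
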