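"""End-to-end study pipeline: subjects in, agreement tables out.

Reads a subject CSV (or takes generated records), applies eligibility
filters, classifies every subject into the BMI/waist groups, computes the
three 4C body-fat estimates per subject, and produces:

* a descriptive characteristics table per group × sex (the cohort table);
* an agreement table — one validity report per group for each DXA-volume
  model (4C-DXA1, 4C-DXA2) against the 4C-ADP criterion;
* per-subject Bland-Altman points for plotting;
* machine-readable run metadata (config echo, seed, stage counts).

Output files are plain CSV/TSV/JSON with deterministic ordering (group,
then method), so identical inputs, config and seed reproduce identical
bytes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import (
    ClassificationConfig,
    DEFAULT_CLASSIFICATION,
    Group,
    group_memberships,
)
from .equations import Method, compute_bmi, estimate_composition
from .records import SubjectRecord, read_subjects_csv
from .reference import GROUPS
from .validity import (
    AnalysisConfig,
    DEFAULT_ANALYSIS,
    PairedSeries,
    ValidityReport,
    build_validity_report,
    report_row,
)

log = logging.getLogger(__name__)

#: Prediction models compared against the 4C-ADP criterion.
PREDICTION_METHODS = (Method.DXA1, Method.DXA2)

#: Smallest group size for which regression-based statistics are reported.
MIN_GROUP_N = 3

TABLE1_VARIABLES = [
    "age", "height_cm", "body_mass_kg", "bmi", "wc_cm",
    "ffm_kg", "fm_kg", "bf_percent",
]


class EmptyInputError(ValueError):
    """No analysable subjects remain after filtering/classification."""


@dataclass
class StudyResult:
    """Everything one pipeline run produces."""

    table1: pd.DataFrame
    reports: list[ValidityReport]
    ba_points: pd.DataFrame
    run_metadata: dict
    counts: dict = field(default_factory=dict)


def read_subjects(path) -> list[SubjectRecord]:
    """Read and validate a subject CSV; raise on an empty cohort."""
    records = read_subjects_csv(path)
    if not records:
        raise EmptyInputError(f"{path}: no subject rows")
    log.info("parsed %d subject rows from %s", len(records), path)
    return records


def _apply_filters(records: list[SubjectRecord]) -> tuple[list[SubjectRecord], dict]:
    kept = []
    n_excluded = 0
    n_age = 0
    for r in records:
        if r.excluded:
            n_excluded += 1
            log.info("subject %s excluded: %s", r.subject_id, r.exclusion)
            continue
        if not r.age_eligible:
            n_age += 1
            log.info("subject %s outside age eligibility (%.0f y)", r.subject_id, r.age)
            continue
        r.check_mass_closure()
        kept.append(r)
    counts = {
        "parsed": len(records),
        "excluded_flagged": n_excluded,
        "excluded_age": n_age,
        "eligible": len(kept),
    }
    log.info(
        "eligibility: %d parsed, %d flag-excluded, %d age-excluded, %d eligible",
        *[counts[k] for k in ("parsed", "excluded_flagged", "excluded_age", "eligible")],
    )
    return kept, counts


def _descriptives(members: list[tuple[SubjectRecord, dict]]) -> dict:
    """Mean ± SD per characteristics-table variable for one cell."""
    data = {v: [] for v in TABLE1_VARIABLES}
    for record, est in members:
        adp = est[Method.ADP]
        data["age"].append(record.age)
        data["height_cm"].append(record.height_cm)
        data["body_mass_kg"].append(record.body_mass_kg)
        data["bmi"].append(compute_bmi(record.height_cm, record.body_mass_kg))
        data["wc_cm"].append(record.waist_circumference_cm)
        data["ffm_kg"].append(adp.fat_free_mass_kg)
        data["fm_kg"].append(adp.fat_mass_kg)
        data["bf_percent"].append(adp.bf_percent)
    out = {"n": len(members)}
    for var, values in data.items():
        arr = np.asarray(values)
        out[f"{var}_mean"] = float(arr.mean())
        out[f"{var}_sd"] = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return out


def run_study(
    records: list[SubjectRecord],
    analysis_cfg: AnalysisConfig = DEFAULT_ANALYSIS,
    classification: ClassificationConfig = DEFAULT_CLASSIFICATION,
    seed: int | None = None,
) -> StudyResult:
    """Classify, estimate, and compare — the full study in one call.

    Groups with fewer than three classified subjects are skipped with a
    warning (regression statistics need n ≥ 3).  Raises
    :class:`EmptyInputError` when no subject lands in any defined group.
    """
    eligible, counts = _apply_filters(records)
    if not eligible:
        raise EmptyInputError("no eligible subjects after exclusion filters")

    by_group: dict[str, list[tuple[SubjectRecord, dict]]] = {g: [] for g in GROUPS}
    n_unclassified = 0
    for record in eligible:
        bmi = compute_bmi(record.height_cm, record.body_mass_kg)
        labels = group_memberships(
            bmi, record.waist_circumference_cm, record.sex, classification
        )
        if labels == (Group.UNCLASSIFIED,):
            n_unclassified += 1
            log.info(
                "subject %s unclassified (BMI %.1f, WC %.1f)",
                record.subject_id, bmi, record.waist_circumference_cm,
            )
            continue
        estimates = {m: estimate_composition(record, m) for m in Method}
        for est in estimates.values():
            if est.flags:
                log.warning(
                    "subject %s, %s: quality flags %s",
                    record.subject_id, est.method.value, ",".join(est.flags),
                )
        for label in labels:
            by_group[label.value].append((record, estimates))
    counts["unclassified"] = n_unclassified
    counts["classified"] = len(eligible) - n_unclassified
    if all(not members for members in by_group.values()):
        raise EmptyInputError("all subjects unclassified; nothing to analyse")

    # Cohort characteristics per group x sex.
    table1_rows = []
    for group in GROUPS:
        for sex in ("M", "F"):
            members = [
                (r, e) for r, e in by_group[group] if r.sex.value == sex
            ]
            if not members:
                continue
            row = {"group": group, "sex": sex}
            row.update(_descriptives(members))
            table1_rows.append(row)
    table1 = pd.DataFrame(table1_rows)

    reports: list[ValidityReport] = []
    ba_rows = []
    for group in GROUPS:
        members = by_group[group]
        if 0 < len(members) < MIN_GROUP_N:
            log.warning(
                "group %s has only %d classified subject(s); skipping validity "
                "statistics (minimum %d)", group, len(members), MIN_GROUP_N,
            )
            continue
        if not members:
            continue
        criterion = np.array([e[Method.ADP].bf_percent for _, e in members])
        ids = [r.subject_id for r, _ in members]
        for method in PREDICTION_METHODS:
            predicted = np.array([e[method].bf_percent for _, e in members])
            series = PairedSeries(predicted=predicted, criterion=criterion)
            report = build_validity_report(group, method.value, series, analysis_cfg)
            reports.append(report)
            for sid, mean_bf, diff in zip(
                ids, report.ba_mean_of_methods, report.ba_differences
            ):
                ba_rows.append(
                    {
                        "subject_id": sid,
                        "group": group,
                        "method": method.value,
                        "mean_of_methods": round(float(mean_bf), 3),
                        "difference": round(float(diff), 3),
                    }
                )
        log.info("group %s: n = %d, 2 validity reports", group, len(members))

    ba_points = pd.DataFrame(
        ba_rows, columns=["subject_id", "group", "method", "mean_of_methods", "difference"]
    )
    run_metadata = {
        "software": {"name": "fourc", "version": __version__},
        "seed": seed,
        "analysis_config": {
            "alpha_base": analysis_cfg.alpha_base,
            "comparisons_per_group": analysis_cfg.comparisons_per_group,
            "adjusted_alpha": analysis_cfg.adjusted_alpha,
            "loa_z": analysis_cfg.loa_z,
            "bias_regressor_mode": analysis_cfg.bias_regressor_mode,
        },
        "classification_config": {
            "bmi_cutoff": classification.bmi_cutoff,
            "wc_threshold_female": classification.wc_threshold_female,
            "wc_threshold_male": classification.wc_threshold_male,
            "group_mode": classification.group_mode,
        },
        "counts": counts,
    }
    return StudyResult(
        table1=table1, reports=reports, ba_points=ba_points,
        run_metadata=run_metadata, counts=counts,
    )


def write_outputs(result: StudyResult, outdir) -> list[Path]:
    """Write table1.csv, table2.csv, table2.json, bland_altman_points.tsv
    and run_metadata.json into ``outdir``; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []

    table1 = result.table1.copy()
    for col in table1.columns:
        if col.endswith(("_mean", "_sd")):
            table1[col] = table1[col].round(1)
    p = outdir / "table1.csv"
    table1.to_csv(p, index=False, lineterminator="\n")
    paths.append(p)

    rows = [report_row(r) for r in result.reports]
    table2 = pd.DataFrame(rows)
    p = outdir / "table2.csv"
    table2.to_csv(p, index=False, lineterminator="\n")
    paths.append(p)

    p = outdir / "table2.json"
    p.write_text(json.dumps(rows, indent=2, sort_keys=True) + "\n")
    paths.append(p)

    p = outdir / "bland_altman_points.tsv"
    result.ba_points.to_csv(p, sep="\t", index=False, lineterminator="\n")
    paths.append(p)

    p = outdir / "run_metadata.json"
    p.write_text(json.dumps(result.run_metadata, indent=2, sort_keys=True) + "\n")
    paths.append(p)
    log.info("wrote %d output files to %s", len(paths), outdir)
    return paths
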