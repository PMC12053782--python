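"""Participant-level awakening records and per-participant recall rates.

Works on tables shaped like the freely available DREAM database export:
one row per awakening with a study ID, a subject ID (unique only within
its study), health status, the sleep stage the participant was woken
from, and the report category, plus subject age and sex.

The pipeline filters to healthy participants and known sleep stages,
builds a study-scoped unique participant identifier, and computes
participant-based percentages of each report type per stage group — kept
only when backed by at least ``min_n`` awakenings, so that a percentage
is never an artifact of one or two data points.
"""

from __future__ import annotations

import logging
from fractions import Fraction
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .study_corpus import MISSING, REPORT_TYPES, HarmonizationError, harmonize_levels

__all__ = [
    "UID_SEPARATOR",
    "STAGE_GROUPS",
    "load_awakenings",
    "participant_uid",
    "age_category",
    "participant_rates",
]

log = logging.getLogger(__name__)

UID_SEPARATOR = "::"

#: Stage groups accepted by :func:`participant_rates`; NREM pools N1-N3.
STAGE_GROUPS: dict[str, tuple[str, ...]] = {
    "NREM": ("NREM", "N1", "N2", "N3"),
    "REM": ("REM",),
    "N1": ("N1",),
    "N2": ("N2",),
    "N3": ("N3",),
    "W": ("W",),
}

_REQUIRED = ("study_id", "subject_id", "stage", "report")


def load_awakenings(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read awakening records, applying the health and stage filters.

    Non-healthy participants and rows whose stage is unknown/#N/A are
    excluded (counts logged).  Stage labels are harmonized to the
    N1/N2/N3/NREM/REM/W vocabulary (legacy S1→N1, S2→N2, S3/S4/SWS→N3);
    unmapped stage or report labels raise rather than guess.

    Returns a DataFrame with columns ``study_id, subject_id,
    participant_uid, stage, report, age, sex``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if schema:
        raw = raw.rename(columns=dict(schema))
    missing = [c for c in _REQUIRED if c not in raw.columns]
    if missing:
        raise ValueError(f"required columns missing: {missing}")

    n0 = len(raw)
    if "health" in raw.columns:
        healthy = raw["health"].str.strip().str.lower().isin(("healthy", "h"))
        raw = raw[healthy]
    n_health_excluded = n0 - len(raw)

    stages = raw["stage"].map(lambda s: harmonize_levels(s, "stage"))
    keep = (stages != "unknown") & (stages != MISSING)
    n_stage_excluded = int((~keep).sum())
    raw = raw[keep].copy()
    raw["stage"] = stages[keep]
    raw["report"] = raw["report"].map(lambda s: harmonize_levels(s, "report"))
    if (raw["report"] == MISSING).any():
        raise HarmonizationError("blank report label")

    raw["sex"] = raw["sex"].map(_sex) if "sex" in raw.columns else MISSING
    raw["age"] = (
        pd.to_numeric(raw["age"], errors="coerce") if "age" in raw.columns else np.nan
    )
    raw["participant_uid"] = [
        participant_uid(s, p) for s, p in zip(raw["study_id"], raw["subject_id"])
    ]
    log.info(
        "loaded %d awakenings from %s (excluded %d non-healthy, %d unknown-stage)",
        len(raw),
        path,
        n_health_excluded,
        n_stage_excluded,
    )
    out = raw[
        ["study_id", "subject_id", "participant_uid", "stage", "report", "age", "sex"]
    ].reset_index(drop=True)
    out.attrs["exclusions"] = {
        "non_healthy": n_health_excluded,
        "unknown_stage": n_stage_excluded,
    }
    return out


def _sex(label: str) -> str:
    text = str(label).strip().lower()
    if text in ("", "na", "n/a", "nan", "none", "missing"):
        return MISSING
    if text in ("f", "female", "w"):
        return "female"
    if text in ("m", "male"):
        return "male"
    raise HarmonizationError(f"unmapped sex label {label!r}")


def participant_uid(study_id: str, subject_id: str) -> str:
    """Injective study-scoped participant identifier.

    Subject IDs repeat across studies; joining with a separator that is
    forbidden inside either component keeps the combination injective.
    """
    for name, value in (("study_id", study_id), ("subject_id", subject_id)):
        if not str(value).strip():
            raise ValueError(f"{name} must be non-empty")
        if UID_SEPARATOR in str(value):
            raise ValueError(f"{name} may not contain {UID_SEPARATOR!r}")
    return f"{study_id}{UID_SEPARATOR}{subject_id}"


def age_category(age: float | None) -> str:
    """Dichotomize age at 30 years (the cohort's rounded mean age).

    Ages at or below 30 are ``le30``, strictly above are ``gt30``;
    missing ages stay missing.
    """
    if age is None or (isinstance(age, float) and np.isnan(age)):
        return MISSING
    if age < 0:
        raise ValueError(f"age must be nonnegative, got {age!r}")
    return "le30" if age <= 30 else "gt30"


def participant_rates(
    records: pd.DataFrame,
    stage_group: str,
    min_n: int = 3,
) -> pd.DataFrame:
    """Per-participant report-type percentages within one stage group.

    For each participant with at least ``min_n`` awakenings in the stage
    group, one row per report type with the exact count ratio.  The three
    rates of a participant sum to one exactly (they share a denominator).

    Returns columns ``participant_uid, study_id, stage_group, report,
    n_matching, n_awakenings, rate, sex, age_category``.
    """
    if len(records) == 0:
        raise ValueError("empty record set")
    if stage_group not in STAGE_GROUPS:
        raise ValueError(f"unknown stage group {stage_group!r}")
    if min_n < 1:
        raise ValueError("min_n must be >= 1")
    sub = records[records["stage"].isin(STAGE_GROUPS[stage_group])]
    rows = []
    for uid, grp in sorted(sub.groupby("participant_uid"), key=lambda kv: kv[0]):
        n = len(grp)
        if n < min_n:
            continue
        counts = grp["report"].value_counts()
        ages = grp["age"].dropna()
        age_cat = age_category(float(ages.iloc[0])) if len(ages) else MISSING
        sexes = grp["sex"][grp["sex"] != MISSING]
        sex = sexes.iloc[0] if len(sexes) else MISSING
        for report in REPORT_TYPES:
            k = int(counts.get(report, 0))
            rows.append(
                {
                    "participant_uid": uid,
                    "study_id": grp["study_id"].iloc[0],
                    "stage_group": stage_group,
                    "report": report,
                    "n_matching": k,
                    "n_awakenings": n,
                    "rate": k / n,
                    "rate_exact": Fraction(k, n),
                    "sex": sex,
                    "age_category": age_cat,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "participant_uid",
            "study_id",
            "stage_group",
            "report",
            "n_matching",
            "n_awakenings",
            "rate",
            "rate_exact",
            "sex",
            "age_category",
        ],
    )
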