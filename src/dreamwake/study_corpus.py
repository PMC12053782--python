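"""Harmonized study-level tables for dream-report awakening studies.

A *study table* holds one row per reviewed study (or study subset): six
categorical context factors describing how awakenings were provoked and
reports collected, participant covariates, and per-sleep-stage percentages
of the three report types ("experience with recall", "experience without
recall", "no report").  All downstream review analyses consume this table.

Proportions are stored internally on the unit scale [0, 1]; rendering
multiplies by 100.  Missing values are encoded as empty fields or "NA" in
files and as ``None``/``NaN`` in memory — never silently mapped to "other".
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

__all__ = [
    "CONTEXT_FACTORS",
    "STAGES",
    "REPORT_TYPES",
    "MISSING",
    "HarmonizationError",
    "ValidationError",
    "StudyRecord",
    "StudyTable",
    "harmonize_levels",
    "infer_no_report",
    "midpoint_age",
    "read_study_table",
    "write_study_table",
    "load_table1",
    "rate_column",
]

#: Context factors extracted from each study, with their canonical levels.
CONTEXT_FACTORS: dict[str, tuple[str, ...]] = {
    "method": ("alarm", "name", "other"),
    "question": ("mind", "dream", "other"),
    "repeated": ("repeated", "single", "both"),
    "setting": ("laboratory", "home", "both"),
    "sleep_type": ("night", "nap"),
    "days": ("multiple", "single"),
}

STAGES: tuple[str, ...] = ("N1", "N2", "N3", "NREM", "REM", "W")
REPORT_TYPES: tuple[str, ...] = ("with_recall", "without_recall", "no_report")

#: Sentinel level for missing categorical values.
MISSING = "missing"

_COVARIATE_COLUMNS = (
    "year",
    "mean_age",
    "percent_female",
    "n_participants",
    "n_awakenings",
    "gentle",
)

_IDENTITY_COLUMNS = ("study_id",)

_NA_STRINGS = frozenset({"", "na", "n/a", "nan", "none", "missing"})


class HarmonizationError(ValueError):
    """A free-text label could not be mapped to a canonical factor level."""


class ValidationError(ValueError):
    """A study table failed validation; message lists offending rows."""


def _load_vocab() -> dict[str, dict[str, str]]:
    ref = importlib.resources.files("dreamwake") / "data" / "harmonization.yaml"
    with ref.open("r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


_VOCAB = _load_vocab()


def harmonize_levels(
    raw_label: object,
    fld: str,
    extra: Mapping[str, str] | None = None,
) -> str:
    """Map a free-text label to a canonical level of factor ``fld``.

    Blank or NA-like inputs return :data:`MISSING`.  Unmapped non-blank
    labels raise :class:`HarmonizationError`; nothing is guessed.

    Parameters
    ----------
    raw_label : str or None
        The label as found in a source table (case-insensitive).
    fld : str
        One of the context factors, ``"gentle"``, ``"stage"`` or
        ``"report"``.
    extra : mapping, optional
        User-supplied additions to the packaged vocabulary
        (lower-cased label -> canonical level).
    """
    if fld not in _VOCAB:
        raise KeyError(f"unknown factor {fld!r}; expected one of {sorted(_VOCAB)}")
    if raw_label is None or (isinstance(raw_label, float) and math.isnan(raw_label)):
        return MISSING
    text = str(raw_label).strip()
    if text.lower() in _NA_STRINGS:
        return MISSING
    table = dict(_VOCAB[fld])
    if extra:
        table.update({k.lower(): v for k, v in extra.items()})
    # canonical levels map to themselves, making harmonization idempotent
    for level in set(table.values()):
        table.setdefault(level.lower(), level)
    key = text.lower()
    if key not in table:
        raise HarmonizationError(
            f"unmapped label {text!r} for factor {fld!r}; "
            "extend the harmonization vocabulary rather than guessing"
        )
    return table[key]


def infer_no_report(with_recall: float, without_recall: float) -> float:
    """Infer the no-report share as 1 − (with + without recall).

    Used when a study reports only the two experience categories; the
    remainder of the awakenings yielded no report at all.
    """
    for name, value in (("with_recall", with_recall), ("without_recall", without_recall)):
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {value!r}")
    total = with_recall + without_recall
    if total > 1.0 + 1e-9:
        raise ValueError(
            f"with_recall + without_recall = {total:.6g} exceeds 1; inconsistent source data"
        )
    return max(0.0, 1.0 - total)


def midpoint_age(min_age: float, max_age: float) -> float:
    """Approximate a study's mean age by the midpoint of its age range."""
    if min_age < 0:
        raise ValueError(f"min_age must be nonnegative, got {min_age!r}")
    if min_age > max_age:
        raise ValueError(f"min_age {min_age!r} exceeds max_age {max_age!r}")
    return (min_age + max_age) / 2.0


def rate_column(stage: str, report: str) -> str:
    """Canonical wide-table column name for a (stage, report type) rate."""
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}")
    if report not in REPORT_TYPES:
        raise ValueError(f"unknown report type {report!r}")
    return f"rate_{stage}_{report}"


_RATE_COLUMNS = tuple(rate_column(s, r) for s in STAGES for r in REPORT_TYPES)


@dataclass
class StudyRecord:
    """One reviewed study (or study subset) in canonical form."""

    study_id: str
    year: int | None = None
    method: str = MISSING
    question: str = MISSING
    repeated: str = MISSING
    setting: str = MISSING
    sleep_type: str = MISSING
    days: str = MISSING
    mean_age: float | None = None
    percent_female: float | None = None
    n_participants: int | None = None
    n_awakenings: int | None = None
    gentle: str = MISSING
    #: sparse mapping (stage, report type) -> proportion in [0, 1]
    rates: dict[tuple[str, str], float] = field(default_factory=dict)


@dataclass
class StudyTable:
    """An ordered collection of :class:`StudyRecord` with provenance."""

    frame: pd.DataFrame
    source: str = "<memory>"

    def __post_init__(self) -> None:
        if len(self.frame) == 0:
            raise ValidationError("no records")
        dup = self.frame["study_id"][self.frame["study_id"].duplicated()]
        if len(dup):
            raise ValidationError(f"duplicate study_id: {sorted(set(dup))}")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def provenance(self) -> dict[str, object]:
        return {"source": self.source, "n_rows": len(self.frame)}

    @property
    def records(self) -> list[StudyRecord]:
        out = []
        for _, row in self.frame.iterrows():
            rates = {}
            for stage in STAGES:
                for report in REPORT_TYPES:
                    col = rate_column(stage, report)
                    if col in row.index and pd.notna(row[col]):
                        rates[(stage, report)] = float(row[col])
            out.append(
                StudyRecord(
                    study_id=row["study_id"],
                    year=None if pd.isna(row.get("year")) else int(row["year"]),
                    method=row.get("method", MISSING),
                    question=row.get("question", MISSING),
                    repeated=row.get("repeated", MISSING),
                    setting=row.get("setting", MISSING),
                    sleep_type=row.get("sleep_type", MISSING),
                    days=row.get("days", MISSING),
                    mean_age=None if pd.isna(row.get("mean_age")) else float(row["mean_age"]),
                    percent_female=None
                    if pd.isna(row.get("percent_female"))
                    else float(row["percent_female"]),
                    n_participants=None
                    if pd.isna(row.get("n_participants"))
                    else int(row["n_participants"]),
                    n_awakenings=None
                    if pd.isna(row.get("n_awakenings"))
                    else int(row["n_awakenings"]),
                    gentle=row.get("gentle", MISSING),
                    rates=rates,
                )
            )
        return out


def _validate_rates(frame: pd.DataFrame, errors: list[str]) -> None:
    for col in frame.columns:
        if not col.startswith("rate_"):
            continue
        vals = frame[col].dropna()
        bad = vals[(vals < 0) | (vals > 1)]
        for idx, v in bad.items():
            errors.append(f"row {idx + 1}: {col} = {v:.4g} outside [0, 1]")
    # where all three report types are present for a stage they must sum to 1
    for stage in STAGES:
        cols = [rate_column(stage, r) for r in REPORT_TYPES]
        if not all(c in frame.columns for c in cols):
            continue
        sub = frame[cols].dropna()
        bad = sub[(sub.sum(axis=1) - 1.0).abs() > 1e-9]
        for idx in bad.index:
            errors.append(
                f"row {idx + 1}: {stage} report-type proportions sum to "
                f"{sub.loc[idx].sum():.6g}, expected 1"
            )


def read_study_table(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    *,
    percent_scale: str = "unit",
    ignore: Iterable[str] = (),
) -> StudyTable:
    """Read and validate a delimited study table.

    Parameters
    ----------
    path : path
        UTF-8 CSV with a header row.
    schema : mapping, optional
        File column name -> canonical column name.  Columns absent from
        the schema (and from ``ignore``) are an error so silent typos in
        headers cannot pass.  With ``schema=None`` the file must already
        use canonical column names.
    percent_scale : {"unit", "percent"}
        Scale of the rate columns in the file; internally everything is
        normalized to the unit scale [0, 1].
    ignore : iterable of str
        File columns to drop without complaint.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if percent_scale not in ("unit", "percent"):
        raise ValueError(f"percent_scale must be 'unit' or 'percent', got {percent_scale!r}")
    raw = pd.read_csv(path, dtype={"study_id": str}, keep_default_na=True)
    ignore = set(ignore)
    if schema is not None:
        unknown = [c for c in raw.columns if c not in schema and c not in ignore]
        if unknown:
            raise ValidationError(f"unknown columns: {unknown}")
        raw = raw.drop(columns=[c for c in ignore if c in raw.columns])
        raw = raw.rename(columns=dict(schema))
    else:
        known = set(_IDENTITY_COLUMNS) | set(CONTEXT_FACTORS) | set(_COVARIATE_COLUMNS)
        known |= set(_RATE_COLUMNS)
        unknown = [c for c in raw.columns if c not in known and c not in ignore]
        if unknown:
            raise ValidationError(f"unknown columns: {unknown}")
        raw = raw.drop(columns=[c for c in ignore if c in raw.columns])
    for col in _IDENTITY_COLUMNS:
        if col not in raw.columns:
            raise ValidationError(f"required column {col!r} missing")
    if len(raw) == 0:
        raise ValidationError("no records")

    errors: list[str] = []
    for fld in CONTEXT_FACTORS:
        if fld not in raw.columns:
            raw[fld] = MISSING
            continue
        harmonized = []
        for idx, val in raw[fld].items():
            try:
                harmonized.append(harmonize_levels(val, fld))
            except HarmonizationError as exc:
                errors.append(f"row {idx + 1}: {exc}")
                harmonized.append(MISSING)
        raw[fld] = harmonized
    if "gentle" in raw.columns:
        raw["gentle"] = [harmonize_levels(v, "gentle") for v in raw["gentle"]]
    else:
        raw["gentle"] = MISSING

    for col in raw.columns:
        if col.startswith("rate_"):
            if col not in _RATE_COLUMNS:
                raise ValidationError(f"unknown rate column {col!r}")
            vals = pd.to_numeric(raw[col], errors="coerce")
            if percent_scale == "percent":
                vals = vals / 100.0
            raw[col] = vals
    _validate_rates(raw, errors)

    if raw["study_id"].isna().any() or (raw["study_id"].str.strip() == "").any():
        errors.append("blank study_id")
    if errors:
        raise ValidationError("; ".join(errors))
    return StudyTable(frame=raw.reset_index(drop=True), source=str(path))


def write_study_table(table: StudyTable, path: str | Path) -> None:
    """Write a study table as canonical UTF-8 CSV (unit-scale rates)."""
    table.frame.to_csv(path, index=False)


def load_table1(*, keep_availability: bool = False) -> StudyTable:
    """Load the packaged transcription of the 69-study review table.

    Context factors and report-type availability flags only; per-stage
    percentages are not part of the printed table and may be supplied by
    the user in the same schema.  With ``keep_availability=True`` the
    yes/no columns recording which report types each study published are
    retained as ``has_*`` columns.
    """
    avail = ("has_with_recall", "has_without_recall", "has_no_report")
    ref = importlib.resources.files("dreamwake") / "data" / "table1_fixture.csv"
    with importlib.resources.as_file(ref) as p:
        if keep_availability:
            cols = pd.read_csv(p, nrows=0).columns
            schema = {c: c for c in cols}
            table = read_study_table(p, schema=schema)
            for c in avail:
                table.frame[c] = table.frame[c] == "yes"
            return table
        return read_study_table(p, ignore=avail)
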