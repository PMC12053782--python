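"""Synthetic awakening records and study tables with known ground truth.

Every analysis stage in this package can be exercised without any
external download: :func:`generate_awakenings` emits participant-level
records in the same shape as the DREAM-database export (studies
containing participants, each contributing per-stage awakenings whose
report categories follow stage-specific probabilities), and
:func:`generate_study_table` emits a review-style study table whose
context-factor effects are known exactly.

The inter-individual mechanism is deliberately minimal: a participant
random effect with SD ``tau`` is added on the logit of the with-recall
probability, and the without-recall/no-report mass is rescaled
proportionally so the three probabilities stay on the simplex.  ``tau=0``
is exactly the null hypothesis of the stratified permutation test; the
same mechanism at the study level (``study_effect_sd``) creates the
between-study differences the test's strata are meant to absorb.

Defaults mirror the scale of the participant-level cohort analyzed in
the review: 18 studies, ~27 participants per study, a handful of
awakenings per participant, and stage-specific report probabilities near
the review's average recall rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .participant_metrics import participant_uid
from .study_corpus import CONTEXT_FACTORS, REPORT_TYPES, StudyTable

__all__ = ["SyntheticConfig", "generate_awakenings", "generate_study_table"]


def _default_stage_mix() -> dict[str, float]:
    return {"N1": 0.10, "N2": 0.35, "N3": 0.20, "REM": 0.27, "W": 0.08}


def _default_base_probs() -> dict[str, tuple[float, float, float]]:
    # (with_recall, without_recall, no_report) per stage, near the
    # review's average per-stage recall rates
    return {
        "N1": (0.85, 0.10, 0.05),
        "N2": (0.53, 0.22, 0.25),
        "N3": (0.51, 0.29, 0.20),
        "REM": (0.83, 0.07, 0.10),
        "W": (0.94, 0.04, 0.02),
    }


@dataclass
class SyntheticConfig:
    """Ground-truth parameters of the awakening-record generator."""

    n_studies: int = 18
    participants_per_study: int | tuple[int, int] = 27
    awakenings_per_participant: int | tuple[int, int] = (3, 12)
    stage_mix: dict[str, float] = field(default_factory=_default_stage_mix)
    base_probs: dict[str, tuple[float, float, float]] = field(
        default_factory=_default_base_probs
    )
    #: SD of the participant random effect on the with-recall logit
    tau: float = 1.0
    #: SD of the study random effect on the same logit
    study_effect_sd: float = 0.5
    sex_ratio: float = 0.57
    #: (mean_young, mean_old, sd, weight_young) normal mixture for ages
    age_distribution: tuple[float, float, float, float] = (24.0, 38.0, 4.0, 0.6)
    seed: int = 0

    def validate(self) -> None:
        if self.n_studies < 1:
            raise ValueError("n_studies must be >= 1")
        lo, _ = _as_range(self.participants_per_study)
        if lo < 1:
            raise ValueError("zero participants")
        if self.tau < 0 or self.study_effect_sd < 0:
            raise ValueError("random-effect SDs must be nonnegative")
        if abs(sum(self.stage_mix.values()) - 1.0) > 1e-9:
            raise ValueError("stage_mix must sum to 1")
        for stage, probs in self.base_probs.items():
            p = np.asarray(probs, dtype=float)
            if p.shape != (3,) or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
                raise ValueError(f"base_probs[{stage!r}] is not a 3-point simplex")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ValueError("sex_ratio must lie in [0, 1]")


def _as_range(value: int | tuple[int, int]) -> tuple[int, int]:
    if isinstance(value, (tuple, list)):
        lo, hi = value
        return int(lo), int(hi)
    return int(value), int(value)


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


def _shift_simplex(probs: np.ndarray, delta: float) -> np.ndarray:
    """Shift the with-recall logit by delta; rescale the rest of the mass."""
    p_with = 1.0 / (1.0 + np.exp(-(_logit(probs[0]) + delta)))
    rest = probs[1:] / probs[1:].sum() if probs[1:].sum() > 0 else np.array([0.5, 0.5])
    out = np.array([p_with, *((1.0 - p_with) * rest)])
    return out


def generate_awakenings(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample a hierarchical awakening-record dataset.

    Sampling order: study effect → participant effect → per-awakening
    stage and categorical report draw.  Returns ``(records, truth)``:
    records in the same columns :func:`~dreamwake.participant_metrics.
    load_awakenings` produces, and a truth table with every participant's
    realized category probabilities per stage.  Byte-identical output for
    a fixed seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    stages = sorted(config.stage_mix)
    mix = np.array([config.stage_mix[s] for s in stages])
    rec_rows = []
    truth_rows = []
    mean_young, mean_old, age_sd, w_young = config.age_distribution
    p_lo, p_hi = _as_range(config.participants_per_study)
    a_lo, a_hi = _as_range(config.awakenings_per_participant)
    for si in range(config.n_studies):
        study_id = f"SYN{si + 1:02d}"
        study_effect = rng.normal(0.0, config.study_effect_sd)
        n_participants = int(rng.integers(p_lo, p_hi + 1))
        for pi in range(n_participants):
            subject_id = f"p{pi + 1:03d}"
            uid = participant_uid(study_id, subject_id)
            part_effect = rng.normal(0.0, config.tau)
            sex = "female" if rng.random() < config.sex_ratio else "male"
            mu = mean_young if rng.random() < w_young else mean_old
            age = float(np.clip(rng.normal(mu, age_sd), 18.0, 80.0))
            probs = {
                s: _shift_simplex(
                    np.asarray(config.base_probs[s], dtype=float),
                    study_effect + part_effect,
                )
                for s in stages
            }
            for s in stages:
                truth_rows.append(
                    {
                        "participant_uid": uid,
                        "study_id": study_id,
                        "stage": s,
                        **{
                            f"p_{rt}": probs[s][j]
                            for j, rt in enumerate(REPORT_TYPES)
                        },
                    }
                )
            n_awk = int(rng.integers(a_lo, a_hi + 1))
            drawn_stages = rng.choice(len(stages), size=n_awk, p=mix)
            for k in drawn_stages:
                stage = stages[k]
                report = REPORT_TYPES[
                    int(rng.choice(3, p=probs[stage]))
                ]
                rec_rows.append(
                    {
                        "study_id": study_id,
                        "subject_id": subject_id,
                        "participant_uid": uid,
                        "stage": stage,
                        "report": report,
                        "age": age,
                        "sex": sex,
                    }
                )
    records = pd.DataFrame(rec_rows)
    truth = pd.DataFrame(truth_rows)
    return records, truth


# empirical context-factor composition of the 69 reviewed studies,
# used to draw realistic study tables
_FACTOR_COMPOSITION: dict[str, dict[str, float]] = {
    "method": {"alarm": 28 / 63, "name": 18 / 63, "other": 17 / 63},
    "question": {"mind": 51 / 68, "dream": 13 / 68, "other": 4 / 68},
    "repeated": {"repeated": 55 / 68, "single": 12 / 68, "both": 1 / 68},
    "setting": {"laboratory": 62 / 68, "home": 5 / 68, "both": 1 / 68},
    "sleep_type": {"night": 53 / 67, "nap": 14 / 67},
    "days": {"multiple": 30 / 67, "single": 37 / 67},
}

_DEFAULT_STAGE_EFFECTS = {("stage", "REM"): 0.25, ("stage", "W"): 0.35}


def generate_study_table(
    coefficients: Mapping[tuple[str, str], float],
    noise_sd: float,
    n_studies: int,
    seed: int = 0,
    *,
    intercept: float = 0.5,
    stages: Sequence[str] = ("NREM", "REM", "W"),
    report_type: str = "with_recall",
) -> tuple[StudyTable, dict[tuple[str, str], float]]:
    """Draw a study table whose context-factor effects are known.

    ``coefficients`` maps ``(factor, level)`` (or ``("stage", level)``)
    to an additive effect on the unit-scale outcome relative to the
    baseline level; the intercept is the baseline NREM outcome.  Stage
    effects default to REM +0.25 and W +0.35 when not given.  Outcomes
    are the linear predictor plus Gaussian noise, clipped to [0, 1]
    (clip count recorded in ``frame.attrs['n_clipped']``).
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be > 0")
    if n_studies < 1:
        raise ValueError("n_studies must be >= 1")
    effects = dict(_DEFAULT_STAGE_EFFECTS)
    effects.update(coefficients)
    for (factor, level), _ in effects.items():
        if factor == "stage":
            continue
        if factor not in CONTEXT_FACTORS or level not in CONTEXT_FACTORS[factor]:
            raise ValueError(f"unknown coefficient target ({factor!r}, {level!r})")
    rng = np.random.default_rng(seed)
    rows = []
    n_clipped = 0
    for i in range(n_studies):
        row: dict[str, object] = {"study_id": f"SIM{i + 1:03d}", "year": 2000 + i % 25}
        for factor, comp in _FACTOR_COMPOSITION.items():
            lvls = sorted(comp)
            row[factor] = rng.choice(lvls, p=[comp[l] for l in lvls])
        row["mean_age"] = float(np.clip(rng.normal(26.9, 11.5), 18.0, 70.0))
        row["percent_female"] = float(np.clip(rng.normal(0.57, 0.21), 0.0, 1.0))
        row["n_participants"] = int(rng.integers(8, 60))
        row["n_awakenings"] = int(row["n_participants"] * rng.integers(2, 7))
        row["gentle"] = "missing"
        base = intercept + sum(
            eff
            for (factor, level), eff in effects.items()
            if factor != "stage" and row.get(factor) == level
        )
        if not -0.5 <= base <= 1.5:
            raise ValueError(
                f"predictor combination yields mean {base:.3g} outside [-0.5, 1.5]"
            )
        for stage in stages:
            mean = base + effects.get(("stage", stage), 0.0)
            value = mean + rng.normal(0.0, noise_sd)
            clipped = float(np.clip(value, 0.0, 1.0))
            if clipped != value:
                n_clipped += 1
            row[f"rate_{stage}_{report_type}"] = clipped
        rows.append(row)
    frame = pd.DataFrame(rows)
    frame.attrs["n_clipped"] = n_clipped
    table = StudyTable(frame=frame, source=f"<synthetic seed={seed}>")
    return table, effects
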