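"""Stratified permutation test for inter-individual differences in recall.

The question: do participants differ in their dream-recall percentages by
more than chance, after controlling for the study they took part in,
their sex, and their age group?  The test statistic is the sample
standard deviation (n−1 denominator) of participant-based percentages —
a direct measure of between-participant variability.  Under the null of
exchangeable report labels, labels are reshuffled *within* strata defined
by study × sex × age category (and, for NREM runs, within each NREM
substage), so the resampled datasets preserve every stratum's label
composition and each participant's awakening count.  The upper tail of
the resampled statistic gives the p-value: significantly large observed
values indicate participant characteristics beyond age, sex and study.

Because shuffling never changes how many awakenings a participant has,
the set of participants passing the ``min_n`` rule is identical in every
resample; percentages are simply recomputed from the permuted labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .participant_metrics import STAGE_GROUPS, age_category
from .review_stats import bh_adjust
from .study_corpus import MISSING, REPORT_TYPES

__all__ = [
    "PermutationConfig",
    "PermutationResult",
    "sd_statistic",
    "permute_labels",
    "run_permutation_test",
    "permutation_family",
]

DEFAULT_STRATA = ("study_id", "sex", "age_category")


@dataclass(frozen=True)
class PermutationConfig:
    """Settings of one stratified permutation test."""

    stage_group: str = "NREM"
    report: str = "with_recall"
    n_resamples: int = 10_000
    strata: tuple[str, ...] = DEFAULT_STRATA
    min_n: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_resamples < 1:
            raise ValueError("n_resamples must be >= 1")
        if not self.strata:
            raise ValueError("strata must be non-empty")
        if self.stage_group not in STAGE_GROUPS:
            raise ValueError(f"unknown stage group {self.stage_group!r}")
        if self.report not in REPORT_TYPES:
            raise ValueError(f"unknown report type {self.report!r}")


@dataclass
class PermutationResult:
    """Observed statistic, null-distribution summary, and p-values."""

    observed_sd: float
    p_raw: float
    n_participants: int
    n_studies: int
    n_resamples: int
    seed: int
    null_mean: float
    null_sd: float
    permuted_sds: np.ndarray | None = field(default=None, repr=False)
    p_cor: float = float("nan")


def sd_statistic(percentages: Sequence[float]) -> float:
    """Sample SD (ddof=1) of per-participant percentages, 0–100 scale."""
    x = np.asarray(list(percentages), dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 participants")
    return float(np.std(x, ddof=1))


def permute_labels(
    records: pd.DataFrame,
    strata: Sequence[str],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Shuffle report labels within strata; everything else stays put.

    Within each stratum the multiset of labels is exactly preserved
    (permutation without replacement); no label ever crosses a stratum
    boundary, so study, sex, age-group and substage compositions are
    conserved.
    """
    for col in strata:
        if col not in records.columns:
            raise ValueError(f"stratum column {col!r} absent from records")
        if (records[col] == MISSING).any() or records[col].isna().any():
            raise ValueError(f"record with undefined stratum (missing {col!r})")
    out = records.copy()
    labels = out["report"].to_numpy().copy()
    for _, idx in records.groupby(list(strata)).indices.items():
        labels[idx] = labels[idx][rng.permutation(len(idx))]
    out["report"] = labels
    return out


def _prepare(records: pd.DataFrame, config: PermutationConfig):
    """Filter, stratify and index records for fast resampling."""
    sub = records[records["stage"].isin(STAGE_GROUPS[config.stage_group])].copy()
    if "age_category" in config.strata and "age_category" not in sub.columns:
        sub["age_category"] = sub["age"].map(age_category)
    # participants with undefined strata cannot be placed in any group
    for col in config.strata:
        if col not in sub.columns:
            raise ValueError(f"stratum column {col!r} absent from records")
        sub = sub[(sub[col] != MISSING) & sub[col].notna()]
    strata_cols = list(config.strata)
    if config.stage_group == "NREM" and "stage" not in strata_cols:
        # keep the N1/N2/N3 grouping intact inside each shuffle
        strata_cols.append("stage")
    sub = sub.reset_index(drop=True)
    return sub, strata_cols


def run_permutation_test(
    records: pd.DataFrame,
    config: PermutationConfig,
    *,
    keep_null: bool = False,
) -> PermutationResult:
    """Run the stratified permutation test on filtered awakening records.

    ``records`` is the output of :func:`~dreamwake.participant_metrics.
    load_awakenings` (or the synthetic generator).  The observed SD of
    participant percentages is compared with ``n_resamples`` stratified
    reshuffles; ``p_raw = (1 + #{permuted ≥ observed}) / (B + 1)``
    (one-sided upper tail with add-one smoothing).  Deterministic given
    ``config.seed``.
    """
    sub, strata_cols = _prepare(records, config)
    if len(sub) == 0:
        raise ValueError("no records remain after stage and stratum filtering")

    uid_codes, uids = pd.factorize(sub["participant_uid"], sort=True)
    totals = np.bincount(uid_codes, minlength=len(uids))
    eligible = totals >= config.min_n
    if eligible.sum() < 2:
        raise ValueError("fewer than 2 participants meet the min_n rule")
    labels = (sub["report"] == config.report).to_numpy(dtype=float)

    def statistic(target: np.ndarray) -> float:
        counts = np.bincount(uid_codes, weights=target, minlength=len(uids))
        pct = 100.0 * counts[eligible] / totals[eligible]
        return float(np.std(pct, ddof=1))

    observed = statistic(labels)
    rng = np.random.default_rng(config.seed)
    stratum_idx = [np.asarray(ix) for ix in sub.groupby(strata_cols).indices.values()]
    work = labels.copy()
    null = np.empty(config.n_resamples)
    for b in range(config.n_resamples):
        for idx in stratum_idx:
            work[idx] = work[idx][rng.permutation(len(idx))]
        null[b] = statistic(work)
    p_raw = (1.0 + float(np.sum(null >= observed - 1e-12))) / (config.n_resamples + 1.0)

    n_studies = sub.loc[
        sub["participant_uid"].isin(uids[eligible]), "study_id"
    ].nunique()
    return PermutationResult(
        observed_sd=observed,
        p_raw=p_raw,
        n_participants=int(eligible.sum()),
        n_studies=int(n_studies),
        n_resamples=config.n_resamples,
        seed=config.seed,
        null_mean=float(null.mean()),
        null_sd=float(null.std(ddof=1)),
        permuted_sds=null if keep_null else None,
    )


def permutation_family(
    records: pd.DataFrame,
    *,
    stage_groups: Sequence[str] = ("NREM", "REM"),
    reports: Sequence[str] = REPORT_TYPES,
    n_resamples: int = 10_000,
    min_n: int = 3,
    seed: int = 0,
) -> dict[tuple[str, str], PermutationResult]:
    """Run a family of tests (report types × stage groups) with BH.

    The corrected p-values treat the whole invocation as one BH family —
    by default the six tests of three report types in NREM and REM.
    Each test gets an independent child seed spawned from ``seed``.
    """
    seeds = np.random.SeedSequence(seed).generate_state(
        len(stage_groups) * len(reports)
    )
    results: dict[tuple[str, str], PermutationResult] = {}
    i = 0
    for group in stage_groups:
        for report in reports:
            cfg = PermutationConfig(
                stage_group=group,
                report=report,
                n_resamples=n_resamples,
                min_n=min_n,
                seed=int(seeds[i] % (2**31)),
            )
            results[(group, report)] = run_permutation_test(records, cfg)
            i += 1
    adjusted = bh_adjust([r.p_raw for r in results.values()])
    for r, a in zip(results.values(), adjusted):
        r.p_cor = float(a)
    return results
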