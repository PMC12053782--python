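"""Study-level analyses of awakening-study recall rates.

Implements the review side of the pipeline: composition statistics over
context factors, condensation of NREM substages into a single NREM level,
ordinary least squares models of report-type proportions on sleep stage
and study context, estimated-marginal-mean (EMM) pairwise contrasts with
Cohen's d and effect-size categories, Welch t-tests comparing N2 with N3,
Benjamini–Hochberg false-discovery-rate correction, and a stepwise-AIC
screen over stage-by-factor interaction terms.

Proportions are modelled on the unit scale [0, 1].  Cohen's d for a factor
contrast is the contrast estimate divided by the model's residual standard
deviation; for covariate slopes and the intercept it is converted from the
t statistic (2t/√df), matching how mixed contrast/slope tables are
conventionally standardized.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import patsy
import scipy.stats
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

from .study_corpus import (
    CONTEXT_FACTORS,
    MISSING,
    REPORT_TYPES,
    STAGES,
    StudyTable,
    rate_column,
)

__all__ = [
    "CompositionResult",
    "ModelFit",
    "ContrastResult",
    "composition_stats",
    "condense_nrem",
    "stack_observations",
    "fit_linear_model",
    "emm_contrasts",
    "covariate_tests",
    "bh_adjust",
    "effect_size_category",
    "n2_n3_test",
    "stepwise_aic_interactions",
    "auxiliary_covariate_model",
    "review_model",
    "contrasts_to_frame",
]

#: NREM substages condensed into the single NREM level for stage models.
NREM_FAMILY = ("NREM", "N1", "N2", "N3")

#: Full term list of the extensive experience-with-recall model.
FULL_TERMS = (
    "stage",
    "method",
    "question",
    "repeated",
    "setting",
    "days",
    "sleep_type",
    "mean_age",
    "percent_female",
)

_COVARIATES = ("mean_age", "percent_female", "year", "awakenings_per_participant")


@dataclass
class CompositionResult:
    """Level proportions (over non-missing records) and raw counts."""

    factor: str
    proportions: dict[str, float]
    counts: dict[str, int]
    n_missing: int


@dataclass
class ModelFit:
    """An OLS fit of a report-type proportion on stage and context terms."""

    outcome: str
    terms: tuple[str, ...]
    coefficients: pd.Series
    residual_sd: float
    residual_df: int
    n_rows_used: int
    aic: float
    result: object = field(repr=False)  # statsmodels RegressionResults
    data: pd.DataFrame = field(repr=False)  # rows actually used in the fit

    @property
    def factors(self) -> tuple[str, ...]:
        return tuple(t for t in self.terms if ":" not in t and self.data[t].dtype == object)

    @property
    def covariates(self) -> tuple[str, ...]:
        return tuple(t for t in self.terms if ":" not in t and self.data[t].dtype != object)


@dataclass
class ContrastResult:
    """One estimated difference (or slope) with its test and effect size."""

    outcome: str
    label: str
    estimate: float
    se: float
    statistic: float
    df: float
    p_raw: float
    d: float
    category: str
    p_cor: float = float("nan")


def composition_stats(table: StudyTable, factor: str) -> CompositionResult:
    """Share of studies at each level of a context factor.

    Proportions are taken over records with a non-missing level, so they
    sum to one; counts and the number of missing records are also
    returned.
    """
    if factor not in CONTEXT_FACTORS:
        raise ValueError(f"unknown factor {factor!r}; expected one of {sorted(CONTEXT_FACTORS)}")
    values = table.frame[factor]
    non_missing = values[values != MISSING]
    if len(non_missing) == 0:
        raise ValueError(f"all records have missing {factor!r}")
    counts = non_missing.value_counts().to_dict()
    total = len(non_missing)
    proportions = {lvl: c / total for lvl, c in counts.items()}
    return CompositionResult(
        factor=factor,
        proportions=proportions,
        counts=counts,
        n_missing=int((values == MISSING).sum()),
    )


def condense_nrem(
    rates: Mapping[str, float],
    weights: Mapping[str, float] | None = None,
    *,
    how: str = "stack",
) -> list[tuple[str, float]] | dict[str, float]:
    """Condense NREM substages (N1, N2, N3, NREM) into one NREM level.

    ``how="stack"`` keeps one observation per available substage value
    (relabelled NREM) for model stacking; ``how="mean"`` collapses them to
    a single weighted mean per study.  REM and W pass through unchanged.
    """
    known = set(STAGES)
    bad = [s for s in rates if s not in known]
    if bad:
        raise ValueError(f"unknown stages {bad}")
    if not rates:
        raise ValueError("empty stage set")
    if how == "stack":
        out = []
        for stage, value in rates.items():
            group = "NREM" if stage in NREM_FAMILY else stage
            out.append((group, float(value)))
        return out
    if how == "mean":
        nrem_vals = [(s, v) for s, v in rates.items() if s in NREM_FAMILY]
        out_d: dict[str, float] = {s: float(v) for s, v in rates.items() if s not in NREM_FAMILY}
        if nrem_vals:
            if weights is None:
                out_d["NREM"] = float(np.mean([v for _, v in nrem_vals]))
            else:
                w = np.array([weights.get(s, 1.0) for s, _ in nrem_vals], dtype=float)
                v = np.array([v for _, v in nrem_vals], dtype=float)
                out_d["NREM"] = float(np.average(v, weights=w))
        return out_d
    raise ValueError(f"how must be 'stack' or 'mean', got {how!r}")


def stack_observations(
    table: StudyTable,
    report_type: str,
    *,
    condense: str = "stack",
) -> pd.DataFrame:
    """One model row per (study × stage observation) for a report type.

    NREM substages are condensed per :func:`condense_nrem`; each row
    carries the study's context factors and covariates alongside the
    outcome proportion ``y``.
    """
    if report_type not in REPORT_TYPES:
        raise ValueError(f"unknown report type {report_type!r}")
    rows = []
    for _, rec in table.frame.iterrows():
        rates = {}
        for stage in STAGES:
            col = rate_column(stage, report_type)
            if col in table.frame.columns and pd.notna(rec[col]):
                rates[stage] = float(rec[col])
        if not rates:
            continue
        condensed = condense_nrem(rates, how=condense)
        pairs = condensed if condense == "stack" else list(condensed.items())
        for group, value in pairs:
            row = {"study_id": rec["study_id"], "stage": group, "y": value}
            for fld in CONTEXT_FACTORS:
                row[fld] = rec.get(fld, MISSING)
            for cov in ("year", "mean_age", "percent_female", "n_participants", "n_awakenings"):
                row[cov] = rec.get(cov, np.nan)
            row["gentle"] = rec.get("gentle", MISSING)
            rows.append(row)
    return pd.DataFrame(rows)


def _formula(terms: Sequence[str], data: pd.DataFrame, outcome: str = "y") -> str:
    parts = []
    for term in terms:
        if ":" in term:
            a, b = term.split(":")
            fa = f"C({a})" if data[a].dtype == object else a
            fb = f"C({b})" if data[b].dtype == object else b
            parts.append(f"{fa}:{fb}")
        elif data[term].dtype == object:
            parts.append(f"C({term})")
        else:
            parts.append(term)
    return f"{outcome} ~ " + " + ".join(parts) if parts else f"{outcome} ~ 1"


def fit_linear_model(
    rows: pd.DataFrame,
    terms: Sequence[str],
    *,
    outcome: str = "y",
    outcome_label: str = "y",
) -> ModelFit:
    """Ordinary least squares of an outcome proportion on model terms.

    Complete cases only; factor terms must retain at least two levels
    after row dropping.  The fit is deterministic given input order and
    reports the Gaussian-likelihood AIC.
    """
    base_cols = sorted({c for t in terms for c in t.split(":")})
    used = rows.dropna(subset=[outcome, *base_cols]).copy()
    # a missing factor level is missing data, not a level of its own
    for col in base_cols:
        if used[col].dtype == object:
            used = used[used[col] != MISSING]
    used = used.reset_index(drop=True)
    for col in base_cols:
        if used[col].dtype == object and used[col].nunique() < 2:
            raise ValueError(
                f"factor {col!r} has fewer than two levels in the complete cases"
            )
    formula = _formula(terms, used, outcome)
    model = smf.ols(formula, data=used)
    exog = model.exog
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        _, r = np.linalg.qr(exog)
        diag = np.abs(np.diag(r))
        aliased = [
            model.exog_names[i]
            for i in range(len(diag))
            if diag[i] < 1e-8 * diag.max()
        ]
        raise ValueError(f"rank-deficient design; aliased terms: {aliased}")
    if exog.shape[0] - exog.shape[1] <= 0:
        raise ValueError("zero residual degrees of freedom")
    res = model.fit()
    return ModelFit(
        outcome=outcome_label,
        terms=tuple(terms),
        coefficients=res.params,
        residual_sd=float(np.sqrt(res.mse_resid)),
        residual_df=int(res.df_resid),
        n_rows_used=int(res.nobs),
        aic=float(res.aic),
        result=res,
        data=used,
    )


def _reference_grid(fit: ModelFit) -> pd.DataFrame:
    """Grid of all factor-level combinations, covariates at sample means."""
    factors = fit.factors
    levels = {f: sorted(fit.data[f].unique()) for f in factors}
    combos = list(itertools.product(*(levels[f] for f in factors))) or [()]
    grid = pd.DataFrame(combos, columns=list(factors))
    for cov in fit.covariates:
        grid[cov] = float(fit.data[cov].mean())
    return grid


def _grid_matrix(fit: ModelFit, grid: pd.DataFrame) -> np.ndarray:
    design_info = fit.result.model.data.design_info
    (mat,) = patsy.build_design_matrices([design_info], grid)
    return np.asarray(mat)


def emm_contrasts(
    fit: ModelFit,
    factor: str,
    *,
    adjust: bool = True,
) -> list[ContrastResult]:
    """All pairwise level differences of estimated marginal means.

    The EMM of a level averages model predictions with equal weight over
    the levels of every other factor, with covariates fixed at their
    sample means.  SEs come from the coefficient covariance; p-values
    from the t distribution on the residual df; d = estimate / residual
    SD.  With ``adjust=True`` the returned set is BH-corrected as one
    family.
    """
    if factor not in fit.factors:
        raise ValueError(f"factor {factor!r} not in fit (factors: {fit.factors})")
    levels = sorted(fit.data[factor].unique())
    if len(levels) < 2:
        raise ValueError(f"factor {factor!r} has a single level")
    grid = _reference_grid(fit)
    mat = _grid_matrix(fit, grid)
    params = np.asarray(fit.result.params)
    cov = np.asarray(fit.result.cov_params())
    emm_rows = {
        lvl: mat[(grid[factor] == lvl).to_numpy()].mean(axis=0) for lvl in levels
    }
    out = []
    for a, b in itertools.combinations(levels, 2):
        c = emm_rows[a] - emm_rows[b]
        est = float(c @ params)
        se = float(np.sqrt(c @ cov @ c))
        t = est / se
        p = 2.0 * scipy.stats.t.sf(abs(t), fit.residual_df)
        d = est / fit.residual_sd
        out.append(
            ContrastResult(
                outcome=fit.outcome,
                label=f"{a} - {b}",
                estimate=est,
                se=se,
                statistic=t,
                df=fit.residual_df,
                p_raw=float(p),
                d=d,
                category=effect_size_category(d),
            )
        )
    if adjust:
        _apply_bh(out)
    return out


def covariate_tests(fit: ModelFit, *, include_intercept: bool = False) -> list[ContrastResult]:
    """t-tests of covariate slopes (and optionally the intercept).

    d is converted from the t statistic (2t/√df), the conventional
    standardization for slopes reported alongside contrast tables.
    """
    res = fit.result
    out = []
    names = list(res.params.index)
    for name in names:
        is_intercept = name == "Intercept"
        if is_intercept and not include_intercept:
            continue
        if not is_intercept and name not in fit.covariates:
            continue
        est = float(res.params[name])
        se = float(res.bse[name])
        t = est / se
        p = 2.0 * scipy.stats.t.sf(abs(t), fit.residual_df)
        d = 2.0 * t / math.sqrt(fit.residual_df)
        out.append(
            ContrastResult(
                outcome=fit.outcome,
                label="(Intercept)" if is_intercept else name,
                estimate=est,
                se=se,
                statistic=t,
                df=fit.residual_df,
                p_raw=float(p),
                d=d,
                category=effect_size_category(d),
            )
        )
    return out


def bh_adjust(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, original order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _apply_bh(results: list[ContrastResult]) -> None:
    adj = bh_adjust([r.p_raw for r in results])
    for r, a in zip(results, adj):
        r.p_cor = float(a)


def effect_size_category(d: float) -> str:
    """Categorize |d|: <0.2 negligible, <0.5 small, <0.8 medium, else large."""
    if not math.isfinite(d):
        raise ValueError(f"Cohen's d must be finite, got {d!r}")
    a = abs(d)
    if a < 0.2:
        return "negligible"
    if a < 0.5:
        return "small"
    if a < 0.8:
        return "medium"
    return "large"


def n2_n3_test(
    table: StudyTable,
    report_type: str,
    *,
    paired: bool = False,
) -> ContrastResult:
    """Welch two-sample t-test of N2 vs N3 study-level proportions.

    ``paired=True`` instead pairs within studies reporting both stages.
    Cohen's d uses the pooled SD.  The three report-type comparisons form
    their own BH family (applied by the caller across the three).
    """
    n2_col = rate_column("N2", report_type)
    n3_col = rate_column("N3", report_type)
    frame = table.frame
    n2 = frame[n2_col].dropna() if n2_col in frame.columns else pd.Series(dtype=float)
    n3 = frame[n3_col].dropna() if n3_col in frame.columns else pd.Series(dtype=float)
    if paired:
        both = frame[[n2_col, n3_col]].dropna()
        if len(both) < 2:
            raise ValueError("fewer than 2 studies report both N2 and N3")
        stat = scipy.stats.ttest_rel(both[n2_col], both[n3_col])
        n2, n3 = both[n2_col], both[n3_col]
        df = float(stat.df)
    else:
        if len(n2) < 2 or len(n3) < 2:
            raise ValueError("need at least 2 studies per stage for the N2-N3 test")
        stat = scipy.stats.ttest_ind(n2, n3, equal_var=False)
        df = float(stat.df)
    est = float(n2.mean() - n3.mean())
    s2, s3 = float(n2.var(ddof=1)), float(n3.var(ddof=1))
    na, nb = len(n2), len(n3)
    sp = math.sqrt(((na - 1) * s2 + (nb - 1) * s3) / (na + nb - 2))
    d = est / sp if sp > 0 else 0.0
    se = est / stat.statistic if stat.statistic != 0 else math.sqrt(s2 / na + s3 / nb)
    return ContrastResult(
        outcome=report_type,
        label="N2 - N3",
        estimate=est,
        se=float(se),
        statistic=float(stat.statistic),
        df=df,
        p_raw=float(stat.pvalue),
        d=d,
        category=effect_size_category(d),
    )


def stepwise_aic_interactions(
    base_fit: ModelFit,
    candidate_terms: Sequence[str],
) -> ModelFit:
    """Greedy bidirectional AIC search over interaction terms only.

    Main effects are retained in every step; at each step the single
    addition or removal of a candidate interaction that most lowers the
    AIC is taken (ties broken by term name order), until no move improves
    it.  Returns the AIC-minimal model visited.
    """
    main_effects = set(base_fit.terms)
    for term in candidate_terms:
        for part in term.split(":"):
            if part not in main_effects:
                raise ValueError(
                    f"candidate {term!r} references {part!r}, absent from the main effects"
                )
    current = base_fit
    included: list[str] = []
    while True:
        moves: list[tuple[float, str, str]] = []
        for term in sorted(candidate_terms):
            if term not in included:
                trial_terms = list(base_fit.terms) + included + [term]
                moves.append(("add", term, trial_terms))
        for term in sorted(included):
            trial_terms = list(base_fit.terms) + [t for t in included if t != term]
            moves.append(("drop", term, trial_terms))
        best = None
        for action, term, trial_terms in moves:
            try:
                trial = fit_linear_model(
                    current.data,
                    trial_terms,
                    outcome_label=base_fit.outcome,
                )
            except ValueError:
                continue  # e.g. rank-deficient with this interaction
            if trial.aic < current.aic - 1e-9 and (
                best is None or trial.aic < best[0].aic - 1e-9
            ):
                best = (trial, action, term)
        if best is None:
            return current
        current, action, term = best
        if action == "add":
            included.append(term)
        else:
            included.remove(term)


def auxiliary_covariate_model(
    table: StudyTable,
    covariate: str,
    report_type: str,
) -> ContrastResult:
    """Check an auxiliary study covariate against a report-type outcome.

    ``covariate`` is ``"year"``, ``"gentle"`` or
    ``"awakenings_per_participant"``.  The outcome is the stacked
    stage-condensed proportion, modelled as ``y ~ stage + covariate``;
    the returned result is the covariate slope (or the gentle yes−no
    contrast).
    """
    rows = stack_observations(table, report_type)
    if covariate == "awakenings_per_participant":
        rows[covariate] = rows["n_awakenings"] / rows["n_participants"]
    if covariate not in rows.columns:
        raise ValueError(f"unknown covariate {covariate!r}")
    sub = rows.dropna(subset=[covariate, "y"])
    if sub[covariate].dtype == object:
        sub = sub[sub[covariate] != MISSING]
    if len(sub) < 3:
        raise ValueError(f"covariate {covariate!r} non-missing for fewer than 3 records")
    if sub[covariate].nunique() < 2:
        raise ValueError(f"constant covariate {covariate!r}")
    terms = ["stage", covariate] if sub["stage"].nunique() > 1 else [covariate]
    fit = fit_linear_model(sub, terms, outcome_label=report_type)
    if sub[covariate].dtype == object:
        results = emm_contrasts(fit, covariate, adjust=False)
        return results[0]
    return covariate_tests(fit)[0]


def review_model(table: StudyTable, outcome: str) -> tuple[ModelFit, list[ContrastResult]]:
    """Fit the review model for one report type and assemble its tests.

    ``with_recall`` gets the extensive model (stage + method + question +
    repeated + setting + days + sleep type + mean age + percent female),
    dropping records at "other"/"both" levels listwise; the other two
    outcomes get stage-only models.  The returned contrasts carry BH
    corrected p-values over the model's whole test family.
    """
    rows = stack_observations(table, outcome)
    if outcome == "with_recall":
        for fld in CONTEXT_FACTORS:
            rows = rows[~rows[fld].isin(("other", "both"))]
        # a factor can collapse to one level once other/both rows are
        # dropped (common in small tables); it then carries no contrast
        terms = tuple(
            t
            for t in FULL_TERMS
            if rows[t].dtype != object
            or rows.loc[rows[t] != MISSING, t].nunique() > 1
        )
    else:
        terms = ("stage",)
    fit = fit_linear_model(rows, terms, outcome_label=outcome)
    family: list[ContrastResult] = []
    family.extend(covariate_tests(fit, include_intercept=True))
    for fld in fit.factors:
        family.extend(emm_contrasts(fit, fld, adjust=False))
    _apply_bh(family)
    return fit, family


def contrasts_to_frame(results: Sequence[ContrastResult]) -> pd.DataFrame:
    """Flatten contrast results into a delimited-friendly table."""
    return pd.DataFrame(
        {
            "outcome": [r.outcome for r in results],
            "contrast": [r.label for r in results],
            "estimate": [r.estimate for r in results],
            "se": [r.se for r in results],
            "t": [r.statistic for r in results],
            "p_raw": [r.p_raw for r in results],
            "p_cor": [r.p_cor for r in results],
            "d": [r.d for r in results],
            "effect_size": [r.category for r in results],
        }
    )
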