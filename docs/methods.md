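# Methods

## The data model

Two levels of data coexist in awakening research. At the *study* level,
a publication reports, per sleep stage, the percentage of awakenings
yielding each report type (experience with recall, experience without
recall, no report), together with design context: how participants were
woken (alarm/buzzer/sound/tone vs. calling by name vs. other), what they
were asked ("What went through your mind?" vs. "What did you dream?" vs.
other), repeated vs. single awakenings per recording, laboratory vs.
home, night sleep vs. naps, and single vs. multiple study days. At the
*participant* level, databases of pooled laboratory studies provide one
row per awakening with subject identity, stage and report category.

All proportions are held internally on the unit scale [0, 1]; rendering
multiplies by 100. Categorical fields use a closed vocabulary
(`data/harmonization.yaml`); a free-text label that is not in the
vocabulary raises an error rather than being guessed into "other",
because "other" is a substantive level (e.g. knocking on the door), not
a dumping ground. Missing is a distinct state, encoded as an empty field
in files, and is excluded from denominators rather than imputed.

Two derivations fill routine gaps in study tables. When a study merges
the two experience categories, the no-report share is inferred as
1 − (with + without); the inference errors if the two inputs already
exceed one. When only an age range is given, the mean age is
approximated by the midpoint (min + max)/2 — the midpoint is the stated
intent of such an approximation, and we compute it literally as the
centre of the range.

## Review-level models

**Composition statistics** are level shares over studies with a
non-missing level, so each factor's shares sum to one.

**Stage condensation.** Most studies report a single NREM figure; others
split N1/N2/N3. To use both on one scale, every NREM-family observation
is relabelled NREM and *stacked*: a study reporting N2 and N3 separately
contributes two NREM rows. (A weighted-mean collapse to one row per
study is available; on synthetic tables both orderings give the same
contrast signs.) REM and W pass through.

**Linear models.** Report-type proportions are modelled by OLS on the
stacked observations. The experience-with-recall outcome gets the
extensive design — stage, awakening method, question, repeated,
setting, study days, sleep type, mean age, percent female — with rows
at "other"/"both" levels dropped listwise, since those heterogeneous
levels do not support interpretable contrasts; the sparser without-
recall and no-report outcomes get stage-only models. Rows are
unweighted: study precision (participant count) varies, but no
principled weight is reported per observation, so each study-stage cell
counts once. If dropping rows collapses a factor to one level, the term
is removed from the design (it carries no contrast). Rank-deficient
designs error, naming the aliased columns.

**EMM contrasts.** Factor effects are reported as pairwise differences
of estimated marginal means: the EMM of a level averages model
predictions with *equal weight* over the levels of every other factor,
with covariates fixed at their sample means. In a balanced design this
reduces exactly to raw group-mean differences (tested); in unbalanced
data it answers "what if the designs were balanced". SEs come from the
coefficient covariance; p-values from the t distribution on the
residual df.

**Effect sizes.** For a factor contrast, Cohen's d = estimate / residual
SD (so d·σ̂ = estimate identically). For covariate slopes and the
intercept a per-unit slope divided by σ̂ is not comparable across
covariate scales, so d is converted from the t statistic as 2t/√df —
the conventional standardization when slopes sit in the same table as
contrasts.

**Multiplicity.** Benjamini–Hochberg step-up correction (via
statsmodels) is applied *per model*: one family per outcome, containing
the intercept/covariate tests and all factor contrasts of that model.
The three N2-vs-N3 comparisons form their own family. The N2–N3 test is
Welch's unequal-variance t-test on study-level proportions (unpaired by
default — studies reporting N2 rarely all report N3; a paired variant
over studies reporting both is available via `paired=True`), with d from
the pooled SD.

**Interaction screen.** Stage-by-factor interactions are screened by a
greedy bidirectional AIC search that may add or remove only interaction
terms; main effects are fixed. Ties are broken by term-name order, a
move requires an AIC improvement > 1e-9, and the AIC is the Gaussian
profile-likelihood form, so nested comparisons equal 2Δk − LR (tested).
On small candidate sets the greedy search matches exhaustive
enumeration (tested).

## Participant-level pipeline

Records are filtered to healthy participants and known stages
(legacy-scored S1/S2 map to N1/N2, S3/S4/SWS to N3; "Unknown"/"#N/A"
rows are dropped with counts logged). Subject IDs are unique only within
a study, so the working identifier is `study_id::subject_id` — the
separator is forbidden inside either component, keeping the map
injective. Age is dichotomized at 30 years (≤30 vs >30), the rounded
mean age of the pooled cohort.

A *participant-based percentage* is, for one participant and one stage
group, the fraction of their awakenings yielding a given report type.
Stage groups are single stages or the NREM pool (NREM ∪ N1 ∪ N2 ∪ N3).
Percentages backed by fewer than `min_n = 3` awakenings are discarded:
with one or two data points a percentage is an artifact of sampling, not
a trait estimate. Rates are exact count ratios (a `Fraction` column
accompanies the float), so a participant's three rates sum to one
exactly and the permutation statistic is free of accumulation drift.
Participants with missing sex or age are excluded before stratified
permutation — their stratum is undefined — and the exclusion is logged;
they remain available for plain stage summaries.

## The stratified permutation test

The statistic is the sample standard deviation (n−1 denominator) of the
eligible participants' percentages, on the 0–100 scale. Under the null
that report labels are exchangeable across participants *within* each
stratum, labels are reshuffled without replacement inside every stratum
(study × sex × age group, plus substage for NREM runs, so the N1/N2/N3
composition of each shuffle is preserved). Shuffling never moves a
label between strata and never changes a participant's awakening count,
so the min-n-eligible participant set is identical in every resample
(asserted in tests); percentages are simply recomputed from the permuted
labels.

The p-value is one-sided upper-tail with add-one smoothing,
p = (1 + #{SD\* ≥ SD_obs}) / (B + 1), since the statistic measures
*excess* variability and a resampling p-value of exactly zero is not
attainable. B defaults to 10 000. When several tests are run in one
invocation (by default 3 report types × {NREM, REM} = 6), they are
BH-corrected as one family. The generator is numpy's seeded
`default_rng` (PCG64); the seed is recorded in every result, and family
runs derive independent child seeds from one root seed.

Monte-Carlo calibration (tested): with 3 studies × 10 participants × 10
NREM awakenings and no participant effect, the rejection rate at
α = 0.05 over 400 replicate cohorts (B = 499) stays within
[0.03, 0.08]; power is nondecreasing over participant-effect SDs
τ ∈ {0, 0.5, 1, 2} (120 replicates per non-null point). These problem
sizes were chosen as the smallest at which Monte-Carlo error on a 5%
rate is acceptably small; the acceptance script uses a lighter 200 × 199
version of the null calibration.

## Synthetic-data generator

`generate_awakenings` samples hierarchically: a study effect
(SD `study_effect_sd`, default 0.5) and a participant effect (SD `tau`,
default 1.0) are drawn on the logit of the with-recall probability; the
without-recall/no-report mass is rescaled proportionally so each
participant-stage probability vector stays on the simplex; awakenings
then draw a stage from `stage_mix` and a report category from that
vector. This one-parameter mechanism was chosen as the simplest way to
make "participants differ" a single dial: `tau = 0` is exactly the
permutation test's null, and the study effect creates the between-study
structure the strata must absorb. Defaults mirror the pooled
participant-level cohort's scale — 18 studies, 27 participants each,
3–12 awakenings per participant — with stage-specific base
probabilities near the review's average per-stage rates (e.g. N2 recall
0.53, REM 0.83). Ages are a two-component normal mixture (means 24 and
38, SD 4, 60% young) straddling the 30-year cutoff; sex is Bernoulli
with 57% female.

What the generator does *not* emulate: sleep architecture (stage
sequences, time of night), correlation between a participant's stages
beyond the shared random effect, non-healthy subpopulations, missing
data patterns, or report-category drift within a night. Passing tests
therefore demonstrate correctness of the machinery and calibration
under a plausible hierarchical null — not that real cohorts satisfy the
null's exchangeability within strata.

`generate_study_table` draws context factors from the empirical
composition of the packaged 69-study table and builds outcomes as
linear predictor + Gaussian noise, clipped to [0, 1] with the clip count
recorded (clipping keeps the generator transparent; at the default
noise levels clips are rare). True coefficients are returned for
recovery tests.

## Reproducibility boundaries

Three published anchors need inputs not distributable here: the exact
review regression/contrast values require the per-study, per-stage
percentages of the review's supplementary table (users can supply them
in the packaged CSV schema via `rate_<stage>_<report>` columns); the
participant-level cohort counts (478 healthy participants / 18 studies;
151 NREM-eligible / 9; 70 REM-eligible / 7) and the NREM observed SDs of
28.7 / 19.3 / 27.1 percentage points require a local copy of the freely
available DREAM database v4 at `data/dream_v4.csv`, mapped to the
canonical columns. The pipeline for both is fully implemented and
exercised end-to-end on synthetic data; the corresponding acceptance
test states the expected cohort numbers and runs whenever the local
copy exists.

## Known limitations

- Study subsets of one publication enter the review models as
  exchangeable rows; no within-publication correlation is modelled.
- The EMM reference grid averages factor levels with equal weight;
  alternative weightings (observed margins) are not implemented.
- The N2–N3 estimate is reported on the unit scale with its SE; some
  published tables mix percent-scale estimates with unit-scale SEs for
  these rows, so cross-check scales when comparing.
- The permutation test detects *any* excess inter-individual
  variability; it does not attribute it to generation, encoding or
  retrieval of experiences, and offers no variance-component estimate.
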