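# Methods

This note documents the models, rules and numerical choices behind
`sleepcohort`, in the order the pipeline applies them, together with the
design decisions that were genuinely open and the limitations a user
should know.

## Extraction rules (hypnogram → nightly measures)

Epochs are half-open intervals `[start + i·epoch_s, start + (i+1)·epoch_s)`,
0-based, 30 s or 60 s. Three rule dialects share the same skeleton and
differ in two thresholds and one flag:

| dialect        | brief-wake exclusion | FA tail rule              |
|----------------|----------------------|---------------------------|
| `embrace`      | ≤ 5 min excluded     | ≥ 2 h required            |
| `eeg_algo`     | none                 | ≥ 2 h required            |
| `eeg_external` | none                 | end of recording accepted |

**SO** is the first epoch of the first sleep run whose total duration is at
least the consolidation window (10 min; the epoch counts toward the
window). **FA** is the first wake epoch after the night's *last*
consolidated sleep run; the remaining recording — which by construction
contains no further consolidated sleep — must last at least 2 h, or reach
the end of the recording where the dialect allows it. We read "followed by
2 h awake" as *2 h free of consolidated sleep* rather than one literally
uninterrupted wake run: with per-epoch classifier noise a single flipped
epoch in the morning would otherwise invalidate nearly every night, and
the two readings coincide exactly on clean sequences. **WASO** sums wake
runs strictly inside [SO, FA), dropping runs at or below the exclusion
threshold (inclusive: a 5-min bout is excluded). The exclusion applies
only to the WASO sum; SO/FA segmentation always runs on raw labels.
**TST = (FA − SO) − WASO** holds as an exact identity, and all quantities
are epoch-count-derived minutes, so daylight-saving shifts cannot corrupt
them. **SOL** is SO minus recording start (the lights-off proxy); values
over 120 min are flagged as outliers and excluded by the validity screen.

MISSING epochs count as wake during segmentation; a night whose [SO, FA)
span exceeds 10% MISSING is flagged unusable. Nights with no qualifying SO
or FA raise typed errors (`NoSleepOnsetError`, `NoFinalAwakeningError`)
that mark an unusable night, not a fault.

Multi-channel staged input is reduced per epoch by majority vote across
non-missing channels; ties break by the higher summed confidence, then by
the fixed order W > N1 > N2 > N3 > REM. The EEG stream is scored twice —
by "its own" algorithm (first channel, `eeg_algo` rules) and by the
external stager (majority vote, `eeg_external` rules) — giving two
distinct nightly estimates of the same latent night.

Parent reports: diary TST = (FA − SO) − WASO on the noon-anchored axis of
the labeled night (onsets past midnight belong to the morning of the
final-awakening date). Questionnaire (typical-night) SO and FA are the
noon-axis means of the weekday and weekend reports before the same TST
identity; WASO is reported once regardless of day type.

## Harmonization and screens

Nights are labeled by the calendar date of final awakening; when two
episodes share a label (an early-evening episode ending the same date),
the episode with the longest TST is the night's main sleep period.
Validity requires, per source: TST 3–16 h (inclusive bounds), sleep onset
between 19:00 and 07:00 inclusive (we apply the window to SO, since SO
starts the episode the criterion qualifies), WASO ≤ 3 h, EEG quality
score > 30/100 where present, SOL ≤ 120 min where defined. The analysis
cohort retains children with ≥ 3 nights *simultaneously* valid on all
required sources, and only those nights. Device-coverage is summarized as
Venn cells over (child, night) pairs passing the gross 3–16 h screen; the
cells sum to the number of distinct covered nights by construction.

## Agreement statistics

Lin's CCC uses population (n-denominator) moments, per the original
estimator. Time-valued measures enter as minutes-since-noon. Significance
comes from shuffling one vector's night labels (default 5,000 iterations);
the test is one-sided (top 0.1th percentile, nominal p = 0.001) and the
reported p uses the add-one estimator (1 + #{null ≥ obs})/(1 + n_iter),
which cannot return zero. The permutation loop is vectorized: under
permutation only the cross-moment changes, so null CCCs are affine in
permuted dot products. Per-child matrices first average each measure
across a child's nights per source and admit the questionnaire as an extra
source (one typical value per child); cells with fewer than 3 aligned
pairs are marked not-computable. Epoch-level sensitivity/specificity
between two devices aligns the overlap on the coarser epoch grid (the
finer series votes by majority within each coarse epoch, ties to wake) and
drops MISSING epochs pairwise.

## Mixed models and effect sizes

Group contrasts fit `outcome ~ diagnosis + age + sex + (1 | family)` by
REML (statsmodels MixedLM; the default optimizer with Powell and
Nelder–Mead fallbacks, since quasi-Newton fits occasionally hit singular
Hessians on family-clustered data). Diagnosis is coded autism = 1,
sex male = 1, age in raw years. ICC = σ²_between/(σ²_between + σ²_within)
from the full model's components. Cohen's f² for diagnosis uses the
*marginal* variance-explained proportion R² = var(Xβ̂)/(var(Xβ̂) + σ²_b +
σ²_w) of the full vs the diagnosis-free nested refit, floored at zero; a
conditional variant (adding σ²_b to the numerator) is available behind a
flag. Welch's t carries Satterthwaite df and Cohen's d with the pooled-SD
denominator √((s²_x + s²_y)/2); the 2×2 χ² reports both Yates-corrected
and uncorrected statistics.

## Dissociation stage

Per-child SOL and WASO come from each EEG scoring route over the child's
valid nights, then from their average (children missing either estimate
are excluded and counted). Each (measure × scale) cell is a Pearson r with
an uncorrected p — deliberately uncorrected, to preserve sensitivity, and
labeled as such in output. Steiger's (1980) Z for two dependent
correlations sharing the behavior variable uses Fisher transforms and the
shared-variable asymptotic covariance with the pooled mean correlation
r̄ = (r₁+r₂)/2:

    s = [ r₁₂(1 − 2r̄²) − ½·r̄²(1 − 2r̄² − r₁₂²) ] / (1 − r̄²)²
    Z = (z₁ − z₂)·√((n − 3) / (2(1 − s)))

with a two-sided p. Degenerate triples (|r| = 1, or a non-positive-definite
correlation matrix) raise errors. Correlation cells use pairwise-complete
observations, with the realized n recorded per cell.

## Synthetic cohort: what it emulates, and what it does not

The generator draws, per family, one autistic child and one sibling, a
shared family environment, and 10–16 nights per child; per night, a latent
sleep/wake trajectory on a 1-minute grid; per night × device, a corrupted
epoch-level observation; plus a biased parent diary, a typical-night
questionnaire report, and behavior scores. All distributional forms are
stand-ins chosen for qualitative realism — no real recordings informed
them — and all randomness flows from one root seed through named
per-(family, child, night, device) streams, so identical (spec, seed)
reproduces identical output byte for byte.

Key defaults (all in `CohortSpec`, all overridable; minutes unless noted):

- lights-off ~ Normal(22:30, 40); the recording starts at lights-off, so
  latent SOL is recoverable from the recording.
- nightly SOL ~ log-normal (non-negative, right-skewed, reproducing the
  long-latency outlier tail) with child-specific mean
  `sol_base (20) + 7.5·autism + family (SD 8) + child (SD 12)` and nightly
  SD `sol_night_sd` (default 0.4 × night_sd = 12 at the base mean). SOL
  varies less night-to-night than overall duration, hence the decoupling
  from `night_sd`.
- sleep period ~ Normal(480 + family TST intercept, 30), with
  `tst_family_sd = 40` so the family share of TST variance is ≈ 0.5 —
  shared schedules dominate sleep duration, matching the intraclass
  correlations reported for multi-device TST in school-age cohorts.
- wake bouts: Poisson(3)/night with exponential durations (mean 8 ×
  child-level log-normal factor), placed ≥ 10 min clear of SO and FA and
  ≥ 1 min apart, all on the integer-minute grid — so noiseless
  discretization at 60 s or 30 s is exact and ground-truth recovery can be
  asserted at 100%.
- devices: per-epoch flip noise (`miss_rate`), spurious ≤ 5-min wake bouts
  (`extra_brief_wake_rate`, large for the smartwatch to emulate its
  oversensitivity), night dropout, and for the EEG a 4-channel stage
  expansion with per-channel disagreement and confidences.
- diary: SO/FA plus bias (5) and noise (SD 10), rounded to 5 min; WASO
  scaled by 0.6 (parents miss awakenings) and floored at 0.
- behavior: one liability per child with loadings solved from the normal
  equations so its correlations with the child-level SOL and WASO
  propensities equal `behavior_sol_corr` (0.3) and `behavior_waso_corr`
  (0) exactly in expectation, even though the two propensities are
  themselves correlated (`sol_waso_propensity_corr = 0.4`; children with
  long onsets also tend to wake more — and without this correlation the
  dependent-correlation comparison at realistic cohort sizes is
  underpowered in a way real data, where the measured SOL–WASO correlation
  is substantial, is not). Eight questionnaire scales are affine readouts
  of the liability (loading 0.95) rescaled to plausible ranges, with the
  adaptive-behavior composite signed negatively.

Not emulated: raw physiological signals (EEG/PPG/EDA waveforms), circadian
dynamics, missing-questionnaire patterns, device-specific systematic
biases beyond the smartwatch's brief-wake oversensitivity, and any
dependence of dropout on sleep quality. Passing tests on this generator
therefore demonstrates that the *pipeline* recovers known structure under
realistic noise — not that any particular device is accurate in the field.

## Verification design

- Extraction is checked for exact agreement against an independent
  brute-force run-enumeration oracle (kept beside the tests, sharing no
  code) on thousands of random block sequences across dialects and epoch
  sizes, plus property tests: the TST identity, WASO monotone in the
  exclusion threshold, and invariance under 1-min → 30-s refinement.
- The permutation test is calibrated empirically (rejection rate at the
  0.001 rule over 2,000 independent-pair datasets); Lin's inequality
  |CCC| ≤ |r| is checked on 10,000 random pairs.
- Mixed-model recovery runs on per-child mean latent SOL under a condition
  whose true family variance share is computable (family SD 6.6, child SD
  10, nightly SD 10, 12 nights → ICC ≈ 0.30): the diagnosis β must fall
  within 2 SE of the injected 7.5 min and the ICC within ±0.1; type-I
  error is checked over 200 null cohorts.
- The dissociation check pools three replicate synthetic cohorts of ~200
  children: the realized liability–SOL correlation varies by ≈ 0.07 at
  that size, so a single cohort's Steiger outcome is itself a noisy draw;
  pooling estimates the intended "majority of scales" property with
  tolerable Monte-Carlo error.
- End-to-end determinism is asserted at the byte level on the full
  artifact tree of two identical runs.

Problem sizes throughout (cohort sizes, replicate counts, permutation
counts in tests) are chosen to give each check adequate statistical
resolution while keeping the default suite fast; `scripts/acceptance.py`
re-derives every headline number from scratch at the same sizes.

## Known limitations

- The FA rule's tolerance of non-consolidated sleep in the morning tail is
  a modeling choice; a stricter uninterrupted-wake reading is available by
  pre-smoothing labels upstream but is not the default.
- Whether the "started between 7 pm and 7 am" validity clause applies to
  sleep onset or recording start is configurable (`ValidityThresholds`);
  the default applies it to SO.
- The mixed model uses a single family random intercept; with repeated
  nights per child the child level is not modeled separately, so nightly
  analyses treat child-level deviations as residual correlation.
- CCC carries no bootstrap confidence intervals, and no Bland–Altman
  limits of agreement are produced.
- The generator's per-scale questionnaire noise is independent across
  scales given the liability; real questionnaires share method variance.
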