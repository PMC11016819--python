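# Methods notes

This document records the modelling assumptions, parameter choices, and
numerical conventions behind `cogmark`, and what the synthetic-data tests do
and do not establish about real data.

## Coordinate and unit conventions

All task coordinates are screen centimetres after card calibration, origin at
the top-left, y increasing downward; distances are Euclidean. Reaction times
are seconds. Biomarkers are pg/mL (the Aβ42/40 ratio is dimensionless) and are
log₁₀-transformed before any correlation or regression, reflecting their
right-skewed distributions.

## Task scoring

**OMT response decomposition.** The literature behind "what was where?" tasks
models localization responses as a mixture of target-directed responses,
misbound responses (centred on a non-target item), and guesses. `cogmark`
classifies each response deterministically by the nearest displayed item,
with a guess threshold τ = 3 cm: a response farther than τ from every item is
a guess. τ equals the minimum item separation the layout generator enforces,
so the clear zone around each item is exactly the region the classifier
attributes to it. This is simpler than fitting a probabilistic mixture
(a possible extension point) but is deterministic, fast, and — by the
round-trip tests — recovers generating mixture weights within Monte-Carlo
error. Imprecision is the SD (n−1) of response-to-assigned-centre distances
over target-classified responses. Location error averages over
identification-correct trials only; when there are none it is missing, never
zero. Reaction times are summarized per participant by the median, which is
robust to the long right tail of unsupervised online responding.

**ROCF anchor-distance score.** Only anchor-relative distances are scored:
per element, the absolute difference d between ideal and actual distance from
the middle large rectangle is compressed logarithmically,
`scaled = min(1, log(1 + d/d₀) / log(1 + D/d₀))`, and the element scores
`1 − scaled`. The constants d₀ = 1 cm (error at which the penalty begins to
compress) and far cutoff D = 10 cm (zero score at or beyond) are exposed as
arguments. The mapping is monotone, exactly 1 at d = 0 and exactly 0 at
d ≥ D. An unplaced element scores 0; an unplaced *anchor* falls back to the
template anchor position and flags the result rather than zeroing the figure.
The 13-element template geometry bundled in `task_scoring.ROCF_TEMPLATE` is
schematic (synthetic): the published figure's element layout is not
distributed, and the score depends only on anchor distances, so any template
with plausible distances is faithful. The score is invariant under rigid
motions applied jointly to all placements.

**CORSI short responses** are penalized, not dropped: each missing click is
charged the arena-diagonal distance (configurable cap) and the trial is
flagged. **DSST idle time** accumulates the excess of each inter-response gap
(including start → first response) over a 5 s grace unit; the attention check
triggers above 60 s total. **TMT** completion time is the last correct click;
incomplete trails are excluded from condition means, and a condition with no
complete trial is missing.

## Quality control

The six checks and the ">3 failed → exclude" rule follow the battery's design.
Two readings were open and are resolved as follows: the OMT speed check
triggers on *any single* localization faster than 0.2 s (strictest reading;
threshold configurable), and the ROCF copy floor applies to control groups
only — an impaired copy in the patient group is expected, not suspicious.
Failed checks discard that task's data before normalization; QC is idempotent.

## Normative z-scores

z = (x − mean(ref)) / sd(ref) over normative-group members within an
*inclusive* ±3-year age window, SD with the n−1 denominator, after averaging
multi-visit rows per participant. Cells with fewer than n_min = 20 usable
reference members (a configurable floor; the source cohort's observed minimum
window occupancy was larger) or zero reference SD are missing, never zero.
Normative-group members are standardized leave-one-out against their own
group, which removes self-inflation; everyone else uses the full window. The
raw metric direction is preserved, so error-type metrics give positive z when
performance is worse.

## Statistics

Group contrasts use the two-sided Mann–Whitney U with the tie-corrected normal
approximation; the rank-biserial effect size is r = 1 − 2U/(n₁n₂) with
U = #(a > b) + ½·ties, so the first group being stochastically smaller gives
r = +1 and swapping groups flips the sign exactly. Partial Spearman
correlations rank-transform the two variables (average ranks), residualize
both on the covariates (age in years, sex coded 0/1, education in years) plus
an intercept by least squares, and correlate the residuals; p-values use a t
approximation on n − k − 2 degrees of freedom. Covariate adjustment by
residualization (rather than stratification) is the documented default. One
Benjamini–Hochberg family spans the entire biomarker × metric grid
(4 × 19 = 76 tests); q-values are monotone in p. All tests are two-tailed at
α = 0.05.

## Classification

Feature importances are −ln p of a univariate test, so `exp(−score)` recovers
the p-value exactly. For classification the feature is discretized into
deciles of the pooled sample (duplicate quantile edges merged; adjacent bins
merged until every expected cell count is ≥ 1) and tested against the label by
Pearson χ² without continuity correction; for regression the slope F test of a
simple linear fit is used (F = t²). Exhaustive model selection fits every
predictor subset — capped at 12 candidates, i.e. 4,096 subsets — on one fixed
complete-case set and ranks by AICc; for linear models k counts the intercept
and the residual variance. Logistic subsets that (quasi-)separate fall back to
a fixed-strength L1 fit and are flagged; the standalone penalized fit chooses
its penalty by stratified cross-validation. AUCs are reported in-sample via
the Mann–Whitney identity (ties counted half); no cross-validation is applied
by default, so AUCs of near-separable small samples are optimistic — this is
deliberate and documented rather than hidden. The DeLong comparison computes
placement values V₁₀/V₀₁ per model, their 2 × 2 covariance across models, and
a two-tailed Z test on the AUC difference; identical score vectors return
Z = 0, p = 1.

## Synthetic cohort generator

The generator defines the study conditions for every test. Group sizes default
to AD 46 / in-person controls (EHC1) 53 / online normative controls (EHC2)
352; ages are normal (68.3 ± 10.2, 68.6 ± 7.0, 59.9 ± 8.5 years, clipped to
[50, 95]); only AD and EHC1 receive plasma panels.

**Latent severity.** One latent severity value per participant
(AD ~ N(2.0, 0.8), EHC1 ~ N(0, 0.8), EHC2 ~ N(0.35, 0.8) — the online group
performs slightly worse, with more misbinding, than the in-person controls)
drives every task parameter through monotone logistic/log-linear maps: the
OMT mixture (healthy baseline ≈ 72% target / 22% misbinding / 6% guessing),
spatial imprecision, identification probabilities, reaction-time scales,
figure-element displacement and omission, tapping error, symbol-matching
speed/accuracy, and trail completion times. The maps were calibrated once so
group-level metric contrasts land in the published effect-size range (large
AD deficits on every metric) and are not revisited per test.

**OMT guesses.** A guess is a placement not directed at any remembered item:
uniform over the arena *excluding* the τ = 3 cm zones around the displayed
items, mirroring the task's clear-zone design. Fully uniform guesses would
land inside an item zone ~19% of the time in the default arena and be
absorbed by the nearest-item classifier, biasing recovered guess rates by
~0.02 — far beyond Monte-Carlo error at n = 10,000. Uniformity is therefore
tested on the guess support. The default arena is 28 × 16 cm (a typical
laptop display at calibration; the source battery does not publish arena
dimensions) with a 1 cm placement margin.

**Biomarkers.** Each biomarker is log-normal with raw-scale group moments
matched to the published cohort means/SDs (p-tau181 5.4 ± 3.4 vs 2.6 ± 1.3
pg/mL; GFAP 224.7 ± 118 vs 111.8 ± 57.9; NfL 29.7 ± 19 vs 17.1 ± 11; Aβ42/40
0.059 ± 0.01 vs 0.067 ± 0.01). The Aβ42/40 ratio and Aβ40 are the generated
primitives and Aβ42 = ratio × Aβ40, so the ratio keeps its published moments
exactly. The log-scale severity slope of each biomarker is identified from the
AD-vs-EHC1 mean difference; a per-biomarker *coupling fraction* (p-tau181 1.0,
NfL 1.0, GFAP 0.15, ratio 0.05) sets how much of that slope also operates
within group, and the residual SD is set so the total within-group
log-variance reproduces the configured moments (keeping raw-scale sample means
on target). The couplings were calibrated once to reproduce the qualitative
association structure reported for such cohorts — p-tau181 most strongly
correlated with cognition, the Aβ42/40 ratio weakest — and are not tuned per
test.

**TMT maps** are generated by dart-throwing circle placement (no overlaps)
followed by 2-opt uncrossing of the visiting order; 2-opt segment reversal
strictly shortens the path, so the loop terminates, with an x-monotone
ordering (crossing-free by construction) as a final fallback. The published
"divide-and-combine" map algorithm is not specified anywhere accessible; only
map validity (non-overlap, non-self-intersecting path) matters downstream.

**What the generator does not emulate:** device heterogeneity and calibration
error, practice effects, within-session fatigue, non-Gaussian age structure,
missing-at-random dropout, and any direct age → cognition dependence beyond
group composition (z-scoring is exercised by the age window, not stressed by
strong age trends). Passing tests therefore demonstrate the *pipeline's*
correctness and calibration under a plausible data-generating process, not
clinical validity on real cohorts.

## Test design notes

- Round-trip recovery of the OMT mixture uses 10,000 trials and 3-SE bounds;
  the radial imprecision SD of a 2-D isotropic Gaussian is σ·√(2 − π/2).
- Null calibration checks (Mann–Whitney type-I, BH FDR, ranking p-value
  uniformity) use 500–1,000 replicates at small n and fixed seeds.
- The generator's no-effect null is checked at n = 1,000/group with reduced
  trial counts (the null is exchangeable across groups regardless of
  trial-level measurement noise), so the ±0.03 AUC band is ~3 Monte-Carlo SE.
- The biomarker-strength *ordering* check averages the per-biomarker mean
  |partial ρ| over eight replicate cohorts at the study sample sizes: a single
  cohort provides one draw of 99 biomarker values, whose sampling noise
  (≈ 0.08–0.1 on a correlation) exceeds the NfL-vs-ratio margin often enough
  that a single-cohort four-way ordering is unstable by design, not by defect.
- Pipeline-scale tests reuse one session-scoped cohort fixture; the pipeline
  smoke test runs at reduced sizes (25/25/150, fewer trials) for speed.

## Known limitations

- The OMT classifier is a hard-assignment stand-in for mixture-model
  decomposition; with large imprecision (σ approaching τ) the rates blur.
- In-sample AUCs on near-separable samples are optimistic; an out-of-sample
  option exists via the penalized fit's CV machinery but is off by default.
- The exhaustive-selection penalized fallback uses a fixed penalty inside the
  subset loop (cross-validating each of up to 4,096 subsets would dominate
  runtime); its AICc entries are flagged and should be compared with care.
- Education and sex enter only as covariates; norms are age-stratified only.
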