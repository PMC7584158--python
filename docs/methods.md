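# Methods

`emostate` implements a pipeline for detecting a person's prevailing
emotional state, and changes of that state, every five minutes from
passively collected smartphone/smartwatch data plus sparse self-reported
emotion words. This note records the model, the defaults and why they were
chosen, and the places where a design decision was genuinely open.

## Emotion model: dominant PAD dimension

Discrete emotion words are mapped to the pleasure–arousal–dominance (PAD)
space through a normative affective-rating table (ANEW-style): each word
carries ratings p, a, d ∈ [1, 9]. Ratings are centred,

    R_s = R − 5 ∈ [−4, +4],

and the *dominant dimension* is the one with the largest |R_s|; its sign
gives the direction. This yields six states: (p,−) discordant, (p,+)
pleased, (a,−) dissuaded, (a,+) aroused, (d,−) submissive, (d,+) dominant.

Open corners of this rule and how the package resolves them:

- **Ties.** Among tied absolute maxima the first *positive* dimension in
  P→A→D order wins (the canonical tie case is a word whose p and a
  ratings coincide); if no tied dimension is positive, the first tied
  dimension in P→A→D order wins with negative direction. Deterministic
  and a strict extension of the positive-tie rule.
- **The neutral point.** A word scaling exactly to (0, 0, 0) has no
  dominant dimension; the package raises an explicit error rather than
  inventing a state.
- **Float round-trip.** R_s + 5 recovers R bit-exactly for R ≥ 2.5
  (Sterbenz), and to one ulp below that; the shipped table is unaffected.

The package ships a small rating table: the two published ANEW rows
(`happy`, `angry`) plus a *synthetic* ten-word vocabulary whose invented
ratings cover all six states (marked as synthetic in the CSV header). Any
user table with columns `emotion,p,a,d` is accepted.

## Windowing and mixed-type aggregation

Per-minute long-form records (person, timestamp, channel, value) are
aggregated onto a 5-minute grid running from midnight of each person's
first day to midnight after their last record, so a complete day is
exactly 288 windows. Aggregators follow the channel kind: mean for
continuous, sum for binary (a 0–5 count of active minutes), max for
ordinal. Windows with no records are fully masked.

Imputation and standardization are training-fold operations:

- **Default order** — fit per-column mean/SD on the *observed* training
  cells, standardize observed cells everywhere, then fill masked cells
  with the sentinel (−1000 by default, configurable). This keeps the
  sentinel out of the statistics.
- **Strict order** (`sentinel_before_scaling=True`) — write the sentinel
  first and fit the statistics over everything, reproducing pipelines
  that standardize after imputation. The sentinel then dominates the
  column mean wherever missingness is heavy.

Zero-variance columns get scale 1 (standardization is a no-op there);
fully missing columns become all-sentinel.

## Engineered features

**Temporal (5 columns).** minute-of-hour, minute-of-day, hour-of-day,
day-of-week (Monday = 0, ordinal), and time-difference-in-minutes since
the person's previous non-empty window (0 at a person's first window; a
gap of three empty windows gives 20). The four calendar columns are
ordinal, the gap continuous. The gap column matters doubly: it measures
sparsity, and in the relaxed transition mode (below) it tells the model
how stale the reference state is.

**Location (3 columns).** Coordinates are snapped to the centre of their
precision-8 geohash cell (40 interleaved bits, longitude first; at the
equator a cell is ≈ 38.2 m east–west × 19.1 m north–south), giving
`cl_latitude`/`cl_longitude`; `geo_dist` is the haversine distance in
metres from the person's previous observed position, using the IUGG mean
Earth radius 6 371 008.8 m. Cell centres (rather than corners) and that
radius are conventions the package fixes explicitly.

## Targets

**State.** Each window carries the state of the self-report(s) falling in
it; when several fall in one window the most recent wins. Unreported
windows are unlabeled.

**Transition.** y = 1 iff the state differs from the reference previous
state. Because reports are sparse, the default reference is the person's
most recent *labeled* window, whatever the gap (the gap is visible to
models through the time-difference feature); `strict_consecutive=True`
restricts the reference to the immediately preceding grid window and
leaves other windows unlabeled. Neither mode is claimed to be uniquely
correct; both are first-class.

**Per-person pruning.** For personalized state modeling, any class with
≤ 6 samples in a person's data is removed; a person left with fewer than
two classes is excluded. The operation is idempotent (removing one class
cannot push another below the threshold).

**Delta features.** The transition task is trained on within-person first
differences T_t,k = f_t,k − f_{t−1,k} of the (standardized, imputed)
labeled-window sequence — the change in each feature since the reference
window. Binary and ordinal columns are differenced like any other, so the
telescoping identity Σ_t T_t,k = f_last,k − f_first,k holds uniformly.
Deltas never cross persons, and each person's first labeled window is
dropped.

## Evaluation harness

Two designs:

- **General** — leave-3-people-out: persons are partitioned (seeded) into
  groups of three; each group is one test fold (18 persons → six folds).
  Location columns are dropped entirely in this mode, since absolute
  coordinates cannot generalize across people.
- **Personalized** — per-person stratified 5-fold over that person's
  labeled windows; metrics are averaged over folds within person, then
  mean (SD) is reported across persons.

Everything that can leak is fit on training rows only, per outer fold:
the > 30 % missingness column filter, standardization, ANOVA-F top-k
feature selection (k ∈ {50, 70, 90, 110}, clamped when fewer columns
survive; ties break by column order), oversampling, and the classifier
(with an optional inner 3-fold stratified grid search maximizing macro
F1; `tune=False` uses the family's default parameters). Each fold's
training-side artifacts (selected columns, scaler parameters, oversampled
arrays, fitted model bytes) are digested so tests can assert
byte-identity under test-row mutation.

Model families: regularized logistic regression, random forest,
gradient-boosted trees (xgboost), and a one-hidden-layer perceptron, each
with a small published-default grid recorded in `MODEL_FAMILIES`.

**Oversampling.** SMOTE and SVMSMOTE are implemented in this package:
synthetic minority rows are convex combinations x + u(x′ − x) of a
minority sample and one of its k = 5 nearest minority neighbours
(neighbourhoods shrink with a log message for tiny classes); the SVM
variant seeds interpolation from minority-class support vectors of an SVC
fit on the training fold. Both balance every class up to the majority
count and are training-only by construction.

**Metrics.** Accuracy, balanced accuracy, macro precision/recall/
specificity/F1, and macro one-vs-rest AUROC over the training class set.
Macro averaging weights every class equally, which is the point under
the heavy imbalance of sparse self-reports. Specificity is TN/(TN+FP)
averaged over classes that have negatives; AUROC terms skip classes
degenerate in the test fold.

**Importance tally.** For each fitted fold (and person), the categories
of the three most important selected features increment a 7 × 3
(category × rank) counter matrix. The attribution is whatever total
ordering the model exposes — tree gain, mean |coefficient|, or
permutation importance as a fallback — because the tally, not the
attribution algorithm, is the analysis. Ties break toward the lower
column index.

## Synthetic data generator

The generator emulates the *structure* of a free-living mobile-sensing
collection so the whole pipeline is testable without any download: 18
default persons, 3–9 days each, per-minute records in seven channel
categories, sparse emotion words, and 38–88 % missing windows.

Mechanics: each person follows an hour-block schedule of context states
(home/sleep, work, with-friends, home/TV, optionally outdoors). Each
context fixes a motion level, an audio level, a location anchor (anchors
≥ 100 m apart so geohash-8 cells separate them; jitter SD ≈ 5 m), a
per-channel Bernoulli probability for phone-state channels, a mean level
for environmental channels, and a near-one-hot pattern on the contextual
label channels (1 % flip noise). Self-reports arrive with uniform
10–60 min gaps; with probability ρ the word is the context's word,
otherwise uniform over the vocabulary. Whole 5-minute windows are then
deleted with probability m.

Parameter defaults and rationale:

| parameter | default | why |
|---|---|---|
| ρ (regularity) | 0.99 | keeps pooled transition prevalence ≈ 13 % (< 15 %), emulating the dominance of no-transition windows in sparse self-report data |
| m (missingness) | 0.38–0.88 across persons | the observed missing-window range in this kind of collection |
| report gap | U(10, 60) min | sparse-but-usable self-report cadence |
| days | cycle over 3–9 | study-scale collection lengths |
| channel counts | 36 (compact) / 273 (`FeatureSchema.build()`) | full-scale counts (138 motion, 28 audio, 17+3 location, 28 phone-state, 6 environmental, 51 contextual) are available; the compact schema keeps experiments fast without changing pipeline shape |

`default_profiles(permute_emotions=True)` gives each person an
individually shuffled context→word mapping: a heterogeneous population on
which general models should fail while personalized models succeed —
the qualitative personalization effect as a testable property.

What the generator does **not** emulate: physically realistic
accelerometer or audio waveforms (channels are context-conditioned
Gaussians/Bernoullis), label noise in self-reports, multi-day
non-stationarity, or report-free periods such as sleep. Consequently,
passing recovery tests shows the pipeline extracts context–emotion
structure when present and finds none when absent; it does not certify
performance numbers on real populations.

## Problem sizes in the test suite

The recovery experiments use one synthetic person with 9 complete days
and 10–20 min report gaps (≈ 860 labeled windows) per ρ, three persons
per ρ for the monotonicity check (generator seeds fixed), and a
six-person population for the leakage and general-mode checks — sizes
chosen so the full suite exercises every stage end to end in about a
minute on one core.

## Known limitations

- The univariate selector is ANOVA-F for all columns, including binary
  ones, where a chi-square score would also be defensible.
- The MLP family exposes no native importances; the tally needs
  validation data for permutation importance there.
- `balanced_accuracy` averages recall over classes present in the test
  fold, while macro precision/recall average over the training class set
  (absent-class terms contribute zero); the two conventions diverge on
  degenerate folds, which are logged rather than silently patched.
- Geohash cells are rectangles in degree space; at high latitudes the
  metric east–west extent shrinks, so the "38.2 m" figure is equatorial.
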