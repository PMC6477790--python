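# Methods

This note documents the models and procedures `painmarkers` implements, the
choices made where the design was genuinely open, and what the synthetic
world does and does not establish.

## Pipeline model

The pipeline treats biomarker discovery as an evidence-accumulation
problem: no single step is trusted, and each candidate accrues points from
six quasi-independent sources (within-subject tracking, prior literature,
an independent severe-pain gradient, and three independent-cohort
prediction tasks). The final Convergent Functional Evidence (CFE) score is
a deliberate weighting scheme, not a fitted model: 36 of the 48 possible
points come from empirical data and 12 from literature, a fixed 3:1 ratio.

### Discovery scoring

The comparison unit is every within-subject (Low Pain, High Pain) visit
pair, pooled across subjects with equal weight per pair. This is the
simplest reading of a "within-subject design followed by across-subject
summation"; a per-subject majority vote would weight subjects rather than
pairs and is not implemented (the pooled fraction is what the point
thresholds act on).

* **DE fold threshold**: 1.2× on the linear scale, configurable. The value
  is a conventional minimal microarray change, not derived from data.
* **33% threshold**: implemented as fraction ≥ 1/3 exactly (within 1e-12),
  so that 4 concordant pairs out of 12 score 2 points while 3/10 scores 0.
* **Marginal calls** in AP scoring never count as a switch; only strict
  A→P / P→A transitions do. The 0/0.5/1 numeric encoding of A/M/P is used
  only in AP-mode validation.
* **Direction ties** (equal increased and decreased concordance) score 0
  and carry no direction; an undirected marker cannot enter risk-oriented
  composites downstream.
* Zero Low-Pain intensity with nonzero High-Pain intensity counts as a
  concordant increase (the ratio diverges); zero/zero counts as no change.
* Each probeset keeps one row per method; the maximum of the AP and DE
  internal scores feeds prioritization and CFE.

### CFG prioritization

Six evidence categories at 2 points each reproduce the 12-point external
cap; weights are configurable because curated evidence bases can warrant
uneven category weights (published tables include external scores, e.g. 7,
that uniform even weights cannot produce). Multiplicity within a category
adds nothing. Scores attach to gene symbols and propagate to all probesets
of the gene through a user-supplied map. The carry-forward cutoff is a
combined (internal + external) score ≥ 6 — one third of the 18-point
maximum — which deliberately admits genes with maximal internal evidence
and no literature record. The prioritization *long-list* cutoff (≥ 8) is
applied to the external score alone.

### Validation

Stratified z-scoring uses sample standard deviation (ddof = 1). A stratum
(gender × diagnosis) in which a probeset has no variance, or only one
sample, is excluded as missing — never zero-filled — matching the 0/0
z-score exclusion rule. "Stepwise" requires strictly ordered group means in
the probeset's discovery direction (ties are not progression). The High
Pain validation group excludes clinically severe visits, which form their
own group. The Bonferroni denominator defaults to the number of candidate
rows entering validation and can be fixed by config.

### Testing

* The ROC AUC is the Mann-Whitney U statistic scaled by
  n_cases × n_controls with ties counted one half; its one-sided p-value
  uses the tie-corrected normal approximation (scipy's asymptotic
  Mann-Whitney). The exact p-method of the original analyses is unknown;
  one-sided normal approximation matches the one-tailed reporting
  convention used throughout.
* Trait models: Cox proportional hazards (lifelines) on the risk-oriented
  marker score, censored at 365 days (first-year outcome) or at the last
  clinical note (all-years); logistic regression (statsmodels) for the
  all-years odds ratio, per 1 z of the marker so ORs are comparable across
  markers. One-sided p-values are half the Wald two-sided p when the
  coefficient is risk-directed, 1 − p/2 otherwise.
* Orientation: decreased-direction markers are negated before any trait
  model, so a hazard or odds ratio > 1 always reads as increased risk.
  Tests assert full invariance of every metric under (negate z, flip
  label).
* Longitudinal features: last level, maximum level, slope into the most
  recent visit, maximum between-visit slope (Δz/Δdays). The composite is
  the equal-weight mean of the four features after cohort-wise z-scoring
  of each; the original feature weighting is not specified beyond naming
  the features, so equal weights are used and exposed.
* Predictions are visit-level for the state outcome (subjects contribute
  all eligible visits) and subject-level at the index (last) visit for
  trait outcomes. Strata with fewer than 2 cases or 2 controls are emitted
  as skipped rows with a reason. The pooled PSYCHOSIS stratum is
  schizophrenia ∪ schizoaffective.

### CFE

Testing points per outcome: 8 / 6 / 4 for the best stratum level (all /
gender / gender × diagnosis) with a nominally significant (one-sided
p < 0.05, uncorrected) result in either mode; Bonferroni-surviving testing
results earn no extra points. Ranking is by total, ties broken by the
empirical (non-literature) subtotal, then by probeset ID for stability.

## Synthetic world

`generate_cohort` emulates the structure the analysis assumes:

* **Visits**: 2–5 per subject; the first two are forced to one Low and one
  High Pain visit so every subject is discovery-eligible (configs allowing
  single-visit subjects are rejected). VAS is uniform within the Low (0–2)
  and High (6–10) blocks; the within-block distribution is a config choice,
  not an empirical claim. High-Pain visits are clinically severe (SF-36
  items 21 + 22 ≥ 10) with probability 0.35 by default.
* **Expression**: log2 intensities are Normal(baseline + shift, noise_sd)
  and exponentiated, matching the log-normal microarray convention and the
  2^x de-log step. Null probesets draw baselines over ±3 log2 units around
  7.0; planted markers sit at baseline − 0.5, inside the Marginal call
  band, so state shifts can flip detection calls. The planted shift is
  effect_size × noise_sd per unit of pain state, with state levels Low 0,
  Intermediate 0.5, High 1.0, Severe 1.5 — the Severe excess is what makes
  planted markers stepwise in validation, chosen once a priori.
* **Calls**: A below baseline − 1 log2 unit, P above baseline, M between.
  This is a stand-in for detection-call generation, which the pipeline only
  consumes, never produces.
* **Follow-up**: homogeneous Poisson emergency-department pain visits per
  subject at base rate 0.0012/day (≈ 35% first-year event fraction at the
  cohort mean), tilted by exp(β·z) where z is the standardized
  risk-oriented composite of the planted markers at the subject's index
  visit and β defaults to 0.5. Follow-up horizon: uniform 1 to ~5.6 years,
  mirroring a long-follow-up registry cohort.
* **Defaults**: 32% female; diagnosis mix dominated by mood and psychotic
  disorders (BP/MDD/SZ/SZA 0.85 combined) as in the intended population.

What a green test establishes: the pipeline recovers planted directions,
discovery/validation scores, and planted hazard/odds parameters under this
idealized world. What it does not: robustness to batch effects, probe-level
noise, medication covariates, non-log-normal intensity distributions, or
informative censoring — none of which are simulated.

`reference_cohort()` is the deterministic 28-subject/79-visit longitudinal
design (3×5, 1×4, 12×3, 12×2 visits; 19 male, 9 female) with alternating
diametric pain states; `reference_evidence()` is the six-category
literature census (212 + 3 + 57 + 26 + 48 + 9 = 355 records) distributed
over synthetic gene symbols. Both are design fixtures, not patient data.

## Numerical notes

* All randomness flows from a single integer seed through one
  `numpy.random.Generator`; identical configs are byte-identical on re-run.
* Stratified z-scores use ddof = 1 throughout; z-moment tests assert mean 0
  and sd 1 to 1e-9 per retained stratum.
* ANOVA p-values come from `scipy.stats.f_oneway` and are checked against a
  permutation F null in tests (2000 permutations, Monte-Carlo tolerance).
* Same-day repeat visits in longitudinal series are perturbed by 1 ns-scale
  day offsets to keep slopes finite; genuinely non-increasing day sequences
  are rejected.
* Degenerate strata (single class, perfect separation, non-convergent
  fits) are reported as skipped rows with reasons, never silently dropped.

## Known limitations

* The evidence table is an input; no literature mining is performed.
* Raw array processing (RMA/MAS5) is out of scope: the pipeline starts from
  normalized linear intensities and A/M/P calls.
* Connectivity-map drug repurposing, pathway analyses, and phenotypic
  subtype clustering are out of scope; CFE carries optional free-text
  annotation columns only.
* When no independent test cohort is supplied, the study cohort doubles as
  the test cohort; resulting prediction metrics are optimistic and suited
  only to synthetic or exploratory use.
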