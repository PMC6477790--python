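# painmarkers

Pain is a subjective report with a biological substrate, and clinical care
lacks an objective readout for it. `painmarkers` implements a six-step
blood gene-expression biomarker pipeline for pain in psychiatric cohorts —
a population with high co-morbid pain burden — going from longitudinal
within-subject discovery to a single ranked convergent-evidence score per
candidate biomarker. It is aimed at researchers running (or re-analysing)
visit-keyed expression studies with repeated pain phenotyping, and ships a
synthetic-cohort generator so the whole pipeline is testable without
patient data.

## The method

1. **Discovery (0–6 points).** Each subject with a diametric pain change —
   at least one Low Pain visit (visual-analog scale, VAS ≤ 2) and one High
   Pain visit (VAS ≥ 6) — contributes all within-subject (Low, High) visit
   pairs. Each probeset is scored for concordant change across those
   comparisons by two methods: **DE** (linear intensity ratio ≥ 1.2× or
   ≤ 1/1.2) and **AP** (Absent→Present or Present→Absent detection-call
   switches). The winning direction's concordant fraction maps to internal
   points: ≥ 33% → 2, ≥ 50% → 4, ≥ 80% → 6.
2. **Prioritization / CFG (0–12 points).** Convergent Functional Genomics:
   prior literature evidence per gene over six categories (human/non-human
   × genetic / nervous tissue / peripheral), 2 points per non-empty
   category, capped at 12. Probesets with combined internal + external
   score ≥ 6 (of a maximum 18) go to validation.
3. **Validation (0–6 points).** Expression is de-logged (2^x where input is
   log2), z-scored within gender × diagnosis strata (zero-variance strata
   excluded, not zeroed), and tested for a strict stepwise change across
   Low Pain → High Pain → Clinically Severe Pain (VAS ≥ 6 and SF-36 items
   21 + 22 ≥ 10): 2 points for stepwise order, 4 if one-way ANOVA p < 0.05,
   6 if Bonferroni-significant over the biomarkers tested.
4. **Testing (0–8 points per outcome).** In an independent cohort, markers
   (risk-oriented z-scores; panels as Σz(increased) − Σz(decreased)) predict
   *state* (High-Pain visit; ROC AUC with one-sided Mann-Whitney p, one-tail
   t and Pearson) and *trait* (future emergency-department pain visits:
   first-year with Cox regression censored at 365 days, all-years with a
   logistic odds ratio per z and Cox censored at the last clinical note),
   cross-sectionally and longitudinally (last level, max level, last slope,
   max slope composite), in all subjects and stratified by gender and
   gender × diagnosis (PSYCHOSIS = SZ ∪ SZA).
5. **–6. CFE tabulation.** Convergent Functional Evidence per biomarker:
   discovery + CFG + validation + 8/6/4 points per testing outcome by the
   best stratum level at which it predicts (all / gender / gender × dx).
   Maximum 48 = 36 empirical + 12 literature (3 : 1 weighting).

## Worked example

```python
import painmarkers as pm

cfg = pm.SimConfig(n_subjects=40, n_probesets=300, n_algogenes=20,
                   n_suppressors=20, effect_size=2.0,
                   p_severe_given_high=0.4, seed=11)
cohort = pm.generate_cohort(cfg)
res = pm.BiomarkerStudy(cohort.visits, cohort.bundle,
                        followup=cohort.followup).fit()
print(res.summary(top=5))
```

prints

```
Blood biomarker study for pain — convergent evidence summary
==============================================================
Subjects: 40   Visits: 130   Probesets: 300
Discovery rows: 600   Carried to validation: 39   Long list: 39   Validated (nominal): 39

Top 5 biomarkers by CFE score (max 48):
 rank probeset_id  discovery_points  cfg_points  validation_points  state_points  trait_year1_points  trait_all_points  total
    1     PS00058                 6         0.0                  6             8                   6                 8   34.0
    2     PS00156                 6         0.0                  6             8                   6                 8   34.0
    3     PS00240                 6         0.0                  6             8                   6                 8   34.0
    4     PS00064                 6         0.0                  6             8                   4                 8   32.0
    5     PS00072                 6         0.0                  6             8                   6                 6   32.0
```

Every top-ranked probeset here is one of the 40 planted markers: each earns
the full discovery score (concordant in ≥ 80% of within-subject
comparisons), the stepwise-validation maximum, and predicts High-Pain state
in all subjects (8 points). CFG points are 0 because no literature-evidence
table was supplied; totals therefore top out at 36.

The same run is available from the shell:

```bash
painmarkers simulate --seed 11 --n-subjects 40 --out cohort/
painmarkers run-all --visits cohort/visits.tsv --expr cohort/expression.tsv \
    --calls cohort/calls.tsv --followup cohort/followup.tsv --out out/
```

with per-stage subcommands (`discover`, `prioritize`, `validate`, `cfe`)
for running steps individually on TSV artifacts.

## Acceptance script

`scripts/acceptance.py` recomputes the scoring scheme's headline quantities
by executing the package: the maximum combined discovery + CFG score, the
maximum CFE total, the points awarded to a fully concordant probeset scored
over ten constructed within-subject comparisons, the numeric encoding of a
Marginal detection call, the testing points for an all-subjects prediction,
and the CFE totals rebuilt from the per-step outcomes of two reference
biomarker rows. Run it from the repository root:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
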