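# dspscore

Tools for building and evaluating the **Difficult Spinal-Arachnoid Puncture
(DSP) Score**, a three-item bedside risk score for predicting difficult
spinal-arachnoid puncture procedures (spinal anesthesia, diagnostic lumbar
puncture, lumbar drainage).

A procedure counts as *difficult* when the performer needed more than three
punctures, needed three punctures with more than six needle passes, or
handed the procedure over after the second puncture while deeming it
difficult. The score predicts that outcome from three things an
anesthesiologist can assess at the bedside:

| Predictor | Levels | Points |
|---|---|---|
| Spine grade (palpability of spinous processes/interspaces) | 1 / 2 / 3 / 4 | 0 / 1 / 2 / 3 |
| Performer experience | ≤ 12 months / > 12 months | 1 / 0 |
| Positioning difficulty | absent / present | 0 / 3 |

yielding an aggregate score of 0–7. The weights are not hand-picked: they
are derived mechanically from model coefficient estimates (−2.715 for spine
grade, −2.98 for positioning difficulty, +1.045 for experience, all with
Pr(>|z|) < 0.01) by keeping significant predictors, rounding |estimate| to
the nearest integer as the maximum weight, and orienting the weights by the
coefficient's sign. `dspscore` implements that construction rule for
arbitrary coefficient tables, not just the built-in one.

The package is aimed at clinical researchers who want to (a) apply the DSP
Score to their own procedure logs, (b) evaluate any integer risk score as a
diagnostic test — ROC/AUC, Youden's J cutoff, prevalence-weighted
efficiency `eff(c; P) = P·sens(c) + (1−P)·spec(c)`, and the full 2×2
statistics panel (sensitivity, specificity, likelihood ratios,
prevalence-adjusted predictive values, accuracy) with exact-binomial,
log-method and logit-method confidence intervals — and (c) stress-test the
pipeline on reconstructed or simulated cohorts when no raw data are
available.

## Worked example

The 300-procedure derivation cohort was never deposited, but its per-group
score distribution is identifiable from the published per-cutoff operating
points; `dspscore reconstruct` rebuilds it and `dspscore evaluate` runs the
whole analysis:

```bash
dspscore reconstruct --out index.csv
dspscore evaluate index.csv --prevalence 0.18
```

prints

```
Operating points (positive: score >= cutoff)
 cutoff    sens    spec
      1   1.000   0.000
      2   0.981   0.565
      3   0.481   0.967
      4   0.037   1.000
      5   0.000   1.000
AUC 0.863 (95% CI 0.798-0.927)
Youden's J point: cutoff 2 (J = 0.547)

Efficiency-optimal cutoffs
     P  cutoff    sens    spec
  0.01       4   0.037   1.000
  0.05       4   0.037   1.000
  0.10       3   0.481   0.967
  0.20       3   0.481   0.967
  0.30       3   0.481   0.967
  0.50       2   0.981   0.565

Diagnostic statistics at cutoff 2:
Category         Difficult      Easy
score >= cut            53       107
score <  cut             1       139

Statistic     Value (95% CI)
Sensitivity   98.15%  (90.11-99.95%)
Specificity   56.50%  (50.06-62.79%)
PLR           2.26  (1.95-2.61)
NLR           0.03  (0.00-0.23)
Prevalence    18.00%
PPV           33.12%  (29.95-36.46%)
NPV           99.29%  (95.21-99.90%)
Accuracy      64.00%  (58.88-69.12%)
```

Reading: at the Youden-optimal cutoff of 2, a score ≥ 2 flags a difficult
puncture with 98% sensitivity but only 57% specificity — a screening
posture; in an 18%-prevalence population a score < 2 all but rules
difficulty out (NPV 99.3%), while a positive flag is right about one time
in three (PPV 33%). Raising the cutoff to 3 trades sensitivity for 97%
specificity, which is why the efficiency criterion prefers cutoff 3–4 at
low prevalence. The AUC of 0.86 reflects the score's overall
discrimination.

The same commands run on your own data: a CSV with columns `spine_grade`
(1–4), `experience` (`<=12mo`/`>12mo`), `positioning_difficulty`
(true/false) and, for evaluation, `punctures`, `passes`,
`handover_declared_difficult`. `dspscore score` appends a `dsp_score`
column; `dspscore simulate` generates fully synthetic cohorts from a
seeded latent logistic model.

Everything is also available as a library:

```python
import dspscore as d

cohort = d.index_cohort()                      # or d.read_cohort("my.csv")
scores = [d.compute_dsp_score(r) for r in cohort]
labels = [r.difficult for r in cohort]
curve = d.roc_from_scores(scores, labels)
cutoff, j = d.youden_optimal_cutoff(curve)
report = d.diagnostic_report(d.build_two_by_two(scores, labels, cutoff), 0.18)
```

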