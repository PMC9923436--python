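# Methods

## The DSP Score and its construction rule

The DSP Score is an additive integer score over three predictors of a
difficult spinal-arachnoid puncture: spine grade (a four-level palpability
grading of the spinous processes and interspaces), performer experience
dichotomized at 12 months, and positioning difficulty. `dspscore` does not
hard-code the weight table; it rebuilds it from the underlying coefficient
estimates by a mechanical three-step rule implemented in
`score_model.build_score_from_coefficients`:

1. **Filter.** Keep predictors with `Pr(>|z|)` strictly below the
   significance threshold (0.01 for the built-in model).
2. **Magnitude.** Each retained predictor's maximum weight is `|estimate|`
   rounded to the nearest integer, half away from zero. (Half-to-even
   would differ only at exact .5, which does not arise for the built-in
   estimates 2.715, 2.98, 1.045; the choice is documented because a user
   supplied table could hit it.) A weight that rounds to 0 is rejected:
   the predictor would be retained but carry no points, which signals a
   mis-scaled coefficient table.
3. **Direction.** A negative estimate puts rising weights on rising
   levels; a positive one reverses them. For ordinal predictors the
   weights are the linear integers `0..max` over the level order, which is
   only well defined when `max = n_levels − 1` (true for spine grade,
   3 = 4 − 1); any other combination is rejected rather than silently
   interpolated, since no published rule covers it. For binary predictors
   the weights are `{0, max}`; an explicit `max_weight_levels` override
   lets the caller pin the scored level when the sign convention of their
   coefficient table differs.

The builder applied to the built-in coefficient table reproduces the
published weights (spine grade 0/1/2/3, positioning difficulty 0/3,
experience 1/0) and the 0–7 range; this is asserted in the tests rather
than assumed.

## Outcome definition

`cohort_io.classify_difficult` encodes the difficult-procedure definition:
more than three punctures, or exactly three punctures with more than six
passes, or a handover after the second puncture with the performer deeming
the procedure difficult. The handover clause is an explicit boolean on the
record — no per-performer log format exists from which it could be
inferred. `passes >= punctures` is enforced (each puncture involves at
least one pass). The classifier is monotone in both counts, a property
the suite checks exhaustively over a grid of escalations.

## Diagnostic statistics and interval methods

Positivity is **score ≥ cutoff** throughout. The published 2×2 table
labels its rows ">2"/"<2", yet its four cells partition all 300 records
and give sensitivity 53/54 at cutoff 2 — arithmetic only consistent with a
≥2 vs <2 split — so the row labels are treated as typographical shorthand
for that split.

Point estimates follow the standard definitions; PPV, NPV and accuracy are
*prevalence-adjusted* via Bayes' theorem so they can be quoted for a
stated prevalence (18% for the index analysis) rather than the sample's.
When the supplied prevalence equals the sample's own, the adjusted values
reduce exactly to `tp/(tp+fp)`, `tn/(tn+fn)` and `(tp+tn)/total`; this
identity is property-tested on random tables.

Interval methods (95% default, z = 1.959964, exact beta quantiles for the
binomial):

- **Sensitivity, specificity** — Clopper-Pearson exact binomial (via
  `statsmodels`' beta-quantile implementation).
- **PLR, NLR** — the log method: a normal interval on `ln(LR)` with
  variance `1/tp − 1/(tp+fn) + 1/fp − 1/(fp+tn)` (fn/tn analogue for the
  NLR). No continuity correction: zero cells propagate to 0 or ∞
  endpoints carrying an `unbounded` flag instead of a 0.5 substitution.
- **Adjusted PPV/NPV** — the logit method: since
  `logit(PPV) = logit(p) + ln(PLR)`, the interval is a normal interval on
  the logit with the same variance as the corresponding log-LR, mapped
  back through the inverse logit. Recomputing the published intervals
  with these two methods reproduces all four printed CI pairs to the
  printed 2 decimals, which is how the methods were identified (the
  source analysis names its calculator but not its formulas).
- **Accuracy** — delta method on `p·sens + (1−p)·spec` with independent
  binomial variances. This yields 58.88–69.12% on the index table, close
  to but not matching the published 58.28–69.44%; the calculator's
  formula for this one interval could not be identified, so the accuracy
  CI is a documented package choice and is not asserted against print.
- **AUC** — Hanley-McNeil variance approximation, reported for
  orientation only (see below).

## ROC, Youden's J and efficiency

Candidate cutoffs are the distinct observed scores plus one past the
maximum, so the curve always spans (sens 1, spec 0) to (sens 0, spec 1).
The AUC is the trapezoid over the vertices `(1−spec, sens)` with (0,0) and
(1,1) anchors; for integer scores this equals the Mann-Whitney two-sample
statistic with half credit for ties, an identity the suite verifies
exactly against a brute-force pair-enumeration oracle and cross-checks
against scikit-learn.

Cutoff selection maximizes either Youden's `J(c) = sens + spec − 1` or the
efficiency `eff(c; P) = P·sens + (1−P)·spec`, the expected fraction
correctly classified at prevalence P. Ties break toward the smaller
cutoff (the published grids contain no ties; a rule is needed regardless).
Two algebraic properties serve as invariants: at P = 0.5 the two criteria
select the same cutoff, and the efficiency-optimal cutoff is
non-increasing in P.

## Reconstructing the index cohort

The derivation cohort (300 procedures, 54 difficult) was published only as
summary tables, but the grouped score distribution is identifiable from
them. With group sizes 54/246 and sensitivity/specificity printed to 3
decimals at cutoffs 2, 3, 4, the counts `round(n·sens(c))` (and
`round(n·spec(c))` below-cutoff for the easy group) are unique — each
implied count reproduces the printed 3-decimal value on re-division, a
consistency check `reconstruction` enforces and would fail loudly on
inconsistent inputs. Differencing gives the bins

    difficult (<2, =2, =3, >=4): 1, 27, 24, 2
    easy:                        139, 99, 8, 0

Only the `<2` bin's internal 0-vs-1 composition is unidentifiable.
Expansion to individual records places it at score 1 by default (the rule
is a parameter); the choice moves the AUC only in the third decimal, which
is why the recomputed AUC (0.863 by trapezoid/tied-rank) is compared to
the published 0.858 with a ±0.01 band instead of asserting equality —
the source's online calculator's exact tie handling is also unknown.
Expanded records carry a deterministic predictor combination realizing
their score under the model and a deterministic outcome consistent with
their group; the expansion makes no attempt to reproduce the joint
distribution of the remaining covariates, which the marginals do not
identify.

## The synthetic cohort generator

`synthetic_data.simulate_cohort` emulates the index cohort's structure for
testing at arbitrary n:

- **Predictor marginals** default to the cohort's pooled frequencies:
  spine grades 95/148/52/5 of 300, experience ≤12 months 196/300,
  positioning difficulty 12/300. Predictors are drawn independently — the
  joint distribution was never published; this is a deliberate
  simplification.
- **Latent outcome.** `logit P(difficult) = b0 + 0.905·(grade−1) +
  1.045·junior + 2.98·positioning`. Slope signs and magnitudes reuse the
  published estimates (the full grade range contributes 2.715 log-odds);
  the intercept is calibrated by root bracketing so the exact expectation
  over the 16-cell predictor lattice equals the 18% target prevalence to
  1e-6.
- **Outcome counts** are drawn consistently with the label: easy
  procedures use 1–3 punctures and at most 6 passes; difficult ones mix
  many-puncture (60%), three-puncture/many-pass (25%) and handover (15%)
  presentations. Any mixture satisfying the classifier would do; these
  defaults keep all three clauses of the definition exercised.
- **Demographics** (age, sex, height/weight/BMI, ASA class, …) are drawn
  from simple distributions matched to the cohort's summary table and
  carry no outcome signal; they exist so I/O and summarization paths see
  realistic records, and can be switched off for large-n runs.

All randomness flows from one `numpy` generator per cohort, seeded from
the config; identical configs give identical cohorts.

What passing simulation tests show — and what they do not: the generator
validates calibration, determinism, scoring and evaluation plumbing, and
that a logistic refit at n = 1e5 recovers the latent slopes within 3 SE.
It does not validate the score against real patients: real predictors are
correlated (grade with BMI, experience with case mix), prevalence varies
by site, and the latent model is exactly the functional form the score
assumes, so simulated discrimination is optimistic by construction.

## Problem sizes and numerical choices

The suite's stochastic checks use 200 replicates of n = 300 for the
prevalence check (±0.05 band on the mean), n = 1e4 for the null-effect
check and a single n = 1e5 cohort for coefficient recovery — sizes at
which the checks are decisive while the full suite stays fast. Monte-Carlo
tests fix their seeds; hypothesis-based property tests run derandomized.
Degenerate inputs (single-class labels, empty tables, zero cells,
unreachable target prevalence) raise typed errors rather than returning
NaNs, except where a statistic is conventionally reported as unbounded
(PLR with specificity 1), which is flagged.

## Known limitations

- The reconstruction reproduces the published grouped distribution, not
  the raw cohort; covariates other than the three predictors are not
  reconstructable.
- The accuracy CI method differs from the (unidentified) one behind the
  published interval.
- The score builder's ordinal rule requires `max weight = n_levels − 1`;
  coefficient tables violating that need manual weight specification via
  the JSON model format.
- Simulated cohorts assume independent predictors and a correctly
  specified logistic link.
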