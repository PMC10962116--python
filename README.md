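# triowa

Outcome-wide triangulation of observational and polygenic-score analyses.

## The problem

Retrospective self-reports of an early-life exposure — here, childhood
maltreatment measured by five 1–5 screener items — are vulnerable to
unmeasured confounding (e.g. childhood socioeconomic position) and recall
bias. A polygenic risk score (PRS) for the same exposure is free of those
biases but carries different ones: weak-instrument attenuation, residual
population stratification, and horizontal pleiotropy. Running the *same*
outcome-wide scan with both exposure measures in non-overlapping samples
and comparing the results per outcome ("triangulation") turns the
disagreement structure itself into evidence: concordant signals are
unlikely to be artifacts of either bias family.

`triowa` implements that design as a tested, reusable pipeline:

- **Observational arm** — the five items are dichotomized at per-item
  cut-offs and summed to a count variable with levels 0 (reference),
  1, 2, 3, 4–5. Each outcome *Y* is screened (prevalence > 1%,
  missingness ≤ 40%) and dispatched by type: continuous outcomes are
  z-scored and fit by OLS (β per count level); binary outcomes with
  prevalence < 10% by logistic regression (OR); binary outcomes with
  prevalence ≥ 10% by **modified Poisson regression** — log-link Poisson
  with an HC1 sandwich variance — giving risk ratios; categorical outcomes
  by baseline-category multinomial logit (an ordinal model is avoided when
  the Brant–Wald check rejects proportional odds). Per-level contrasts and
  a test of trend (count scored 0–4) are estimated with the full covariate
  roster, overall and sex-stratified, with Benjamini–Hochberg FDR applied
  separately per contrast family.
- **Missing data** — covariates and rare "prefer not to say" item
  responses are multiply imputed by chained equations (predictive mean
  matching for numerics, logistic/polytomous draws for categoricals;
  m = 10, 10 iterations by default) and estimates are pooled by Rubin's
  rules: pooled variance `T = W̄ + (1 + 1/m)·B` with Barnard–Rubin
  degrees of freedom.
- **E-value layer** — for an association on the risk-ratio scale,
  `E = RR + √(RR·(RR − 1))` is the minimum exposure–confounder and
  confounder–outcome association strength needed to explain it away. The
  CI E-value applies the formula to the confidence limit closest to the
  null; an association is flagged *robust* when its CI E-value exceeds the
  magnitude of a benchmark covariate coefficient (maternal smoking at
  birth, a childhood-SES proxy), or — for β-scale outcomes, converted via
  `RR ≈ exp(0.91·β)` — when it reaches the top half of all CI E-values.
- **Genetic arm** — variants pass QC (MAF > 0.01, HWE p > 1e−10,
  info > 0.8), are greedily LD-clumped (R² ≥ 0.1 within 250 kb, ascending
  p), and scored at thresholds p < 5e−8 and p < 0.5 as Σⱼ β̂ⱼ·dosageᵢⱼ
  with allele alignment; the standardized score (and its quintiles)
  replaces the count in the same scan, adjusted for birth year, sex,
  sequencing array and the top 20 dosage principal components.
- **Triangulation** — per outcome, the observational trend and the
  per-SD genetic estimate are joined and classified:
  concordant-significant, observational-only, genetic-only, neither, or
  discordant (both significant, opposite directions), with the robustness
  flag overlaid and summaries by health theme.
- **Synthetic cohort generator** — a liability-threshold simulator with
  LD-structured genotypes, known confounding/pleiotropy structure and a
  hidden truth channel, so every stage (and the capstone three-group
  triangulation experiment) is testable without restricted biobank data.

## Worked example

```python
from triowa import ci_evalue, evalue_from_rr
round(evalue_from_rr(1.57), 2)    # 2.52  — point E-value for OR 1.57
round(ci_evalue(1.57, 1.53, 1.62), 2)   # 2.43 — at the lower 95% limit
ci_evalue(1.05, 0.98, 1.12)       # 1.0  — CI crosses the null
```

An association of OR 1.57 (95% CI 1.53–1.62) would need an unmeasured
confounder associated with both exposure and outcome at risk ratios of at
least 2.43 before even its interval could be moved onto the null.

A full scan (see `examples/03_observational_scan.py`) prints, for a
simulated catalog with planted effects:

```
outcome            family           scale estimate           95% CI        q
quality_of_life    linear           beta    -0.102  (-0.142,-0.062)   0.0000
rare_diagnosis     logistic         OR       1.312    (1.131,1.520)   0.0004
common_condition   modified-poisson RR       1.134    (1.076,1.195)   0.0000
unrelated_trait    linear           beta     0.018   (-0.022,0.059)   0.3713
```

Each estimate is per unit of the 0–4 count score on its family's scale;
`q` is the BH-adjusted p-value within the trend contrast family. The
planted effects (−0.1 SD, log-OR 0.25, log-RR 0.12, null) are recovered
and only the null outcome fails the FDR cut. The other scripts in
`examples/` walk through simulation, imputation/pooling, E-values,
polygenic scoring, and the end-to-end triangulation study.

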