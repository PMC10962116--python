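# Methods

This note documents the models, defaults and numerical choices behind
`triowa`, and what the synthetic studies do and do not establish.

## Synthetic cohort model

**Genotypes.** Biallelic dosages in equicorrelated LD blocks: within a
block, a Gaussian copula with target correlation `ld_rho` drives all
variants; each latent value is cut at the Hardy–Weinberg thresholds for the
variant's allele frequency (drawn uniformly from `maf_range`), yielding
dosages 0/1/2 with probabilities ((1−p)², 2p(1−p), p²). Thresholding
attenuates correlation, so each variant's loading on the block factor is
inflated by the analytic attenuation factor
`a = (φ(t₀)+φ(t₁))/√(2p(1−p))` (capped at loading 1); the realized
*dosage* correlation then approximates `ld_rho`. Blocks sit 1 Mb apart
(5 kb within), making LD strictly block-local — sufficient for clumping
semantics, deliberately nothing like a human LD map. Causal liability
effects go to `n_causal` variants, one per block round-robin, scaled so the
raw genetic score has unit variance.

**Exposure.** A liability
`L = √h²·S + Σ c_k·x̃_k + ε`, standardized to unit total variance, where
`S` is the standardized genetic score, the `x̃_k` are standardized
covariates (plus a *hidden* confounder `u` that no analysis sees), and ε
fills the remaining variance (floor 0.05). Each of five ordinal items is
`L + σ_item·noise` cut at four ordered thresholds. Default thresholds are
set from target dichotomized type prevalences (9.5%, 5.5%, 4%, 6.5%, 3%)
so the count distribution resembles a population screener: ~80% zeros and
a rare top category. The default item noise SD (1.3) keeps items only
moderately correlated so the types are nearly disjoint. Item marginal
distributions are configurable, not matched to any particular instrument;
the dichotomization cut-offs are likewise mandatory configuration (default
score ≥ 3 on every item) and carry no claim of clinical validation.

**Outcomes.** The generating exposure is the five-level count category
scored 0–4 (counts 4 and 5 share the top level, matching the analysis
coding — this makes the trend model correctly specified and parameter
recovery well-defined). Linear predictors add confounder loadings and an
optional direct genetic-score effect (horizontal pleiotropy). Links:
identity + N(0,1) noise for continuous outcomes; logit or log for binary
(intercept solved by bisection to hit the target prevalence; log-link
probabilities capped at 0.99); baseline-category logit for categoricals.

**Missingness.** Covariate MAR: the per-cell deletion probability is the
target rate times a logistic weight in observed age and sex, renormalized
to preserve the marginal rate. Items get a distinct "prefer not to say"
sentinel (not plain missing) at a sub-1% rate. Originals are retained in a
truth channel so tests never re-run generators.

## Imputation

Chained equations, variables visited in ascending missingness order, m
chains run independently from random observed-margin starts. Numeric
variables: type-1 predictive mean matching — observed cases matched on
OLS fitted means, missing cases on means under a Bayesian draw
β* ~ N(β̂, σ̂²(XᵀX)⁻¹); the donor pool is the k = 5 nearest observed
predictions and one donor is drawn uniformly, so imputed values are always
observed values. Binary variables: Bernoulli draws from a
ridge-stabilized (λ = 1e−6) Newton logistic fit with a coefficient draw.
Multi-level categoricals: renormalized one-vs-rest logistic probabilities
without a coefficient draw — a pragmatic simplification; categorical
covariates here carry little missingness, and its main cost is slight
understatement of between-imputation variance for those variables.
Defaults m = 10, 10 iterations (reduced-scale studies use m = 5, 5).

Pooling follows Rubin's rules on the link scale (β, log-OR, log-RR), with
Barnard–Rubin degrees of freedom when a complete-data df is supplied and
the classic `(m−1)/λ²` otherwise; ratio estimates are exponentiated after
pooling, and intervals/p-values use the t reference with the pooled df.
Whether to pool or stack imputed data was an open design choice; pooling
was chosen for the normality of the link-scale estimator. Per-dataset fits
that degenerate numerically (separation; runaway log-link cells — detected
as link-scale SE > 50) are dropped from pooling; a record is flagged
non-converged when most of its fits degenerate, and flagged records are
excluded from the FDR enumeration with a logged count.

## Observational scan

Family dispatch is a pure function of declared type and prevalence, with
the ≥ 10% boundary sent to modified Poisson and prevalence computed on the
analytic (post-screening, pre-imputation) sample. The sandwich flavour is
HC1. Continuous outcomes are z-scored *within each imputed dataset* to
avoid leaking moments across imputations. The trend codes category 4–5 as
4. The multinomial reference level is the most frequent category.
BH correction runs separately per (contrast, stratum) family; categorical
outcomes contribute one test per non-reference outcome level, so a catalog
enumerates to slightly more tests than outcomes (the enumeration is
returned with the results). The proportional-odds check is a Brant-style
Wald test treating the cumulative splits as independent — conservative,
adequate for its advisory role.

## E-values and robustness

`E = RR + √(RR(RR−1))` for RR ≥ 1, reciprocal first otherwise; the CI
E-value uses the limit closest to the null and is 1 when the interval
contains it. Odds ratios from logistic fits enter the formula as-is (no
rare-outcome square-root conversion) — this is the operative convention of
the results being reproduced, and the printed values confirm it. β-scale
estimates are converted by `RR ≈ exp(0.91·β)` before the formula; exact
reproduction of published continuous-outcome E-values from *rounded*
printed limits can differ by ±0.02, a documented tolerance rather than an
error. The benchmark comparison uses strict `>` against
`max(b, 1/b)`; "top 50th percentile" is read inclusively (≥ median, ties
robust). A CI E-value of 1 is never robust.

## Polygenic score

QC comparisons are strict inequalities (a variant with info exactly 0.8
fails). Clumping estimates R² as the squared Pearson correlation of
dosages in the scoring sample itself (no external reference panel);
p-value ties break by genomic position, so the greedy pass is
deterministic. Scores count the summary-statistics effect allele, flipping
`d → 2−d` when the panel counts the other allele, which makes raw scores
invariant to panel orientation; unresolvable allele mismatches drop the
variant with a warning. Standardization is computed within the scoring
sample; quintiles are rank-based on the raw score with stable tie-breaking
(bin sizes never differ by more than one). Principal components come from
the column-standardized dosage matrix without LD pruning (block-local
synthetic LD makes pruning unnecessary), with signs fixed by the
largest-magnitude loading. The genetic scan reuses the observational
family dispatch for symmetry; the regression family per outcome in the
genetic arm was not otherwise pinned down, and this assumption is logged
here. The sequencing array covariate is a random binary batch label,
included to exercise the covariate plumbing.

## Triangulation

"Significant" means FDR-rejected within each arm separately (a raw-p
switch exists via each arm's settings). Direction is the sign of the
link-scale estimate, so protective ratios compare correctly. Outcomes
present in only one arm are reported as unjoined, never forced into a
category.

## Designed studies and their scales

`studies.py` freezes three reduced-scale study definitions used by the
acceptance tests; their sizes were chosen so the full suite runs on a
laptop-class single core in minutes.

- **Triangulation study**: 3,000 observational + 20,000 genetic
  individuals (non-overlapping, the genetic sample larger as in the
  two-arm biobank design), 200 variants in 50 blocks, liability
  h² = 0.25, discovery GWAS n = 200,000. Planted groups: 10 true-effect
  outcomes (0.25 SD per count level), 10 outcomes loading 0.50 SD on the
  hidden confounder, 5 outcomes with a 0.05 SD direct genetic-score
  effect. These constants target ~90% power in the arm meant to detect
  each group while the leakage path (the genetic correlate of the count
  for pleiotropic outcomes, and vice versa) stays below the FDR cut; they
  are part of the study definition, not tuning knobs.
- **Recovery study**: n = 10,000, per-count effects of 0.1 (β, log-OR on
  a 5% outcome, log-RR on a 30% outcome), 20% MAR missingness on two
  covariates, m = 5. Its item thresholds use richer type prevalences
  (15–25%) than the screener-emulating defaults: a CI-calibration study
  needs the count to carry real information at this scale, and with the
  rare-top-category defaults the rare-outcome trend would rest on a
  handful of events, putting Wald intervals outside their asymptotic
  regime for reasons unrelated to the machinery under test.
- **Null-FDR study**: 20 pure-noise outcomes at n = 400 per seed; with
  all-null catalogs the false-discovery proportion is 1 exactly when
  anything is rejected, so its mean over seeds estimates the BH FDR.

**What passing does and does not show.** The generator reproduces the
*structure* of a biobank maltreatment study (mixed outcome families,
skewed ordinal exposure, MAR covariates, sub-1% PNS, LD-blocked
genotypes, confounding vs pleiotropy) but not real LD maps, ancestry
structure, relatedness, imputation-quality variation, or the marginal
distributions of any particular instrument. Tests therefore validate the
statistical machinery and the triangulation logic, not substantive claims
about real cohorts.

## Known limitations

Multilevel imputation, imputation diagnostics beyond the convergence
trace, Mendelian-randomization estimators, external LD reference panels,
non-additive scores, time-to-event models and formal cross-design effect
combination are out of scope. The polytomous imputation model draws no
coefficient uncertainty. X-chromosome and admixture are not simulated.
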