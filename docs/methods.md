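# Methods

## The effective-coverage cascade

For each RMNCH service the package models coverage as an ordered sequence
of conditional stages over a service-specific target population:

1. **service contact** — reached a relevant provider;
2. **crude coverage** — received the intervention;
3. **quality-adjusted coverage** — received it according to recommended
   standards;
4. **user-adherence-adjusted coverage** — received it to standard *and*
   followed the guideline.

Each stage is, by definition, conditional on the previous one, so stage
coverages are non-increasing. The built-in registry fixes the stage depth
per service at what household surveys measure consistently: delivery care
and ITN use stop at crude coverage, family planning and postnatal care at
quality, and ANC, immunisation and diarrhoea treatment run all four
stages. Stage predicates are conjunctions over pre-derived boolean fields
in the canonical CSV; deriving those booleans from raw questionnaire items
(skilled-provider lists, vaccine-card parsing, the PNC rule that counts
SBA-attended births as PNC contact) is upstream data preparation, outside
this package's scope.

Raw indicators are stored unconditionally and nesting is enforced at
estimation time by cumulative conjunction, because real survey data
contain skip-pattern inconsistencies; each repaired record-stage is
counted and logged. A missing raw indicator at any required stage makes
the nested indicator missing at that and deeper stages rather than
guessing either way. Conditional retention `100·p_{k+1}/p_k` is flagged
undefined (not 0 or 100) when the upstream coverage is zero. Losses and
retentions are carried at full precision; rounding (1 decimal for
percentages and percentage points, 2 for indices) happens only when
tables are written.

## Design-based estimation

Records carry a stratum id, a PSU id and a positive sampling weight.
Proportions use the Hajek ratio `Σwx/Σw`; its variance comes from Taylor
linearisation of the ratio estimator — linearised scores
`z_i = w_i(x_i − p)/ΣW` are totalled by PSU and contrasted within strata
with the usual `n_h/(n_h − 1)` factor. Replication methods (jackknife,
BRR), finite-population corrections and calibration are out of scope.

Decisions taken where the convention is genuinely open:

* **Single-PSU strata** default to centring the lone PSU total at the
  grand mean (with a logged warning) so sparse strata do not abort an
  analysis; a strict `error` policy is available.
* **Confidence intervals** are normal-score by default, truncated to
  [0, 1] for proportions; a t option with `n_psu − n_strata` degrees of
  freedom exists but is off by default.
* **Pooling** across countries first rescales each country's normalized
  weights to an external population total (so countries contribute by
  population), then namespaces stratum/PSU ids by country so clusters
  never merge.

The simulation calibration study (500 replicates of a 20-stratum,
100-PSU, n = 2,000 clustered design with cluster-level outcome shifts of
±0.1) is the package's check that these choices give 93–97% coverage for
the nominal 95% interval.

## Inequality measures

The ridit score of ordered group *g* is the midpoint of its cumulative
weighted population-share interval, `r_g = F(g−) + p_g/2`; the weighted
mean of assigned scores is exactly 0.5. Ridits are recomputed **within
each analysis sample** (each service's target population) with weighted
group shares — each outcome has a different target population, so a
single global ranking would be wrong for all of them. Whether group
shares should be weighted is not a settled convention; weighted is used
here as the design-consistent choice.

* **RII** comes from a Poisson working model with log link — the standard
  way to estimate risk ratios for common binary outcomes, where
  log-binomial models routinely fail — fitted by weighted estimating
  equations with a robust sandwich clustered at the PSU. `RII = exp(β̂)`
  with its CI from the log-scale Wald interval; the SE field is the
  delta-method SE on the RII scale.
* **SII** is the ridit coefficient from the identity-link Poisson fit
  (started at the weighted least-squares solution). Identity-link Poisson
  on binary data can leave the parameter space; the documented fallback
  is the survey-weighted linear probability fit with the same clustered
  variance, flagged via `link="linear_probability"` in the result —
  never silently.
* **Erreygers' index** is `E = 8·cov_w(y, r)` for binary outcomes — the
  bounded-outcome normalisation of the relative concentration index
  `C = 2·cov/μ` (equivalently `E = 4μC`), restoring the [−1, 1] range.
  No analytic variance is standard for survey data here, so the SE is a
  seeded clustered bootstrap: PSUs resampled with replacement within
  strata, 1,000 draws by default (200 in the pipeline for speed).
* The default adjustment set is age group, residence and parity; the
  stratifier is never included in its own adjustment set. No
  multiple-testing correction is applied.

Useful identities exploited by the test suite: with equal-size quintiles
and equal weights, `E = 8·var(r)·slope = 0.64·slope` (quintile midpoints
have variance 0.08); reversing ranks flips E's sign exactly; under a
log-link data-generating process the marginal RII at stage *k* is
`exp(Σ_{j≤k} β_j)`, so relative inequality mechanically accumulates along
a cascade whose stage gradients are all positive.

## The synthetic-data generator

The generator emulates the features of multi-country DHS microdata that
the estimators are sensitive to: stratified two-stage cluster sampling
(strata → PSUs → individuals), a latent socioeconomic score with a
cluster-level Normal intercept (defaults: cluster SD 0.5, individual SD
1.0, ICC ≈ 0.2) cut into weighted within-country wealth quintiles,
wholly-urban-or-rural clusters (40% urban by default), categorical
covariates, positive sampling weights with mean 1 per country
(Gamma(shape = 10) draws rescaled; the within-country weight distribution
of real surveys is not standardised, so this mild right-skew is a
modelling choice), and per-service cascades generated stage by stage from
`P(stage k | stage k−1) = exp(α_k + β_k r + γ_k'z)`.

Three properties make it an oracle rather than a fixture:

* the generative link equals the RII's estimating link, so `exp(β_k)` is
  the exact conditional truth and parameter recovery is a sharp test;
* probabilities are never clipped — a truth whose probabilities could
  exceed 1 is rejected at validation (checked at ridit 0 and 1 and the
  most favourable covariate pattern), because clipping would bias the
  truth silently;
* `true_stage_coverage` returns the exact marginal coverage by summing
  the product of conditional probabilities over the discrete
  (quintile ridit × covariate pattern) distribution.

Eligibility is independent of SES by default, with an optional logit
slope knob to study selection effects separately. Covariates (and
education) are drawn independently of the latent SES; consequently
wealth-based gradients have known truth while education-based analyses
exercise only the mechanics. Missingness is injected completely at
random per covariate field.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: informative (non-MCAR) missingness,
eligibility correlated with unobserved need, measurement error and recall
bias in stage indicators, non-response weight adjustments, household
rosters with multiple eligible members, and education gradients driven by
the same latent score as wealth.

## Problem sizes and numerics

Recovery studies use one country of 25 strata × 10 PSUs × 200 individuals
(n = 50,000) over 200 seeded replicates — large enough that binomial
error is small against the 0.05 bias tolerance, small enough to keep the
whole suite in a few minutes. The default desk-scale dataset is 3
countries × 1,250 records. GLM fits use statsmodels' IRLS (max 200
iterations); non-convergence is flagged in the result, never raised
silently. Determinism everywhere: `numpy.random.default_rng` seeded from
the configuration, record order fixed by (country, stratum, PSU,
household, person), ties in the quintile cut broken by record order.

## Known limitations

* RII/SII variance clusters at the PSU but does not subtract
  within-stratum PSU means as the Taylor proportion does; with many PSUs
  per stratum the difference is negligible, but in tiny designs the
  regression SEs can differ from a full `svy`-style linearisation.
* The identity-link SII estimand under a non-linear truth differs
  slightly between the Poisson and the linear-probability weighting; the
  result records which link produced the estimate.
* League tables flag failed cells and carry on; they do not impute or
  suppress the remaining cells of a failed group.
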