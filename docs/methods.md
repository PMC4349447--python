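# Methods

## The analysis problem

`exwas` implements an exposome-wide association scan (ExWAS) for a single
continuous child outcome measured on a bounded checklist scale (feasible
range 126–232, higher = more typical) against thousands of correlated
questionnaire exposures collected before and during pregnancy.  The
analysis is hypothesis-free in the GWAS sense, but unlike genetic variants
the exposures are strongly and pervasively correlated, so a univariable
screen alone cannot separate candidate causes from their correlates.  The
pipeline therefore selects variables in three stages:

1. **Univariable screen.**  Each exposure, standardized to unit variance, is
   regressed on its own against the outcome.  Slopes are read as outcome
   points per 1 SD of exposure.  Multiplicity is controlled by the
   Benjamini–Hochberg step-up procedure at a stringent family-wide rate
   q = 0.001: sort the m p-values, find the largest i with p(i) ≤ i·q/m, and
   pass everything at or below p(i).  The criterion is *variable* — it spans
   q/m (the Bonferroni critical value, binding for the smallest p-value) up
   to q (the nominal level, binding for the largest) — and the operative
   threshold p(i*) is data-dependent.  That threshold is reused as the
   inclusion/removal criterion of every later stage.
2. **Domain-specific models.**  The survivors, grouped into ten thematic
   domains, are reduced by backwards-stepwise regression within each domain.
   This removes within-domain confounding (a domain model cannot, by
   construction, adjust for other domains — an accepted source of residual
   confounding at this stage, visible as attenuation of the weaker domain
   coefficients).
3. **Final model.**  The union of domain survivors is reduced once more, by
   default with best-subset search: the subset maximizing R² among subsets
   whose every member satisfies p ≤ p(i*) in the joint fit.  Forwards and
   backwards searches are available for comparison; their results seed the
   subset search, so the subset model's R² never falls below either.

Missing data are imputed between stages 1 and 2 by chained equations over
the stage-1 survivors; selection runs on the first completed dataset and the
selected model is then re-estimated on all M completed datasets and pooled
by Rubin's rules.  Probes of the final model (pairwise interactions,
quadratic terms, mediator adjustment, prevalence translation) and
sensitivity analyses (proportional-odds refit, factor-space selection,
CHAID-style tree, cross-method consistency) round out the analysis.

## Key parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `q` | 0.001 | family-wide FDR rate | stringent rate appropriate for thousands of correlated tests; identifies major factors by variance explained |
| `p_crit` | stage-1 threshold p(i*) | p-value | one criterion for inclusion/removal at every stage |
| `M`, `n_iter` | 5, 10 | imputations, cycles | conventional chained-equation settings; between-imputation variance is propagated by Rubin's rules |
| PMM donor pool | 5 | donors | preserves discreteness and feasible ranges of ordinal variables |
| `max_exhaustive` | 15 | candidates | exhaustive subset search is exact up to 2^15 subsets; larger pools use branch-and-bound with greedy incumbents |
| interaction / quadratic `p_crit` | 0.001 | p-value | matches the probe criterion used in this style of analysis |
| ordinal outcome bins | 20 | equal-frequency categories | near-continuous fidelity while keeping the proportional-odds fit estimable; halved on non-convergence |
| factor retention | eigenvalue > 1, varimax | — | the conventional default for questionnaire batteries; configurable |
| CHAID `alpha_split`, `min_leaf` | 0.001, 50 | p-value, subjects | Bonferroni-adjusted F-test splits for a continuous outcome; merging restricted to adjacent categories since predictors are ordinal after quintile pre-binning |

## The synthetic cohort

The original cohort data are access-restricted, so the package ships a
generator whose defaults define the study conditions used by the test suite
and the validation studies:

* 7600 subjects (the analysis-sample scale), 600 exposures in 10 domains;
* a Gaussian copula: latent multivariate normal with block-exchangeable
  correlation (0.3 within domain, 0.1 across), discretized per variable by
  quantile thresholds — one cutpoint for binary marginals (prevalences
  cycling over 0.25–0.75), 3–5 equal-frequency cutpoints for ordinal ones,
  identity for continuous ones; the type mix is 30% binary / 50% ordinal /
  20% continuous, questionnaire-like;
* 20 planted effects of 0.4–0.8 outcome points per exposure SD.  Effects are
  applied to the *population-standardized observed* columns, so "per SD"
  retains its meaning for discretized variables.  Consecutive magnitudes are
  paired within a domain (clustered risk factors of comparable strength,
  one sign per domain, signs alternating across domains so no global
  confounding direction dominates);
* outcome = 200 + planted signal (+ optional interaction products and
  mediator path) + sinh–arcsinh-skewed noise (skew −0.6, left tail), clipped
  to 126–232.  The noise SD (7.2 points) is calibrated so that the realized
  final-model R² of the default cohort sits at ≈13.4%, the total explanation
  scale this kind of scan reports; the implied total outcome SD (~7.7) is of
  the same order as checklist totals in cohort data (~9);
* 16% missing data points, MAR by default: a logistic model on the two fully
  observed "anchor" variables of each domain drives missingness, with the
  intercept solved by bisection so the realized rate matches the target.
  MCAR is available for calibration studies;
* 2% of subjects lack all partner-reported variables (~15% of columns),
  chosen uniformly at random.

Each dataset carries a `TruthRecord` sufficient to regenerate it
bit-identically and to score recovery.

**What the generator does not emulate:** longitudinal repeat measures,
instrument-specific responses or wording, outcome missingness (the outcome
is fully observed at desk scale, whereas the real analysis sample is roughly
half the imputation sample), MNAR mechanisms, and the long-tailed
correlation spectrum of a real questionnaire battery (the block-exchangeable
structure is a deliberate simplification; the spectrum of real exposome
correlations is unknown).  Passing recovery tests therefore demonstrates
that the *procedure* behaves as designed under controlled correlated
missing-data conditions, not that it would recover truth in any particular
real cohort.

## Partner-variable convention

Partner-reported answers of subjects without a partner are set to an
arbitrary fill value (default 0, the lowest feasible value) and flagged via
a convention mask; a partner-status indicator is then forced into every
model containing a filled partner variable, never counts against model size,
and is exempt from the significance filter.  The fill value is provably
immaterial: changing it shifts the partner columns by a multiple of the
status indicator, so all other coefficients and the fitted values are
unchanged (verified to 1e-10 in the suite).  Convention-filled cells are
*observed* for the imputation step.

## Imputation

Chained equations are implemented directly over a numpy Generator: Bayesian
linear regression (scaled inverse-χ² / normal posterior draws) for
continuous variables, logistic regression with an asymptotic posterior draw
for binary ones, and type-1 predictive-mean matching (donor pool 5) for
ordinal ones.  Variables cycle in order of increasing missingness; initial
values are sampled from each variable's observed margin.  The outcome joins
the chain as a predictor — standard practice, since omitting it biases
exposure–outcome associations toward zero — but the completed outcome column
is discarded: subjects without an observed outcome contribute to imputation
only.  Proper parameter draws make Rubin's total variance
(within + (1+1/M)·between, Barnard–Rubin degrees of freedom) honest; the
suite checks 95% pooled-interval coverage lands in [93, 97] under 20% MCAR.

## Numerical choices

* All subset/stepwise fits run through precomputed Gram matrices (columns
  centered once; the intercept is implicit), so a fit costs O(k³) regardless
  of sample size.  Cholesky solves, with a pivoted-screen fallback that
  reports aliased (collinear) variables rather than failing.
* Forwards selection performs an elimination sweep after each addition, so
  every member of a returned model satisfies the criterion — without the
  sweep, early entrants can drift above it.
* Ties on entry p-values break by candidate order and are recorded in the
  selection trace; replaying a trace reproduces the model.
* Best-subset search prunes a branch when the RSS of its full fit cannot
  beat the best admissible subset found; within the exhaustive regime this
  is provably exact, beyond it a node cap makes the search best-effort while
  the greedy incumbents guarantee it never returns less than forwards or
  backwards.
* p-values come from the t reference distribution throughout (exact at test
  scale, indistinguishable from normal at cohort scale).
* Zero p-values are floored at the smallest positive float for Q–Q plotting.
* The empirical prevalence-shift uses the interpolated ECDF consistent with
  `np.quantile`, so a zero shift returns exactly the tail fraction; frozen
  distributions use the closed form.
* Mediation's "share of total explanation mediated" uses a semi-partial
  decomposition: the exposure-attributable R² after mediator adjustment is
  R²(exposures + mediators) − R²(mediators alone), and the share is its
  relative drop from the unadjusted model R².  Sign-discordant attenuations
  are flagged, never clipped.

## Validation studies and problem sizes

`exwas.studies` backs both the acceptance tests and `scripts/acceptance.py`.
Problem sizes were chosen to keep each study's Monte-Carlo error well inside
its decision margin: 1000 random vectors for FDR-oracle agreement, 2000
global-null replicates (m = 1000, n = 2000) for family-wise control, 100
random instances for subset-oracle agreement, 50 seeds of the default
cohort for recovery, 200 replicates for pooled-CI coverage, 2000 replicates
for interaction size.  The acceptance script reports the same quantities at
moderately reduced replicate counts (recorded in its JSON output as `n`).

## Known limitations

* Beyond `max_exhaustive` candidates the subset search is not guaranteed
  globally optimal (node-capped branch-and-bound).
* The CHAID variant is simplified: adjacent-category merging, F-tests, and
  a Bonferroni adjustment across predictors rather than Kass's full
  category-partition multiplier.
* The factor model uses principal-axis extraction with varimax rotation, not
  maximum-likelihood factor analysis; retention by eigenvalue > 1 is a
  convention, not an inference.
* Stepwise selection on one completed dataset (then pooling the final model
  across imputations) follows the reporting pipeline's design; per-imputation
  selection with voting is a known alternative that is not implemented.
* Inference after selection is not corrected for the selection event; the
  reported CIs are conditional on the chosen model, as is standard in this
  literature.
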