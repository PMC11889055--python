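# Methods

## Response model

Items are ordered-polytomous with codes `0..C` (tested throughout at
`C = 2`, i.e. 3-point items; the code is generic in `C`).  The generalized
partial credit model (GPCM) gives category probabilities in divide-by-total
form,

    P(Y = c | theta) = exp(s_c) / sum_r exp(s_r),
    s_c = sum_{v=1}^{c} alpha (theta - beta_v),   s_0 = 0,

so each item carries one discrimination `alpha > 0` and `C` thresholds.  A
threshold `beta_c` is the trait value where categories `c-1` and `c` are
equally likely.  All probability work is in log space (max-shifted
log-sum-exp); the likelihood is additive over persons and items, and both
ordinary missing values and items never administered to a cohort contribute
exactly zero.

## Hierarchical multi-group structure

With groups `j = 1..J` (J small, here 3):

- traits: `theta_i ~ N(mu_j, 1/tau_j)` for person `i` in group `j`;
- group means: `mu_j ~ N(0, variance 10)` (precision 0.1);
- group precisions: `tau_j ~ Gamma(shape 1, rate 0.1)` (prior mean
  precision 10).  The Gamma convention is BUGS-style shape/rate; a
  `PriorConfig.gamma_as_rate=False` switch reinterprets the 0.1 as a scale
  for users who read the parameterization the other way;
- group-specific item parameters
  `xi~_kj = (alpha_kj, beta_1kj, beta_2kj) ~ N(xi_k, Q^{-1})` with
  `Q = 0.1 * I`.  The low precision makes these *quasi-fixed effects*:
  with few groups, random-effects shrinkage of group differences is
  undesirable, so the prior is flattened until each group's parameters are
  essentially free, while the shared `xi_k` still links cohorts that
  answered disjoint item subsets through the common items;
- general item parameters: `xi_k ~ N(xi_0, Sigma_xi)`;
- hyperpriors: `xi_0 ~ N((1, 0, 0), I^{-1})`,
  `Sigma_xi ~ InvWishart(I, d)` with `d = 3`, the number of item parameters
  per item (one discrimination, two thresholds); `d` must exceed that
  number minus one.

(Group, item) cells outside the administration mask are excluded from the
parameter state entirely rather than sampled from their prior; a cohort
that answered only a short form contributes information only through its
administered items, and its non-administered parameters simply do not
exist in the model.

## Identification

Location and unit of the latent scale are undetermined per group: a cohort
can score higher because its trait mean is higher or because all its
thresholds are lower, and likewise variance trades off against
discriminations.  The model is identified per group by

- mean threshold over administered items = 0, and
- product of discriminations over administered items = 1.

The transform (`g` = geometric mean of discriminations, `m` = mean of
`g`-scaled thresholds): `alpha' = alpha/g`, `beta' = g beta - m`,
`theta' = g theta - m`, `mu' = g mu - m`, `tau' = tau/g^2`.  It leaves every
category probability unchanged (an exact algebraic identity, tested to
1e-12), so it can be applied deterministically after each MCMC sweep;
stored draws therefore satisfy the constraints (residuals are tracked and
are at machine precision).  For a group administered only a subset of
items, the constraints use that subset only.

Comparing group means is meaningful under the substantive assumption the
restriction encodes: the *average* item difficulty is the same in every
group (individual items may still deviate — that is exactly the DIF the
model allows).

## Sampler

Metropolis-within-Gibbs, chosen to match the conditional structure:

- `theta_i`: random-walk Metropolis, one proposal per person per sweep,
  vectorized over persons (conditionally independent given parameters);
- `(log alpha_kj, beta_1kj, beta_2kj)`: joint random-walk Metropolis per
  administered (group, item) block, all blocks proposed simultaneously
  (conditionally independent given traits).  Proposing on `log alpha`
  keeps discriminations positive by construction; the prior is evaluated
  on the `alpha` scale with the Jacobian term in the acceptance ratio;
- `mu_j`, `tau_j`, `xi_k`, `xi_0`, `Sigma_xi`: conjugate Gibbs
  (normal/gamma/multivariate normal/inverse-Wishart).

Proposal scales adapt every 25 sweeps during burn-in toward a 20–50%
acceptance rate (multiplicative update, clipped), then freeze; typical
realized rates are ~0.35 for both traits and item blocks.  Initialization
is deterministic and data-driven: traits from per-group standardized sum
scores, discriminations 1, thresholds from smoothed adjacent-category
logits, hyperparameters at their prior means.  Per-cell log-likelihoods
are cached across sub-steps (Gibbs updates and the identification
transform leave them invariant), which roughly halves the cost per sweep.

Reference runs use 1000 burn-in / 10000 kept iterations
(`paper_scale_mcmc` in the pipeline config).  The test suite and the
simulation studies below use reduced fits (200/800) so that a 3-group,
16-item, 900-person fit takes a few seconds; all replicate-based checks
were sized accordingly.  Non-finite log-posteriors abort with a state
summary; near-singular covariances are repaired with 1e-8 jitter and the
repair is defensive only (never observed in the test runs).

A `McmcConfig.identify=False` switch disables the per-sweep identification
transform.  It exists for prior-recovery checks: with no data the
`mu_j` posterior must reproduce its `N(0, 10)` prior, which holds for the
raw Gibbs draws but not on the identified scale (the transform mixes in
prior-sampled item parameters).

Convergence reporting (split-R-hat, effective sample size) delegates to
arviz; single chains are split in half.  Summaries report the posterior
mean, SD (the "standard error" of a latent mean), and central 95%
interval; the interval endpoints are reported as the group-mean range
columns.

## DIF and DTF quantification

`dif_table` summarizes, per shared item and parameter, the posterior
distribution of the focal-minus-reference difference; a 95% central
interval excluding 0 flags the parameter.  With many items this is a
screening device: at the 95% level roughly one in twenty invariant
parameters will flag spuriously.

Scale-level DTF uses the expected-score method: `DTFR` is the mean, over
the focal group's estimated traits, of the difference between the expected
total score under focal parameters and under reference parameters
(`TCC_F - TCC_R`; positive DTFR means focal parameters yield higher
expected scores at equal trait level).  Traits enter as posterior means;
`compute_dtfr_draws` provides the alternative of averaging over posterior
parameter draws.  `SD_F` in `d_DTF = DTFR / SD_F` is the *observed*
sum-score SD of the focal group on the shared items (the report tables are
sum-score statistics, not latent-scale ones).  `IMPACT = OMD - DTFR` holds
exactly by construction for every computed result.  Because the
identification restriction forces average thresholds to zero in every
group, true mean differences are absorbed by the trait means and DTFR
should be near zero when the items are invariant — the no-DIF simulations
below confirm |DTFR| well under 0.1 of the focal SD.

Comparisons involving a short-form cohort are restricted to the items both
groups were administered (by default, the full shared set).  TCC curves
are evaluated between the minimum and maximum estimated trait in the two
compared groups, and plots fix the y-axis to the full theoretical score
range `[0, TS]`, `TS = C x (number of items)`, so that negligible DTF
*looks* negligible; no uncertainty bands are drawn (a known limitation of
the expected-score method — only expected scores, not their variability,
are visualized).

## Synthetic cohorts

The generator draws traits from the group-specific normal distributions
and responses from the GPCM cell probabilities, masks non-administered
cells, and optionally duplicates a fraction of persons as twin pairs with
bivariate-normal traits (configurable correlation) so the one-per-family
filter has realistic input.  A DIF ledger plants threshold shifts and/or
discrimination factors in chosen (item, group) cells.  Stored truth is
expressed after the identification transform, so recovery comparisons
against a fitted model are well-posed even when masking or planted DIF
makes the per-group constraints bite differently.

Built-in scenarios mirror a three-cohort harmonization design: `adhd` — 16
items (11 long-form + 5 short-form), cohort sizes 1551/878/4501, third
cohort administered only the short form, score range 0–32; `anxdep` — 36
items (31 + 5), sizes 1507/866/4504, third cohort administered only 4
short-form items, range 0–72.  Default group trait means are (0, −0.40,
+0.54) for `adhd` and (0, 0, +0.58) for `anxdep` — ordered third > first ≥
second with gaps of roughly half a trait SD, echoing the latent-mean
contrasts typical of cohorts differing in age structure.  Base item
parameters (discriminations spread ±0.3 on the log scale around 1,
ordered thresholds spanning about ±1.4) are deterministic and
illustrative; they are not estimates of any published item set.

What the generator does *not* emulate: informative (non-ignorable)
missingness, age or other covariate effects, local item dependence,
response styles, and instrument mode effects.  Passing recovery tests on
these data shows the estimation machinery is correct under the model's own
assumptions, not that real questionnaire data satisfy them.

## Simulation study sizes and frozen checks

The replicate studies in the test suite use 3 groups x 300 persons, 16
items, latent means (0, 0.4, 1.0), reduced 200/800 fits, 20 replicates:

- *recovery*: with a +0.5 first-threshold shift planted in one group,
  posterior group-mean contrasts fall within 3 posterior SDs of the
  identified truth and the planted deviation has the correct posterior
  sign in at least 19/20 replicates;
- *DIF screening*: the planted item is interval-flagged in at least 4/20
  replicates (per-replicate power ≈ 0.45 at this effect size and sample
  size, against a 5% false-positive rate — a one-sided binomial separation
  of about 4 orders of magnitude);
- *null*: with no DIF, |DTFR| < 0.1 SD_F in at least 18/20 replicates;
- *trait recovery*: correlation between posterior-mean and true traits
  exceeds 0.8 in every replicate (typical value ≈ 0.93 at 16 items).

## Numerical choices and edge cases

- Tolerances: probability normalization and transformation invariance to
  1e-12; identification residuals to 1e-8; likelihood preservation under
  identification to 1e-10.
- Degenerate inputs: empty datasets are valid (zero log-likelihood,
  prior-only fits); groups need at least 2 administered items to be
  identifiable; sum-score SDs require n >= 2; DTFR requires a non-empty
  focal group and items shared by both groups.
- Report rounding: DTF tables round to two decimals; full-precision
  results are returned alongside.
- CSV I/O round-trips bit-exactly on the canonical dialect (UTF-8, comma,
  header row, configurable missing token, default "NA").

## Known limitations

Single latent dimension; no Bayes-factor or posterior-predictive DIF
hypothesis tests (screening is by posterior intervals and effect sizes);
no imputation of ordinary missing responses (complete-case analysis per
scale); no uncertainty propagation into the TCC plots; quasi-fixed-effects
device targets small numbers of groups — for many groups a genuine
random-effects variance model would be preferable.
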