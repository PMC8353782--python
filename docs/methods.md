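# Methods

This note documents the models, conventions and numerical choices behind
`gafscore`, in the spirit of a statistical software methods appendix.

## The graded response model

Responses to each item are ordered categories 1..K (K = 5 throughout the
GAFS-8).  The probability of responding in category k+1 or above follows a
logistic in the latent trait θ,

    P*_k(θ) = logistic(a θ + d_k),      d_1 > d_2 > … > d_{K−1},

and category probabilities are successive differences, P(k) = P*_{k−1} −
P*_k with P*_0 = 1 and P*_K = 0.  The slope/intercept parameterization is
used everywhere (more positive intercepts = "easier" boundaries).  Slopes
convert to standardized factor loadings by λ = (a/D)/√(1+(a/D)²) with
D = 1.702, the logistic-to-probit scaling constant; this conversion
reproduces the published loading column of the embedded bank to three
decimals, which is why D is fixed rather than configurable.

Fisher information is I(θ) = Σ_k (∂P(k)/∂θ)²/P(k) with ∂P(k)/∂θ =
a[w_{k−1} − w_k], w = P*(1−P*); categories with vanishing probability
contribute zero by the limit convention.  Grid operations (modal-category
census, wABC integration, EAP) default to θ ∈ [−6, 6] at step 0.01.

## The embedded GAFS-8 bank and scoring

The bank holds the published calibration of TAS-20 items 1, 2, 6, 9, 11,
12, 13, 14 (a multi-group calibration with the general-population group
fixed at N(0, 1)).  MAP scores maximize the log-posterior under a normal
prior by bounded 1-D optimization on [−8, 8] (the posterior is unimodal
for this model); tolerance 1e−8.  EAP scores use fixed-grid quadrature
(201 points on [−8, 8] by default).  Missing items are dropped from the
likelihood and the result carries `n_items_used` as a quality flag — the
source study is silent on partial patterns, so partial scoring is allowed
but flagged rather than refused.

The default prior is the normative N(0, 1): scores read as Z-scores
relative to the general adult population, and T = 50 + 10·θ̂.
`CLINICAL_PRIOR` is the clinical calibration group's latent density
reconstructed from published score moments: MAP scores shrink the latent
SD by √ρxx, so with reported score SD 1.17 and marginal reliability
0.895 the latent density is N(1.01, (1.17/√0.895)²) ≈ N(1.01, 1.24²).
The published extreme scores (−2.19 for the all-lowest pattern, 3.52 for
the all-highest) are reproduced under this prior, not under N(0, 1) —
they were evidently computed for the clinical sample under its own group
density.  Conditional reliability is r(θ) = I(θ)/(I(θ) + 1/σ²_prior)
with σ_prior = 1, which reproduces the published 0.7-crossing interval
(−2.43, 3.53).

Classical composites follow the questionnaire conventions: reverse-keyed
items {4, 5, 10, 18, 19} are reflected as 6 − x; the prorated total is
the mean of ≥ 16 available items × 20; totals at or above 61 flag "high
alexithymia".

## Estimation

Single- and multi-group models are fitted by Bock–Aitkin EM with a fixed
rectangular quadrature grid, default 61 points on [−6, 6] — fixed rather
than adaptive so runs are bit-reproducible; the count is configurable.
The E-step computes each respondent's posterior over the grid; the
M-step maximizes the expected complete-data log-likelihood per item with
a small number of damped Newton steps (finite-difference Hessian of the
analytic gradient, backtracking so the objective never decreases), a
generalized-EM update that preserves the ascent property; items are
batched by category count and updated vectorized.  Intercepts are
optimized in (d₁, log-gap) coordinates so ordering is maintained by
construction.  Convergence is declared when the largest parameter change
falls below 1e−4 (default); non-convergence is flagged on the result,
not raised.  Start values: slopes 1.0, intercepts from inverse-logit
cumulative category proportions.  Categories never observed in the
fitted data are collapsed with a warning.

Multi-group models fix the reference group at N(0, 1) and estimate other
groups' latent means/SDs from posterior moments; items are constrained
equal across groups unless listed as free.  A fully constrained
multi-group fit reproduces the pooled single-group fit exactly (tested).

Standard errors come from the observed information.  The default method
follows the Oakes identity: the marginal score equals the posterior
expectation of the complete-data score (computable analytically from one
E-step), and the information matrix is its numerical Jacobian.  A direct
central-difference Hessian of the marginal log-likelihood is available
as an independent cross-check ("numerical"); the two agree within a few
percent on test fixtures.

## Limited-information fit

The C2-style statistic is a Browne-type residual quadratic form on
low-order margins: univariate category proportions (K−1 per item) plus
one score cross-moment E[X_i X_j] per pair.  Degrees of freedom are
J(K−1) + C(J,2) − 5J, matching the published df bookkeeping (20 for 8
items; 27/35/44 for 9/10/11).  The weight matrix uses the sample
covariance of the margin statistics and the numerical Jacobian of the
model-implied margins; the exact weighting of the originally cited
construction is not printed in the source, and the Browne form is
asymptotically equivalent under the null (the statistic is well
calibrated on self-simulated data in the test suite).  CFI is computed
against an independence baseline (zero slopes, margins matched), RMSEA
as √(max(C2−df,0)/(df·n)), and SRMR over observed-minus-implied
inter-item Pearson correlations of the integer scores.  Residual
correlations are screened at |r| > 0.1.  The model-implied correlations
use Pearson on the categorical scores (the source does not state which
scale it used; polychoric screening is available separately via
`polychoric`).  Marginal reliability is 1 − E[posterior variance]/prior
variance averaged over the fitted sample.

## DIF testing

The iterative Wald procedure: round one tests each item with all other
items as anchors (the tested item's parameters free per group, focal
latent moments free); omnibus Wald statistics (df = 5: slope plus four
intercepts) are corrected by Benjamini–Hochberg FDR at 0.05; flagged
items lose anchor status and the procedure repeats with only unflagged
anchors until the flag set stabilizes.  Wald covariances come from the
Oakes observed information of the full model (forward differences for
speed on the test path).  Flagged items get follow-up single-parameter
Wald tests, FDR-corrected within the item's five-parameter family.

Effect sizes: wABC integrates |ES_ref − ES_foc| against the focal
group's estimated normal density (μ_F ± 6σ_F, 601 points) — the normal
density rather than an empirical score histogram, which is the cleaner
population-level definition; the sample-based UETSDS uses grid-MAP trait
estimates of the focal respondents per its "in the sample" definition.
ESSD and ETSSD standardize the signed expected difference by the pooled
(total-variance) item/test score SD under the focal density; positive
values mean the focal group scores higher at equal trait level.  The
practical-significance threshold on wABC is 0.30.

## Bifactor indices

PUC enumerates all item pairs; a pair is contaminated when the two items
share any non-general factor, *including* the reverse-coded method
factor — this convention reproduces both published PUC values exactly and
is therefore fixed.  ECV is Σλ²_G/(Σλ²_G + Σλ²_spec), with item- and
subscale-level analogues.  Categorical omegas follow Green–Yang:
expected covariances of the threshold-categorized items are computed
from bivariate-normal orthant probabilities at the model-implied latent
correlations, with the general-factor-only (ω_H), all-factor (ω_T) and
subscale-restricted (ω_S, ω_HS) numerators over the full-variance
denominator.  ω_T matches the parallel-forms reliability of a 60k-
respondent simulation within 0.02 in the test suite.  Loadings and
thresholds are inputs (from any external CFA or the simulator); no
weighted-least-squares factor estimator is shipped.

## Robust Bayesian validity statistics

Correlations use a bivariate Student-t likelihood with free locations,
scales and a shared tail parameter ν (prior: shifted exponential with
mean 29, the conventional weakly-informative choice); the correlation
gets a Fisher-z normal prior with SD 1 (configurable `prior_scale`).
Partial correlations parameterize the trivariate correlation matrix
through the partial correlation itself (plus the two control
correlations), which guarantees positive definiteness and makes the
effect size a primitive parameter.  Polyserial correlations fix the
ordinal thresholds at inverse-normal marginal proportions (two-step) and
compute the posterior over ρ on a grid.  The group comparison is
BEST-style with separate scales; Cohen's d standardizes by the
normal-equivalent scale σ·t₀.₇₅(ν)/z₀.₇₅ (the quartile consistency
correction, analogous to MAD × 1.4826) so that d does not inflate when
contamination drives ν down — without this, 1% gross outliers shift d by
~0.07; with it, under 0.05.  Posteriors are sampled with emcee (affine-
invariant ensemble; chain lengths chosen so repeated runs agree to ~0.01
on the effect-size median); summaries are the posterior median and 95%
HDI (shortest sample interval).

BF_ROPE = [P_prior(ROPE)/(1−P_prior)]/[P_post(ROPE)/(1−P_post)] with
ROPE ±0.2 for r and d, ±0.1 for partial r; thresholds 3 and 1/3 classify
substantial evidence.  The source's exact prior families live in an
unavailable supplement, so priors here are explicit, documented and
configurable; the ROPE and thresholds are as published.

## Synthetic data

`default_two_group_config` mirrors the calibration design: normative
group θ ~ N(0, 1), n = 721; clinical group θ ~ N(1.01, 1.17²), n = 743;
responses drawn from the published bank.  DIF injection shifts all
intercepts of an item by a constant (positive = easier in that group)
and/or scales its slope; ordering is re-validated after the shift.
Bifactor ordinal data: independent standard-normal factors, loading-
weighted sums plus residuals scaled to unit total variance, cut at
probit thresholds.  Covariates are a·θ + b·confounder + noise with
coefficients solved to hit target zero-order correlations and a chosen
confounder-mediated share (the confounder correlates 0.475 with θ by
default, the published neuroticism correlation).

What the generator does *not* emulate: item-level missingness patterns
beyond MCAR, acquiescence/response styles, cross-loadings, non-normal
trait distributions, or sampling designs.  Passing recovery tests on
these data therefore demonstrates correctness of the estimators under
the stated model, not robustness to real-data violations of it.

## Replicate study sizes

The error-rate study for the DIF procedure uses 10 null and 10
planted-DIF replicates at n = 700 per group with 41 quadrature points
and EM tolerance 3e−4 (coarser than the single-fit defaults; the Wald
statistics are insensitive to this resolution).  Parameter-recovery runs
use n = 2000 (single group) and 1500 per group (multi-group).  Monte
Carlo oracles use 10⁶ draws for effect sizes and 6×10⁴ respondents for
the omega parallel-forms check.

## Known limitations

- The C2 weight matrix is the Browne residual form, not a byte-level
  reproduction of any particular software's statistic; its df and
  calibration match the published bookkeeping.
- The readability syllable counter is a heuristic with a small exception
  lexicon; commercial tools tokenize differently, so published grade
  levels from such tools are approximated, not reproduced.  The TAS-20
  item text is copyrighted and not distributed; readability runs on
  user-supplied text only.
- Polyserial correlations use two-step thresholds (not jointly sampled).
- Multi-group limited-information fit conditions on the estimated group
  densities (df counts item parameters only).
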