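# Methods

`amhcut` estimates age-specific diagnostic cut-offs for a continuous
biomarker — serum anti-Müllerian hormone (AMH, ng/mL) discriminating
polycystic ovary syndrome (PCOS) cases from normo-ovulatory controls —
parameterized directly by predictive values rather than by
sensitivity/specificity. This note records the models, the defaults and
why they were chosen, the synthetic-data generator's scope, and the
numerical decisions.

## The step-function disease-probability model

Disease status `d` given biomarker `x` is modeled as

    P(d = 1 | x) = theta_pos   if x >= c
    P(d = 1 | x) = theta_neg   if x <  c

The likelihood conditions on `x`, so its marginal distribution drops
out. That choice is what gives the two rates their clinical meaning:
`theta_pos` is literally the positive predictive value (PPV) of the
test "x >= c", and `1 - theta_neg` is the negative predictive value
(NPV). Ties `x == c` count as test-positive throughout the package.
The cut-off `c` is a model parameter supported on the observed
biomarker range `[min x, max x]`.

### Priors

Three families:

* **uninformative** — Beta(1, 1) on both rates, uniform on `c`;
* **informative** — Beta priors with user-supplied means (defaults
  PPV 0.95, NPV 0.85) at effective sample size 20, and a
  truncated-Normal prior on `c` centered by default at 4.7 ng/mL (the
  single-threshold value reported in the AMH/PCOS meta-analytic
  literature) with SD 1 ng/mL;
* **mixture** — a 50/50 mixture of the two, applied independently to
  each rate and to the cut-off density.

### Sampling

Metropolis-within-Gibbs with the rates **collapsed out of the cut-off
move**. Under Beta (or Beta-mixture) priors the rates integrate out
analytically, leaving a Beta-binomial marginal likelihood for `c`; the
Metropolis step targets that marginal, and the rates are then drawn
from their exact conjugate conditionals (under mixture priors, from the
posterior mixture with recomputed weights). Collapsing matters: the
step likelihood is piecewise constant in `c` with potentially
well-separated local modes, and a non-collapsed sampler traps chains in
dominated modes because the sampled rates adapt to the current split.

The `c` proposal mixes a Gaussian random walk (reflected at the support
bounds) with a 10% probability of an independence proposal uniform over
the support, which lets chains relocate across distant modes. The
random-walk step starts at `0.25 * IQR(x)` and is tuned during burn-in
toward ~30% acceptance, then frozen, so the post-burn-in kernel is
fixed and valid. Per-iteration cost is O(log n) via a sorted-data
cumulative disease count.

Defaults: 3 chains x 20,000 iterations, 5,000 burn-in, thin 1, chain
seeds derived from one master seed. Reported point estimate is the
posterior mean (median also emitted); intervals are equal-tailed 95%
credible intervals; convergence is monitored with the split-chain
potential scale reduction factor (warning above 1.1) and the
acceptance rate (warning outside [0.1, 0.6]).

Sampler self-checks implemented as tests: with `c` fixed the marginals
must match the closed-form Beta posteriors (KS < 0.05); with the
likelihood switched off the sampler must reproduce each prior's means.

## The PSI comparator

The predictive summary index is the predictive-value analogue of the
Youden index: `PSI = max_c (PPV_c + NPV_c - 1)`. Candidate cut-offs are
the sorted unique observed values (positivity `x >= c`); a candidate is
admissible only when both sides are non-empty; ties break toward the
smallest cut-off (within 1e-12, guarding float noise between
mathematically equal candidates). Uncertainty comes from a
nonparametric case-resampling bootstrap with percentile intervals
(default B = 1000); replicate seeds are spawned from the master seed so
extending B keeps earlier replicates identical.

Two empirical properties of this estimator worth knowing (both
quantified in the test suite): under a null (labels independent of
`x`), the maximized PSI is strongly inflated — median ~0.5 at n = 200 —
because extreme cut-offs with tiny positive sides reach PPV = 1 by
chance; and the bootstrap distribution of the cut-off can have a sparse
far tail, making the 2.5% percentile endpoint genuinely unstable even
at large B.

## Age categorization

An exploratory binomial GAM (logit link) of disease on smooth(age) +
smooth(AMH) — penalized cubic B-splines, 10 basis functions per term,
penalty chosen by a small generalized-cross-validation grid with a
heavily-penalized fallback — establishes the nonlinear age structure.
Age cut-points themselves are chosen by exhaustive search: k in
{1, 2, 3} cut-points on a 0.5-year grid strictly inside [20, 40], each
candidate tuple scored by the in-sample empirical AUC (rank-based, ties
half-counted) of a logistic working model with the categorized age
factor. Bands are left-closed/right-open except the last; tuples
leaving a band under 5% of subjects are skipped; ties break toward
balanced band sizes, then smaller cut-points.

**Design choice — no biomarker term in the categorization model.** The
working model is univariate (age bands only) by default. With any
flexible AMH term (linear, log-linear, or spline) the AUC argmax
collapses both cut-points into a narrow young-age range, because the
biomarker term absorbs precisely the age-specific diagnostic signal the
bands are meant to stratify; the univariate categorization recovers
well-separated late-20s / mid-30s boundaries on the calibrated cohort
and recovers planted cut-points exactly on step fixtures. An
`amh_col=` argument opts back into the adjusted variant. Training-data
AUC is the objective (no cross-validation), matching in-sample usage.

## Synthetic cohort generator

The reference cohort is not publicly deposited, so the generator
emulates its published anatomy:

* AMH log-normal within group with a log-linear age trend:
  controls `log AMH ~ N(4.471 - 0.13 age, 0.40^2)`, cases
  `N(3.907 - 0.08 age, 0.40^2)` — cases higher at every age and
  declining more slowly;
* control ages uniform on [20, 40]; case ages from a moment-matched
  scaled Beta with mean 27.9 and SD 4.6 years (cases younger);
* BMI Normal(26.6, 5²), independent of AMH and identical across groups.

Calibration was done once against the published group medians/IQRs
(pooled and per age band) and the pooled AMH-age Pearson correlation
(~ -0.63), then frozen with regression tests. A pure fit of the band
medians alone gives r ≈ -0.45 (the log-normal right tail inflates
Var(AMH)); within the freedom the published IQR windows allow, the
steeper frozen slopes reproduce both the medians (with margin, across
seeds) and the correlation. What the generator does **not** emulate:
assay error structure, the old-skewed control age distribution of the
source cohort, phenotype heterogeneity, BMI-AMH dependence, or any
Table-1 variable beyond age/AMH/BMI/group. Passing tests therefore
demonstrate that the estimators recover the structure this generator
plants — not that the original study's numeric cut-offs are
reproduced.

Two auxiliary generators provide clean validation data: the step model
itself (for estimator recovery at known truth, default c = 4.5,
PPV = 0.95, NPV = 0.85 on Uniform(0, 12)), and a piecewise-constant
prevalence-by-age process (for cut-point recovery, default cut-points
27/35 with prevalences 0.8/0.5/0.1).

## Simulation study

Per replicate: generate step data at known truth, run both estimators,
record point estimates and nominal-95% intervals; score bias, empirical
coverage and mean interval length per method and parameter. Inside
replicated simulations the sampler runs reduced settings (2 chains x
5,000 iterations, 1,000 burn-in) and B = 500 bootstrap replicates —
problem sizes chosen so the full default comparison stays desk-scale;
the expected qualitative pattern (Bayesian coverage and interval length
superior at n = 30, both methods unbiased by n = 2000 under all three
priors) is insensitive to these settings. Everything is deterministic
given the scenario's master seed.

## Preprocessing conventions

* Quantiles: linear interpolation between order statistics ("type 7")
  everywhere — fences and IQRs depend on the rule, so it is fixed.
* Tukey outlier filter: fences Q1 - 1.5 IQR / Q3 + 1.5 IQR computed
  within each group on AMH only, one pass (idempotent on its own
  output); values exactly on a fence are kept; exclusions logged by id.
* Group comparisons: Welch t (no homogeneity assumption), Mann-Whitney
  U with normal approximation and tie correction, Pearson chi-square
  without continuity correction. Two-sided p-values, no multiplicity
  correction.
* Fractional polynomials: exhaustive search over powers
  {-2, -1, -0.5, 0, 0.5, 1, 2, 3} (0 = log; repeated power p gives
  x^p and x^p log x), least squares, deviance = residual sum of
  squares, degrees 1 and 2 exposed.
* Assay conversion: picoAMH = 0.01 + 1.69 * GenII.

## Degenerate inputs and edge cases

Empty groups, single-class outcomes, degenerate biomarker ranges,
all-tied ages, exclusions exceeding enrolment and invalid probabilities
are rejected with explicit messages; impossible outcomes under
degenerate rates return log-likelihood -inf rather than raising;
bootstrap replicates where the optimizer is undefined are dropped and
counted; constant MCMC chains report R-hat 1.0 by convention.

## Known limitations

* The Bayesian cut-off and PSI maximizer answer slightly different
  questions (likelihood argmax vs PPV+NPV argmax); on data that do not
  follow a step model — including the synthetic cohort — they can
  legitimately disagree.
* In-sample AUC as the categorization objective inherits the usual
  optimism of training-data selection; a cross-validation flag exists
  but is off by default to match in-sample usage.
* The pipeline treats band estimates independently; no shrinkage or
  ordering constraint across bands is imposed, so the decreasing
  cut-off pattern is an empirical outcome, not a model constraint.
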