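# amhcut

Age-specific diagnostic cut-offs for serum anti-Müllerian hormone (AMH)
in polycystic ovary syndrome (PCOS), estimated from predictive values.

Most biomarker-threshold work reports sensitivity/specificity via ROC
analysis. For a clinician deciding about the patient in front of them,
the quantities that matter are the positive and negative predictive
values — P(disease | test-positive) and P(no disease | test-negative).
`amhcut` implements a threshold methodology built directly on them:

* **Bayesian step model** — disease probability is a step function of
  the biomarker, `P(d=1 | x) = θ₊` for `x ≥ c` and `θ₋` for `x < c`,
  where the likelihood conditions on `x` so that `θ₊ = PPV` and
  `1 − θ₋ = NPV`, and the cut-off `c` is itself a model parameter.
  Posterior sampling is a collapsed Metropolis-within-Gibbs scheme
  (Beta-binomial marginal for `c`, exact conjugate draws for the
  rates) with uninformative, informative, and mixture priors.
* **PSI comparator** — the frequentist predictive summary index,
  `PSI = max_c {PPV_c + NPV_c − 1}`, with case-resampling percentile
  bootstrap intervals.
* **Data-driven age bands** — logit-link GAM exploration plus an
  exhaustive AUC-maximizing search for age cut-points, so the age
  categories come from the data instead of being imposed.
* **Simulation harness** — bias / coverage / interval-length comparison
  of the two estimators across sample sizes and priors.
* **Calibrated synthetic cohort generator** — a case/control cohort
  with log-normal AMH declining in age (cases higher and declining more
  slowly, cases younger), calibrated to published descriptive
  statistics, so the full pipeline is testable without any data
  download.

## Worked example

```python
from amhcut import (McmcConfig, PriorSpec, StepGenParams,
                    generate_step_data, sample_posterior, summarize_posterior)

data = generate_step_data(StepGenParams(true_cutoff=4.5, true_ppv=0.95,
                                        true_npv=0.85, n=2000, seed=7))
chains = sample_posterior(data.x.to_numpy(), data.d.to_numpy(),
                          prior=PriorSpec.uninformative(),
                          config=McmcConfig(n_chains=3, n_iter=10_000,
                                            n_burnin=2_000, seed=1))
print(summarize_posterior(chains).table().round(3).to_string(index=False))
```

prints

```
parameter  mean  median  ci_lower  ci_upper  rhat
   cutoff 4.495   4.494     4.487     4.510 1.001
      ppv 0.945   0.946     0.932     0.957 1.000
      npv 0.845   0.845     0.819     0.870 1.000
```

The data were generated from the step model with cut-off 4.5 ng/mL,
PPV 0.95 and NPV 0.85; the posterior means recover all three, and the
95% equal-tailed credible intervals cover the truth. `rhat` is the
split-chain convergence diagnostic (values near 1 indicate the chains
agree).

The `examples/` directory has one short script per capability:
cohort generation and descriptives, the Bayesian cut-off, the PSI
cut-off, age partitioning, the full age-banded pipeline, and the
estimator-comparison simulation. The same functionality is exposed as
a thin CLI:

```sh
amhcut simulate cohort --n 500 --seed 1 --out cohort.csv
amhcut run-all --in cohort.csv --seed 1 --out results/
```

On the calibrated synthetic cohort the full pipeline reproduces the
hallmark clinical pattern: the Bayesian AMH cut-off decreases across
ascending age bands (AMH declines physiologically with age), and the
pooled single cut-off lies between the youngest- and oldest-band
values.

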