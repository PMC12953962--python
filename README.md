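# otobayes

Bayesian analysis of opioid-prescribing survey data in pediatric
otolaryngology: how often do surgeons report an opioid-sparing regimen after
pediatric adenotonsillectomy, and which surgeon characteristics predict it?

The package is built for biostatisticians analysing small cross-sectional
clinician surveys with geographic clustering. It provides, as a tested
reusable library:

- **Evidence-weighted prior elicitation.** Historical studies reporting an
  opioid-sparing proportion p_i with sample size n_i and publication year
  y_i receive normalized weights

  w_i ∝ t_i · n_i · p_i (1 − p_i),  t_i = y_i − 2013,

  where 2013 (the FDA black-box warning against codeine in children after
  adenotonsillectomy) anchors recency. The pooled proportion
  p̄ = Σ w_i p_i centres a normal prior on the model intercept at
  logit(p̄). An inverse-variance × recency alternative
  (w_i ∝ t_i n_i / (p_i(1−p_i))) is available behind a flag.

- **A hierarchical Bernoulli-logit model.** For respondent i in province
  j(i):

  y_i ~ Bernoulli(p_i),  logit(p_i) = α + x_iᵀβ + b_{j(i)},

  with α ~ N(logit(0.61), 1.18), β_k ~ N(0, 0.5), σ ~ Exponential(1),
  b_j | σ ~ N(0, σ). Covariates are dichotomized surgeon characteristics
  (age ≤40/>40, pediatric vs general/other subspecialty, academic vs
  community setting, ≤50/>50 procedures per year, intracapsular coblation
  vs other techniques). Sampling is componentwise adaptive random-walk
  Metropolis on (α, β, log σ, z) with likelihood-invariant group moves;
  convergence is assessed by split-chain Gelman–Rubin R-hat and effective
  sample size.

- **Posterior probability of superiority.** For each covariate, the share
  of posterior mass with the index group's sparing probability above the
  reference group's — for this model, P(β > 0).

- **Model ranking by LOO ELPD.** Pareto-smoothed importance sampling
  (with an in-repo generalized-Pareto tail fit and k̂ diagnostics) plus an
  exact refit-n-times cross-check feasible at survey scale.

- **Synthetic data.** A parametric generator of the assumed data-generating
  process (with hidden truth, for calibration tests) and a deterministic
  reconstruction of a published 100-respondent survey's one-way marginals.

## Worked example

```python
from otobayes import (PriorConfig, build_model_spec, complete_case_filter,
                      paper_margins_dataset, probability_of_sparing,
                      sample_posterior, summarize_vector)

complete = complete_case_filter(paper_margins_dataset(seed=0))   # 96 of 100
spec = build_model_spec(complete, [], PriorConfig())
draws = sample_posterior(spec, n_chains=4, n_warmup=2000, n_iter=2000, seed=0)
for mode in ("new_province", "median_province"):
    m, lo, hi = summarize_vector(probability_of_sparing(draws, mode, seed=0), 0.90)
    print(f"P(opioid-sparing), {mode}: {m:.2f}  90% CrI [{lo:.2f}, {hi:.2f}]")
```

prints

```
P(opioid-sparing), new_province: 0.76  90% CrI [0.63, 0.88]
P(opioid-sparing), median_province: 0.76  90% CrI [0.68, 0.84]
```

i.e. with 73 of 96 complete respondents reporting an opioid-sparing
regimen, the model puts the probability of opioid-sparing prescribing at
about 76%. The `new_province` mode folds the posterior geographic
variability σ into the interval (the probability for a previously unseen
province); `median_province` conditions on b = 0 and is narrower.

The `examples/` directory has one short script per capability: prior
elicitation, survey descriptives, the baseline fit above, subgroup
comparisons with superiority probabilities, LOO model ranking, and the full
pipeline. A thin CLI mirrors the stages:

```sh
otobayes elicit-prior --studies examples/data/historical_studies_synthetic.csv \
    --out prior.yaml --seed 0
otobayes report --data survey.csv --studies studies.csv --out out/ --seed 0
```

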