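# Methods

This note documents the statistical model, the numerical choices behind it,
and what the synthetic data can and cannot establish.

## Model

Each survey respondent i contributes a binary outcome y_i (1 = reports an
opioid-sparing regimen after pediatric adenotonsillectomy) and a province
j(i). The hierarchical Bernoulli-logit model is

    y_i | p_i       ~ Bernoulli(p_i)
    logit(p_i)      = α + x_iᵀβ + b_{j(i)}
    α               ~ Normal(m_α, s_α)
    β_k             ~ Normal(0, s_β)          (one per covariate)
    σ               ~ Exponential(λ)
    b_j | σ         ~ Normal(0, σ)            (one per province)

The province random intercept absorbs geographic clustering (provincial
drug policy, regional practice culture) that would otherwise bias the
intercept's precision. All covariates are binary contrasts of surgeon
characteristics; with no covariates the model is the "baseline" used for
the headline probability.

### Priors and their provenance

| parameter | prior | default | rationale |
| --- | --- | --- | --- |
| α (intercept, logit scale) | Normal(m_α, s_α) | m_α = logit(0.61) ≈ 0.45, s_α = 1.18 | m_α from the evidence-weighted pooling below; s_α = 1.18 approximates a logistic distribution on the probability scale, keeping the implied prior on p near-uniform-tailed |
| β_k (log odds ratios) | Normal(0, 0.5) | — | no prior direction of association; SD 0.5 keeps group-wise prior probabilities similar |
| σ (between-province SD, logit scale) | Exponential(1) | — | weakly informative; no external information on inter-provincial variability |

Prior elicitation pools historical studies with weights
w_i ∝ t_i n_i p_i(1−p_i), normalized to sum to one, where t_i is years
since the 2013 reference event. The printed form of this weight's
denominator in the source literature does not normalize its numerator, so
the package normalizes by the sum of the numerators; the classical
meta-analytic precision weight (w_i ∝ t_i n_i / (p_i(1−p_i)), larger for
extreme p_i) is provided as a selectable alternative, since the two differ
in which studies they favour. Studies published in or before the reference
year are rejected outright: a zero or negative recency weight would
silently discard evidence, and every intended source postdates 2013.

The interval implied by the prior is characterized by simulation, drawing
μ ~ N(m_α, s_α), σ ~ Exp(λ), b ~ N(0, σ) and reporting equal-tailed
quantiles of invlogit(μ + b) (default 200 000 draws, seed mandatory). With
the default configuration the 90% interval is ≈ [0.09, 0.96] — wide, as a
weakly-informative prior should be. Only qualitative width (lower bound
below 0.25, upper above 0.90) is asserted in tests, since the exact
interval depends on whether the random-intercept layer is included.

### Probability functionals

Two summaries of "the probability of opioid-sparing prescribing" are
implemented, and they answer different questions:

- **median_province**: invlogit(α), the probability in a province at the
  median of the random-effect distribution (b = 0). Used for subgroup
  curves, where the contrast between arms is the object of interest.
- **new_province** (headline default): invlogit(α + b*) with a fresh
  b* ~ N(0, σ_draw) per posterior draw. This marginalizes over geographic
  variability and yields a wider interval, appropriate for a statement
  about Canadian practice at large rather than any one province.

The posterior probability of superiority for a covariate is the fraction
of draws with the index arm's probability above the reference arm's; at a
common b this equals P(β > 0). Exact ties (possible in persisted,
rounded draw files) count one half. No multiplicity adjustment is applied
across the five covariates; the probabilities are reported directly, as
descriptive posterior statements.

## Sampling

The sampler is componentwise adaptive random-walk Metropolis on the
unconstrained vector (α, β, log σ, z), where b = σz is the non-centered
parameterization of the random intercepts and the log transform makes
σ = 0 unreachable (the Jacobian term is included). Each iteration also
makes two likelihood-invariant group moves that target the posterior's
stiff directions: a translation (α and the z_j shifted oppositely, linear
predictor unchanged) and a rescaling (log σ shifted, z scaled so b is
unchanged, with its −Jδ log-Jacobian). Without them, α mixes very slowly
once the data are informative, because α and the province effects are
strongly negatively correlated. Proposal scales adapt during warmup by
Robbins–Monro toward ≈35% acceptance per move and are frozen afterwards.

The likelihood is evaluated on (province × covariate-pattern)
sufficient-statistic cells — algebraically identical to the
per-respondent sum, but an order of magnitude cheaper at survey scale,
and verified against the per-row form in tests. Bernoulli terms use
log-add-exp, finite for |η| well past 700.

Defaults: 4 chains, 2000 warmup, 2000 kept iterations; chains seeded
independently from (seed, chain index), so runs are bit-reproducible.
Convergence passes when max split-chain R-hat < 1.01 and min ESS ≥ 400.
ESS uses chain-averaged FFT autocorrelations with Geyer initial-monotone
truncation at the first negative pair sum. Two constant chains at the same
value report R-hat 1 with a degenerate-chain warning; at different values,
R-hat is infinite. The pipeline fails loudly (or warns, if configured
lenient) on any fit missing the thresholds; the library itself returns the
draws with the report, never a silent success.

Validation of the sampler: (a) with no data, it reproduces the prior
(mean/SD of α, mean of σ, marginal SD of b against a Monte-Carlo oracle);
(b) with the random-effect variance forced to ~0, posterior means of α
match 1-D quadrature within 0.01; (c) across 100 simulated surveys
(n = 2000, 10 provinces), 90% credible intervals for α and β cover the
truth at 84–96%.

## Leave-one-out model comparison

PSIS-LOO: per observation, raw importance ratios are the inverse
per-draw likelihoods. With S draws, the M = min(⌈0.2S⌉, ⌈3√S⌉) largest
ratios are replaced by quantiles of a generalized Pareto distribution
fitted to their exceedances over the remaining maximum, at the expected
order-statistic positions (z − 0.5)/M, then truncated at the raw maximum.
The GPD fit is the profile-posterior (grid-over-rate) estimator with a
mild shrinkage of the shape toward 0.5 (10 pseudo-observations),
implemented in-repo and validated against simulated GPD samples; the
resulting smoothed weights and k̂ values match an independent
implementation to machine precision in tests. k̂ > 0.7 flags an
observation whose estimate is unreliable.

Exact refit LOO refits the model once per observation (guarded at
n ≤ 200), keeping the full province set so a province emptied by the
deletion retains its random intercept informed only by the prior.
Sub-fits use shorter chains with relaxed guard-rail diagnostics
(R-hat < 1.05, ESS ≥ 100); failures are counted in the result, not
hidden. ELPD differences between models are reported with the paired SE
√(n·var(pointwise differences)), with no significance labels. Models are
only ranked together when evaluated on the same observations; the
pipeline excludes (and logs) models whose complete-case set differs, as
happens when the practice-setting contrast drops "other" respondents.

## Data handling

Survey CSV fields are closed enumerations; unknown tokens are rejected
with the offending line number, and the canonical writer round-trips
byte-identically. Complete-case filtering retains respondents with no
missing value among the modeling fields (province, age group, setting,
subspecialty, annual volume, technique, outcome), mirroring the analysis
population of the survey the package reconstructs.

Dichotomization choices that were genuinely open:

- Practice setting "other" is treated as missing for the academic-vs-
  community contrast (the contrast names only two arms) rather than pooled
  into community; `setting_other="community"` pools it instead. The
  complete-case rule of each model then governs exclusion.
- Intracapsular microdebrider is coded with the reference arm of the
  coblation contrast by default (`microdebrider_intracapsular=True` moves
  it), since the published contrast names coblation specifically.
- An annual volume of exactly 50 belongs to the ≤50 arm.

The minimum-age CI uses the t distribution with n−1 degrees of freedom;
at the survey's n = 49 the t and z intervals agree to the reported digit.
Opioid-preference questions allow multiple selections (encoded
`a;b`); percentages are per answering respondent, so multi-select tallies
may exceed 100% in total.

## Synthetic data

`generate()` simulates the exact process the model assumes: multinomial
provinces, independent Bernoulli covariates, b_j ~ N(0, σ), outcomes from
the logistic model, and completely-at-random missingness. Defaults emulate
the reconstructed survey's scale: 100 respondents, 10 provinces led by
ON/QC/BC (0.33/0.22/0.13), covariate prevalences 0.60/0.24/0.40/0.50/0.16
(age >40, pediatric, academic, >50 procedures — not tabulated in the
source, set to an even split — and coblation), baseline rate 0.73, σ = 0.5.
The hidden truth is returned for recovery and coverage tests.

`paper_margins_dataset()` reconstructs the published survey's one-way
marginals exactly: 100 respondents, the printed province/age/role/
setting/subspecialty/technique counts, 73 opioid-sparing, a 45/2/1/49
split of the minimum-age question with bimodal numeric ages in [2, 18],
morphine preferred by 82 and codeine least preferred by 79. The published
setting column sums to 101 for n = 100; the fixture keeps the printed
40 academic / 58 community and reduces "other" to 2. Exactly four
respondents are incomplete — missing the annual-volume response, the one
modeling field absent from the published demographics — and are coded
non-sparing, so the complete-case count is 96 with 73 sparing among them
while the overall tally stays 73/100. Because no outcome-by-covariate
cross-tabulation was ever published, the joint structure is randomized
under the seed. Consequently the fixture supports **marginal-level**
checks (the 96-of-100 filter, the 73% rate, the baseline posterior) but
**not** subgroup posterior probabilities or ELPD values, which depend on
the unobtainable respondent-level joint data; those are covered by the
calibration and power properties below instead.

What passing tests on synthetic data do not show about real data: the
generator has no informative missingness, no within-institution
clustering beyond province, no response-propensity structure, and
independent covariates — real surveys have none of these guarantees.

## Problem sizes used in the test suite

Chosen to give each statistical check adequate power while keeping the
default suite practical to run routinely: calibration coverage uses 100
replicate fits at n = 2000 with 2 chains × (400 warmup + 600 kept) —
interval-coverage checks need many replicates more than they need long
chains; ELPD ranking power uses 50 replicates at n = 150 with a simulated
subspecialty log-odds effect of 1.2; the PSIS vs exact-refit agreement
uses n = 40 (41 fits). The headline baseline fit always runs at the full
4 × (2000 + 2000) defaults.

## Known limitations

- The random-walk kernel, even with the group moves, is adequate at survey
  scale (n ≲ a few thousand, tens of provinces) but would need a
  gradient-based replacement for much larger designs; the contract is the
  stationary distribution and the diagnostics, not the kernel.
- Exact-refit LOO at n near the 200 guard is slow by construction;
  PSIS-LOO is the intended estimator there.
- The elicitation layer implements one weighting family (plus one
  documented alternative), not general meta-analysis: no heterogeneity
  τ², no forest plots.
- Only binary outcomes, binary covariates and a single grouping level are
  supported, matching the survey designs the package targets.
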