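"""Univariate subgroup comparisons with posterior superiority probabilities.

For each surgeon characteristic, fits intercept + one binary covariate +
province random intercepts and reports each arm's sparing probability at
the median province along with P(index arm > reference arm).  The fixture's
outcome-by-covariate joint structure is randomized (it was never published),
so the subgroup numbers below illustrate the machinery, not the survey.
"""

from otobayes import (
    COVARIATES,
    PriorConfig,
    complete_case_filter,
    fit_univariate,
    paper_margins_dataset,
)

complete = complete_case_filter(paper_margins_dataset(seed=0))
prior = PriorConfig()
for i, cov in enumerate(COVARIATES):
    res = fit_univariate(complete, cov, prior,
                         n_chains=2, n_warmup=1000, n_iter=1500, seed=10 + i)
    rm, rl, rh = res.reference_summary
    im, il, ih = res.index_summary
    print(f"{cov}: {res.index_label} {im:.2f} [{il:.2f},{ih:.2f}] vs "
          f"{res.reference_label} {rm:.2f} [{rl:.2f},{rh:.2f}]  "
          f"P(superior) = {res.superiority_probability:.2f}")
# A superiority probability near 0.5 means the data cannot separate the
# arms; near 1 (or 0) means strong evidence the index (reference) arm
# spares opioids more often.
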