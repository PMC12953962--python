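"""Descriptive statistics of the reconstructed survey.

Builds the 100-respondent dataset whose one-way tallies match the published
demographics, then summarizes the minimum-age question and the opioid
preference questions.
"""

from otobayes import (
    complete_case_filter,
    paper_margins_dataset,
    response_rate,
    summarize_min_age,
    tally_preferences,
)

dataset = paper_margins_dataset(seed=0)
print(f"respondents: {len(dataset)} "
      f"(response rate {response_rate(len(dataset), 517):.1f}% of 517 eligible)")
complete = complete_case_filter(dataset)
print(f"complete cases for modeling: {len(complete)}")

ma = summarize_min_age(dataset, ci_level=0.95)
print(f"minimum-age question: {ma.n_no_limit} no limit, {ma.n_never} never "
      f"prescribe, {ma.n_weight_based} weight-based, {ma.n_numeric} numeric")
print(f"numeric minimum age: mean {ma.mean_years:.1f} y (SD {ma.sd_years:.1f}), "
      f"95% CI [{ma.ci_bounds[0]:.1f}, {ma.ci_bounds[1]:.1f}]")

for field in ("preferred_opioid", "least_preferred_opioid"):
    tally = tally_preferences(dataset, field)
    top = tally.iloc[0]
    print(f"{field}: {top['category']} ({top['percent']:.0f}% of respondents)")
# Morphine dominates as preferred; codeine as least preferred — mirroring
# the post-2013 shift away from codeine in children.
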