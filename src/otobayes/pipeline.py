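"""End-to-end analysis orchestration.

``run_full_analysis`` wires the stages together: elicit the intercept prior
from historical studies, fit the baseline intercept-only hierarchical model,
fit one univariate comparison per covariate, fit a joint multivariable
model, and rank everything by PSIS-LOO ELPD.  Every stage writes a CSV to
the output directory; a JSON manifest records the seed, package version and
a hash of the analysis-relevant configuration so that a run can be
reproduced and audited.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .compare import fit_multivariable, fit_univariate
from .errors import ConvergenceError, ValidationError
from .loo import compare_models, pointwise_loglik, psis_loo
from .model import (
    build_model_spec,
    convergence_report,
    probability_of_sparing,
    sample_posterior,
    summarize_vector,
)
from .priors import (
    PriorConfig,
    build_prior_config,
    compute_study_weights,
    pooled_prior_proportion,
    prior_predictive_interval,
    read_historical_csv,
)
from .survey import (
    COVARIATES,
    MODELING_FIELDS,
    SurveyDataset,
    complete_case_filter,
    read_survey_csv,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_full_analysis"]


@dataclass(frozen=True)
class RunConfig:
    """Settings of a full analysis run."""

    survey_csv: str
    historical_csv: Optional[str]
    out_dir: str
    covariates: tuple[str, ...] = COVARIATES
    level: float = 0.90
    n_chains: int = 4
    n_warmup: int = 2000
    n_iter: int = 2000
    seed: int = 0
    intercept_sd: float = 1.18
    coef_sd: float = 0.5
    re_sd_rate: float = 1.0
    reference_year: int = 2013
    strict_convergence: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.level < 1.0:
            raise ValidationError("interval level must lie in (0,1)")

    def analysis_hash(self) -> str:
        """Hash of every analysis-relevant setting (not the output path)."""
        d = dataclasses.asdict(self)
        d.pop("out_dir")
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _check_converged(report, stage: str, strict: bool) -> None:
    if not report.passed:
        worst_rhat = max(v for v in report.rhat.values() if np.isfinite(v))
        worst_ess = min(v for v in report.ess.values() if np.isfinite(v))
        msg = (
            f"stage {stage!r} failed convergence thresholds "
            f"(max R-hat {worst_rhat:.4f}, min ESS {worst_ess:.0f})"
        )
        if strict:
            raise ConvergenceError(msg)
        logger.warning(msg)


def run_full_analysis(config: RunConfig) -> dict:
    """Execute elicitation → baseline → univariate → multivariable → ELPD.

    Returns a dict of in-memory results; files are written under
    ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.seed)

    # --- prior elicitation -------------------------------------------------
    if config.historical_csv is not None:
        studies = read_historical_csv(config.historical_csv)
        weights = compute_study_weights(studies, config.reference_year)
        pooled = pooled_prior_proportion(studies, weights)
        prior = build_prior_config(
            pooled, config.intercept_sd, config.coef_sd, config.re_sd_rate,
            config.reference_year,
        )
        logger.info("elicited prior: pooled %.4f -> intercept mean %.4f",
                    pooled, prior.intercept_mean)
    else:
        prior = PriorConfig(
            intercept_sd=config.intercept_sd, coef_sd=config.coef_sd,
            re_sd_rate=config.re_sd_rate, reference_year=config.reference_year,
        )
    prior.to_yaml(out / "prior.yaml")
    prior_est = prior_predictive_interval(prior, config.level, seed=seed)

    # --- data --------------------------------------------------------------
    dataset = read_survey_csv(config.survey_csv)
    complete = complete_case_filter(dataset, MODELING_FIELDS)
    logger.info("respondents: %d read, %d complete", len(dataset), len(complete))

    # --- baseline fit ------------------------------------------------------
    spec0 = build_model_spec(complete, [], prior)
    draws0 = sample_posterior(
        spec0, config.n_chains, config.n_warmup, config.n_iter, seed
    )
    report0 = convergence_report(draws0)
    _check_converged(report0, "baseline", config.strict_convergence)
    p_marginal = probability_of_sparing(draws0, "new_province", seed)
    p_median = probability_of_sparing(draws0, "median_province")
    baseline = pd.DataFrame(
        [
            ("p_sparing_new_province", *summarize_vector(p_marginal, config.level)),
            ("p_sparing_median_province", *summarize_vector(p_median, config.level)),
        ],
        columns=["quantity", "mean", "lower", "upper"],
    )
    baseline.to_csv(out / "baseline_summary.csv", index=False)
    report0.to_dataframe().to_csv(out / "baseline_convergence.csv", index=False)
    draws0.save_csv(out / "draws_baseline.csv")

    elpd_results = [psis_loo(pointwise_loglik(draws0, spec0))]
    elpd_labels = ["baseline"]

    # --- univariate comparisons -------------------------------------------
    comp_rows = []
    for i, cov in enumerate(config.covariates):
        res = fit_univariate(
            complete, cov, prior,
            config.n_chains, config.n_warmup, config.n_iter,
            seed=seed + 1 + i, level=config.level,
        )
        _check_converged(res.convergence, f"univariate:{cov}",
                         config.strict_convergence)
        comp_rows.append(
            {
                "covariate": cov,
                "reference_group": res.reference_label,
                "index_group": res.index_label,
                "reference_mean": res.reference_summary[0],
                "reference_lower": res.reference_summary[1],
                "reference_upper": res.reference_summary[2],
                "index_mean": res.index_summary[0],
                "index_lower": res.index_summary[1],
                "index_upper": res.index_summary[2],
                "superiority_probability": res.superiority_probability,
            }
        )
        res.draws.save_csv(out / f"draws_univariate_{cov}.csv")
        # ELPD comparison requires a common observation set: only models on
        # exactly the complete-case rows of the baseline are comparable
        if res.spec.n_obs == spec0.n_obs:
            elpd_results.append(psis_loo(pointwise_loglik(res.draws, res.spec)))
            elpd_labels.append(f"univariate:{cov}")
        else:
            logger.warning(
                "model univariate:%s uses %d observations (baseline %d); "
                "excluded from the ELPD comparison", cov, res.spec.n_obs, spec0.n_obs,
            )
    comparisons = pd.DataFrame(comp_rows)
    if comp_rows:
        comparisons.to_csv(out / "comparisons.csv", index=False)

    # --- multivariable model ----------------------------------------------
    multi = None
    if len(config.covariates) >= 2:
        multi = fit_multivariable(
            complete, list(config.covariates), prior,
            config.n_chains, config.n_warmup, config.n_iter,
            seed=seed + 101, level=config.level,
        )
        _check_converged(multi.convergence, "multivariable",
                         config.strict_convergence)
        rows = [
            {
                "covariate": c,
                "beta_mean": multi.beta_summaries[c][0],
                "beta_lower": multi.beta_summaries[c][1],
                "beta_upper": multi.beta_summaries[c][2],
                "p_beta_positive": multi.superiority[c],
            }
            for c in multi.covariates
        ]
        pd.DataFrame(rows).to_csv(out / "multivariable_summary.csv", index=False)
        multi.draws.save_csv(out / "draws_multivariable.csv")
        if multi.spec.n_obs == spec0.n_obs:
            elpd_results.append(psis_loo(pointwise_loglik(multi.draws, multi.spec)))
            elpd_labels.append("multivariable")
        else:
            logger.warning(
                "multivariable model uses %d observations (baseline %d); "
                "excluded from the ELPD comparison", multi.spec.n_obs, spec0.n_obs,
            )

    # --- ELPD ranking ------------------------------------------------------
    elpd_table = compare_models(elpd_results, elpd_labels)
    elpd_table.to_csv(out / "elpd_comparison.csv", index=False)

    # --- manifest & plain-text summary ------------------------------------
    manifest = {
        "package_version": __version__,
        "seed": seed,
        "config": {k: v for k, v in dataclasses.asdict(config).items()},
        "config_hash": config.analysis_hash(),
        "n_respondents": len(dataset),
        "n_complete": len(complete),
        "prior_interval": list(prior_est.prior_interval),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    lines = [
        f"otobayes {__version__} analysis",
        f"respondents: {len(dataset)} read, {len(complete)} complete cases",
        (
            f"prior: intercept Normal({prior.intercept_mean:.3f}, "
            f"{prior.intercept_sd}), implied {int(config.level*100)}% interval "
            f"[{prior_est.prior_interval[0]:.2f}, {prior_est.prior_interval[1]:.2f}]"
        ),
        (
            "baseline P(opioid-sparing), new province: "
            f"{baseline.iloc[0]['mean']:.3f} "
            f"[{baseline.iloc[0]['lower']:.3f}, {baseline.iloc[0]['upper']:.3f}]"
        ),
    ]
    for row in comp_rows:
        lines.append(
            f"{row['covariate']}: {row['index_group']} "
            f"{row['index_mean']:.2f} vs {row['reference_group']} "
            f"{row['reference_mean']:.2f}; "
            f"P(superiority) = {row['superiority_probability']:.2f}"
        )
    lines.append("ELPD ranking (best first): " + ", ".join(
        f"{r.label} {r.elpd:.1f}" for r in elpd_table.itertuples()
    ))
    (out / "summary.txt").write_text("\n".join(lines) + "\n")

    return {
        "prior": prior,
        "prior_estimate": prior_est,
        "dataset": dataset,
        "complete": complete,
        "baseline_summary": baseline,
        "baseline_draws": draws0,
        "comparisons": comparisons,
        "multivariable": multi,
        "elpd_table": elpd_table,
        "manifest": manifest,
    }
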