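"""Subgroup comparisons: univariate/multivariable fits and superiority probabilities.

A univariate comparison fits the hierarchical model with one dichotomized
covariate and contrasts the two arms at the median province (b = 0): the
reference group's probability is invlogit(α), the index group's
invlogit(α + β).  The posterior probability of superiority is the share of
posterior mass with the index group's probability above the reference
group's, which for this model equals the posterior probability that β > 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .model import (
    ConvergenceReport,
    ModelSpec,
    PosteriorDraws,
    PosteriorSummary,
    build_model_spec,
    convergence_report,
    sample_posterior,
    summarize_vector,
)
from .priors import PriorConfig, invlogit
from .survey import SurveyDataset, covariate_group_labels

__all__ = [
    "ComparisonResult",
    "MultivariableResult",
    "fit_univariate",
    "fit_multivariable",
    "superiority_probability",
]


@dataclass(frozen=True)
class ComparisonResult:
    """Two-group posterior contrast for one covariate."""

    covariate: str
    reference_label: str
    index_label: str
    p_reference: np.ndarray          # per-draw probability, reference arm
    p_index: np.ndarray              # per-draw probability, index arm
    reference_summary: tuple[float, float, float]   # mean, lower, upper
    index_summary: tuple[float, float, float]
    level: float
    superiority_probability: float
    draws: PosteriorDraws
    convergence: ConvergenceReport
    spec: ModelSpec


@dataclass(frozen=True)
class MultivariableResult:
    """Joint fit with several covariates; per-covariate summaries on the odds scale."""

    covariates: tuple[str, ...]
    beta_summaries: dict[str, tuple[float, float, float]]
    superiority: dict[str, float]    # P(beta_k > 0) per covariate
    level: float
    draws: PosteriorDraws
    convergence: ConvergenceReport
    spec: ModelSpec


def superiority_probability(
    draws_a: np.ndarray, draws_b: np.ndarray, paired: bool = True
) -> float:
    """P(A > B) from posterior draw vectors; exact ties count one half.

    Paired: draws share an index (same posterior draw), the usual case for
    two functionals of one fit.  Unpaired: all cross-pairs are compared
    (a rank statistic, used when the two vectors come from separate fits).
    """
    a = np.asarray(draws_a, float).ravel()
    b = np.asarray(draws_b, float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValidationError("superiority_probability needs nonempty draw vectors")
    if paired:
        if a.size != b.size:
            raise ValidationError(
                f"paired comparison needs equal lengths, got {a.size} and {b.size}"
            )
        return float(np.mean((a > b) + 0.5 * (a == b)))
    # unpaired: Mann–Whitney statistic via sorting
    order = np.argsort(b, kind="mergesort")
    bs = b[order]
    higher = np.searchsorted(bs, a, side="left")
    ties = np.searchsorted(bs, a, side="right") - higher
    return float((higher + 0.5 * ties).sum() / (a.size * b.size))


def fit_univariate(
    dataset: SurveyDataset,
    covariate: str,
    prior: PriorConfig,
    n_chains: int = 4,
    n_warmup: int = 2000,
    n_iter: int = 2000,
    seed: int = 0,
    level: float = 0.90,
    **dichotomize_kwargs,
) -> ComparisonResult:
    """Fit intercept + one binary covariate + province random intercepts."""
    spec = build_model_spec(dataset, [covariate], prior, **dichotomize_kwargs)
    x = spec.X[:, 0]
    ref_label, idx_label = covariate_group_labels(covariate)
    for arm, label in ((0.0, ref_label), (1.0, idx_label)):
        if not np.any(x == arm):
            raise ValidationError(
                f"covariate {covariate!r}: group {label!r} has no respondents"
            )
    draws = sample_posterior(spec, n_chains, n_warmup, n_iter, seed)
    report = convergence_report(draws)
    alpha = draws.stacked("alpha")
    beta = draws.stacked(f"beta[{covariate}]")
    p_ref = invlogit(alpha)
    p_idx = invlogit(alpha + beta)
    sup = float(np.mean((beta > 0) + 0.5 * (beta == 0)))
    return ComparisonResult(
        covariate=covariate,
        reference_label=ref_label,
        index_label=idx_label,
        p_reference=p_ref,
        p_index=p_idx,
        reference_summary=summarize_vector(p_ref, level),
        index_summary=summarize_vector(p_idx, level),
        level=float(level),
        superiority_probability=sup,
        draws=draws,
        convergence=report,
        spec=spec,
    )


def fit_multivariable(
    dataset: SurveyDataset,
    covariates: Sequence[str],
    prior: PriorConfig,
    n_chains: int = 4,
    n_warmup: int = 2000,
    n_iter: int = 2000,
    seed: int = 0,
    level: float = 0.90,
    **dichotomize_kwargs,
) -> MultivariableResult:
    """Joint model with several dichotomized covariates (complete cases across all)."""
    if len(covariates) < 2:
        raise ValidationError("fit_multivariable needs at least 2 covariates")
    spec = build_model_spec(dataset, list(covariates), prior, **dichotomize_kwargs)
    # duplicate/collinear columns are only a warning: the proper priors keep
    # the posterior proper
    for i in range(spec.n_covariates):
        for j in range(i + 1, spec.n_covariates):
            if np.array_equal(spec.X[:, i], spec.X[:, j]):
                warnings.warn(
                    f"covariates {covariates[i]!r} and {covariates[j]!r} are "
                    "identical columns; coefficients are only jointly identified",
                    stacklevel=2,
                )
    draws = sample_posterior(spec, n_chains, n_warmup, n_iter, seed)
    report = convergence_report(draws)
    betas = {c: draws.stacked(f"beta[{c}]") for c in covariates}
    return MultivariableResult(
        covariates=tuple(covariates),
        beta_summaries={c: summarize_vector(v, level) for c, v in betas.items()},
        superiority={
            c: float(np.mean((v > 0) + 0.5 * (v == 0))) for c, v in betas.items()
        },
        level=float(level),
        draws=draws,
        convergence=report,
        spec=spec,
    )
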