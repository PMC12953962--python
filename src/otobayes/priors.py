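"""Prior elicitation from historical studies.

The intercept prior of the hierarchical logistic model is built from a small
set of previously published studies reporting the proportion of clinicians
using an opioid-sparing regimen.  Each study is weighted by how large and how
recent it is: study *i* with publication year :math:`y_i`, sample size
:math:`n_i` and reported sparing proportion :math:`p_i` receives a weight
proportional to

.. math::  t_i \\, n_i \\, p_i (1 - p_i), \\qquad t_i = y_i - y_{\\mathrm{ref}},

normalized to sum to one.  The reference year defaults to 2013, the FDA black
box warning against codeine after pediatric adenotonsillectomy, the event
taken to mark the start of the modern prescribing era.  The weighted average
of the :math:`p_i` is mapped to the logit scale and becomes the centre of a
normal prior on the model intercept.

An alternative weighting, inverse-variance times recency
(:math:`w_i \\propto t_i n_i / (p_i(1-p_i))`, the classical meta-analytic
precision weight for a proportion), is available via ``scheme``.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import DomainError, ValidationError

__all__ = [
    "HistoricalStudy",
    "WeightVector",
    "PriorEstimate",
    "PriorConfig",
    "compute_study_weights",
    "pooled_prior_proportion",
    "logit",
    "invlogit",
    "build_prior_config",
    "prior_predictive_interval",
    "read_historical_csv",
    "write_historical_csv",
]

DEFAULT_REFERENCE_YEAR = 2013


@dataclass(frozen=True)
class HistoricalStudy:
    """One historical study feeding the prior.

    Parameters
    ----------
    study_id
        Short label for the study.
    publication_year
        Calendar year of publication; must postdate the reference year.
    sample_size
        Number of respondents/patients in the study, ``>= 1``.
    sparing_proportion
        Reported proportion of opioid-sparing practice, strictly in (0, 1).
    """

    study_id: str
    publication_year: int
    sample_size: int
    sparing_proportion: float

    def __post_init__(self) -> None:
        if self.sample_size < 1:
            raise ValidationError(
                f"study {self.study_id!r}: sample_size must be >= 1, "
                f"got {self.sample_size}"
            )
        if not 0.0 < self.sparing_proportion < 1.0:
            raise ValidationError(
                f"study {self.study_id!r}: sparing_proportion must lie in "
                f"(0, 1), got {self.sparing_proportion}"
            )


@dataclass(frozen=True)
class WeightVector:
    """Normalized study weights; sums to 1 within 1e-12."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if w.ndim != 1 or w.size == 0:
            raise ValidationError("weights must be a nonempty 1-D vector")
        if np.any(w < 0):
            raise ValidationError("weights must be nonnegative")
        if abs(float(w.sum()) - 1.0) > 1e-12:
            raise ValidationError(f"weights must sum to 1, got {w.sum()!r}")

    def __len__(self) -> int:
        return int(self.weights.size)


@dataclass(frozen=True)
class PriorEstimate:
    """Pooled proportion plus the interval implied by the prior by simulation."""

    pooled_proportion: float
    logit_mean: float
    interval_level: float
    prior_interval: tuple[float, float]


@dataclass(frozen=True)
class PriorConfig:
    """Hyperparameters of the hierarchical Bernoulli-logit model priors.

    intercept: Normal(intercept_mean, intercept_sd) on the logit scale;
    coefficients: Normal(coef_mean, coef_sd) each;
    random-intercept SD: Exponential(re_sd_rate).
    """

    intercept_mean: float = 0.4473122180436648  # logit(0.61)
    intercept_sd: float = 1.18
    coef_mean: float = 0.0
    coef_sd: float = 0.5
    re_sd_rate: float = 1.0
    reference_year: int = DEFAULT_REFERENCE_YEAR

    def __post_init__(self) -> None:
        if self.intercept_sd <= 0 or self.coef_sd <= 0 or self.re_sd_rate <= 0:
            raise ValidationError(
                "intercept_sd, coef_sd and re_sd_rate must all be strictly "
                f"positive, got {self.intercept_sd}, {self.coef_sd}, "
                f"{self.re_sd_rate}"
            )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PriorConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ValidationError(f"prior config {path}: expected a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"prior config {path}: unknown keys {sorted(unknown)}")
        return cls(**raw)


def compute_study_weights(
    studies: Sequence[HistoricalStudy],
    reference_year: int = DEFAULT_REFERENCE_YEAR,
    scheme: str = "recency_size",
) -> WeightVector:
    """Normalized evidence weights for a set of historical studies.

    ``scheme="recency_size"`` (default): weight_i ∝ t_i·n_i·p_i·(1−p_i).
    ``scheme="inverse_variance"``: weight_i ∝ t_i·n_i/(p_i·(1−p_i)), the
    precision-weighting used in standard meta-analysis of proportions, kept
    as a documented alternative.
    """
    if len(studies) == 0:
        raise ValidationError("need at least one historical study")
    for s in studies:
        if s.publication_year <= reference_year:
            raise DomainError(
                f"study {s.study_id!r} published in {s.publication_year}, "
                f"not after the reference year {reference_year}"
            )
    t = np.array([s.publication_year - reference_year for s in studies], float)
    n = np.array([s.sample_size for s in studies], float)
    p = np.array([s.sparing_proportion for s in studies], float)
    if scheme == "recency_size":
        raw = t * n * p * (1.0 - p)
    elif scheme == "inverse_variance":
        raw = t * n / (p * (1.0 - p))
    else:
        raise ValidationError(f"unknown weighting scheme {scheme!r}")
    return WeightVector(raw / raw.sum())


def pooled_prior_proportion(
    studies: Sequence[HistoricalStudy], weights: WeightVector
) -> float:
    """Weighted average Σ w_i p_i of the reported sparing proportions."""
    if len(weights) != len(studies):
        raise ValidationError(
            f"{len(weights)} weights for {len(studies)} studies"
        )
    p = np.array([s.sparing_proportion for s in studies], float)
    pooled = float(np.dot(weights.weights, p))
    # convex combination of values in (0,1): strictly inside by construction
    return pooled


def logit(p):
    """Natural-log odds, ln(p/(1−p)); domain the open unit interval."""
    arr = np.asarray(p, dtype=float)
    if np.any(arr <= 0.0) or np.any(arr >= 1.0):
        raise DomainError(f"logit requires 0 < p < 1, got {p!r}")
    out = np.log(arr) - np.log1p(-arr)
    return float(out) if np.isscalar(p) or arr.ndim == 0 else out


def invlogit(x):
    """Inverse logit 1/(1+exp(−x)), overflow-safe for any real x."""
    arr = np.asarray(x, dtype=float)
    out = np.empty_like(arr)
    pos = arr >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-arr[pos]))
    ex = np.exp(arr[~pos])
    out[~pos] = ex / (1.0 + ex)
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


def build_prior_config(
    pooled: float,
    intercept_sd: float = 1.18,
    coef_sd: float = 0.5,
    re_sd_rate: float = 1.0,
    reference_year: int = DEFAULT_REFERENCE_YEAR,
) -> PriorConfig:
    """Centre the intercept prior at logit(pooled); other fields copied."""
    if not 0.0 < pooled < 1.0:
        raise ValidationError(f"pooled proportion must lie in (0,1), got {pooled}")
    return PriorConfig(
        intercept_mean=float(logit(pooled)),
        intercept_sd=float(intercept_sd),
        coef_sd=float(coef_sd),
        re_sd_rate=float(re_sd_rate),
        reference_year=int(reference_year),
    )


def prior_predictive_interval(
    config: PriorConfig,
    level: float = 0.90,
    n_draws: int = 200_000,
    seed: int = 0,
) -> PriorEstimate:
    """Equal-tailed Monte-Carlo interval of the implied prior probability.

    Simulates invlogit(μ + b) with μ ~ Normal(intercept_mean, intercept_sd),
    σ ~ Exponential(re_sd_rate) and b | σ ~ Normal(0, σ), i.e. the prior on
    the sparing probability of a fresh province before any data.
    """
    if not 0.0 < level < 1.0:
        raise ValidationError(f"level must lie in (0,1), got {level}")
    if n_draws < 1000:
        raise ValidationError(f"n_draws must be >= 1000, got {n_draws}")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x9E3779]))
    mu = rng.normal(config.intercept_mean, config.intercept_sd, n_draws)
    sigma = rng.exponential(1.0 / config.re_sd_rate, n_draws)
    b = rng.normal(0.0, 1.0, n_draws) * sigma
    p = invlogit(mu + b)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(p, [alpha, 1.0 - alpha])
    return PriorEstimate(
        pooled_proportion=float(invlogit(config.intercept_mean)),
        logit_mean=float(config.intercept_mean),
        interval_level=float(level),
        prior_interval=(float(lo), float(hi)),
    )


_HIST_COLUMNS = ["study_id", "publication_year", "sample_size", "sparing_proportion"]


def read_historical_csv(path: str | Path) -> list[HistoricalStudy]:
    """Read historical studies from a UTF-8 CSV with the canonical header."""
    df = pd.read_csv(path)
    if list(df.columns) != _HIST_COLUMNS:
        raise ValidationError(
            f"{path}: expected header {_HIST_COLUMNS}, got {list(df.columns)}"
        )
    studies = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            studies.append(
                HistoricalStudy(
                    study_id=str(row.study_id),
                    publication_year=int(row.publication_year),
                    sample_size=int(row.sample_size),
                    sparing_proportion=float(row.sparing_proportion),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"{path}, line {i}: {exc}") from exc
    return studies


def write_historical_csv(studies: Iterable[HistoricalStudy], path: str | Path) -> None:
    df = pd.DataFrame([dataclasses.asdict(s) for s in studies], columns=_HIST_COLUMNS)
    df.to_csv(path, index=False)
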