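"""Hierarchical Bernoulli-logit model with province random intercepts.

The model for respondent i in province j(i):

.. math::

    y_i \\sim \\mathrm{Bernoulli}(p_i), \\qquad
    \\mathrm{logit}(p_i) = \\alpha + x_i^\\top \\beta + b_{j(i)},

with priors α ~ Normal(m_α, s_α), β_k ~ Normal(0, s_β),
σ ~ Exponential(λ) and b_j | σ ~ Normal(0, σ).  The intercept prior is
elicited from historical studies (see :mod:`otobayes.priors`).

Sampling uses componentwise adaptive random-walk Metropolis on the
unconstrained vector (α, β, log σ, b); the log-σ transform contributes the
usual Jacobian term, so σ = 0 is unreachable and every retained draw has
σ > 0.  Because covariates are binary and provinces few, the likelihood is
evaluated on (province × covariate-pattern) sufficient-statistic cells,
which is algebraically identical to the per-respondent sum.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .priors import PriorConfig, invlogit
from .survey import SurveyDataset, dichotomize

__all__ = [
    "ModelSpec",
    "ModelParams",
    "PosteriorDraws",
    "ConvergenceReport",
    "PosteriorSummary",
    "build_model_spec",
    "log_likelihood",
    "log_prior",
    "sample_posterior",
    "rhat",
    "ess",
    "convergence_report",
    "summarize",
    "summarize_vector",
    "probability_of_sparing",
]

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class ModelSpec:
    """Complete-case design: outcome, binary covariates, province of each row."""

    y: np.ndarray                      # (n,) 0/1
    X: np.ndarray                      # (n, k) binary columns
    provinces: np.ndarray              # (n,) contiguous ints 0..J-1
    prior: PriorConfig
    covariate_names: tuple[str, ...] = ()
    province_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        y = np.asarray(self.y, dtype=float)
        X = np.asarray(self.X, dtype=float)
        prov = np.asarray(self.provinces, dtype=int)
        if X.ndim != 2:
            X = X.reshape(len(y), -1)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "provinces", prov)
        n = y.shape[0]
        if X.shape[0] != n or prov.shape[0] != n:
            raise ValidationError(
                f"length mismatch: y={n}, X={X.shape[0]}, provinces={prov.shape[0]}"
            )
        if np.any(np.isnan(y)) or np.any(np.isnan(X)):
            raise ValidationError("ModelSpec requires complete cases (no NaN)")
        if not np.all(np.isin(y, (0.0, 1.0))):
            raise ValidationError("outcome must be binary 0/1")
        if n > 0:
            J = int(prov.max()) + 1
            if self.province_labels:
                # explicit province set: indices must fit it, but a level may
                # be empty (e.g. during leave-one-out refits)
                if prov.min() < 0 or J > len(self.province_labels):
                    raise ValidationError(
                        "province integers must index province_labels"
                    )
            elif prov.min() < 0 or len(np.unique(prov)) != J:
                raise ValidationError("province integers must be contiguous from 0")
        else:
            J = 0
        if self.covariate_names and len(self.covariate_names) != X.shape[1]:
            raise ValidationError("covariate_names length mismatch")
        object.__setattr__(self, "_n_provinces", int(max(J, len(self.province_labels))))
        # sufficient-statistic cells: unique (province, x-pattern) rows
        if n > 0:
            design = np.column_stack([prov.astype(float), X])
            cells, inverse = np.unique(design, axis=0, return_inverse=True)
            counts = np.bincount(inverse, minlength=cells.shape[0]).astype(float)
            successes = np.bincount(
                inverse, weights=y, minlength=cells.shape[0]
            ).astype(float)
            object.__setattr__(self, "_cell_prov", cells[:, 0].astype(int))
            object.__setattr__(self, "_cell_X", cells[:, 1:])
            object.__setattr__(self, "_cell_n", counts)
            object.__setattr__(self, "_cell_s", successes)
        else:
            k = X.shape[1]
            object.__setattr__(self, "_cell_prov", np.zeros(0, dtype=int))
            object.__setattr__(self, "_cell_X", np.zeros((0, k)))
            object.__setattr__(self, "_cell_n", np.zeros(0))
            object.__setattr__(self, "_cell_s", np.zeros(0))

    @property
    def n_obs(self) -> int:
        return int(self.y.shape[0])

    @property
    def n_covariates(self) -> int:
        return int(self.X.shape[1])

    @property
    def n_provinces(self) -> int:
        return int(self._n_provinces)


@dataclass(frozen=True)
class ModelParams:
    """One point in parameter space: intercept, coefficients, RE SD, province effects."""

    alpha: float
    beta: np.ndarray
    sigma: float
    b: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "beta", np.atleast_1d(np.asarray(self.beta, float)))
        object.__setattr__(self, "b", np.atleast_1d(np.asarray(self.b, float))
                           if np.size(self.b) else np.zeros(0))


def build_model_spec(
    dataset: SurveyDataset,
    covariates: Sequence[str],
    prior: PriorConfig,
    **dichotomize_kwargs,
) -> ModelSpec:
    """Design matrix from a survey dataset: dichotomize + complete cases.

    Rows missing the outcome, the province, or any requested covariate are
    dropped; the province index is rebuilt over the retained rows.
    """
    y_raw = np.array(
        [np.nan if r.opioid_sparing is None else float(r.opioid_sparing)
         for r in dataset]
    )
    prov_raw = [r.province for r in dataset]
    cols = [dichotomize(dataset, c, **dichotomize_kwargs) for c in covariates]
    X_raw = np.column_stack(cols) if cols else np.zeros((len(dataset), 0))
    keep = ~np.isnan(y_raw)
    keep &= np.array([p is not None for p in prov_raw])
    if X_raw.shape[1]:
        keep &= ~np.isnan(X_raw).any(axis=1)
    idx = np.flatnonzero(keep)
    labels = sorted({prov_raw[i] for i in idx})
    pmap = {p: j for j, p in enumerate(labels)}
    return ModelSpec(
        y=y_raw[idx],
        X=X_raw[idx],
        provinces=np.array([pmap[prov_raw[i]] for i in idx], int),
        prior=prior,
        covariate_names=tuple(covariates),
        province_labels=tuple(labels),
    )


def _cell_loglik(eta: np.ndarray, s: np.ndarray, n: np.ndarray) -> float:
    # sum_cells [ s*eta - n*log(1+e^eta) ], stable for |eta| up to ~700+
    return float(np.dot(s, eta) - np.dot(n, np.logaddexp(0.0, eta)))


def log_likelihood(params: ModelParams, spec: ModelSpec) -> float:
    """Bernoulli-logit log likelihood Σ y log p + (1−y) log(1−p)."""
    if params.beta.shape[0] != spec.n_covariates:
        raise ValidationError(
            f"beta has {params.beta.shape[0]} entries for {spec.n_covariates} covariates"
        )
    if params.b.shape[0] < spec.n_provinces:
        raise ValidationError(
            f"b has {params.b.shape[0]} entries for {spec.n_provinces} provinces"
        )
    if spec.n_obs == 0:
        return 0.0
    eta = params.alpha + spec._cell_X @ params.beta + params.b[spec._cell_prov]
    return _cell_loglik(eta, spec._cell_s, spec._cell_n)


def log_prior(params: ModelParams, prior: PriorConfig) -> float:
    """Joint log prior density (up to an additive constant in the data).

    Returns −inf (rejection) when σ ≤ 0 rather than raising.
    """
    if params.sigma <= 0.0:
        return -math.inf
    lp = (
        -0.5 * ((params.alpha - prior.intercept_mean) / prior.intercept_sd) ** 2
        - math.log(prior.intercept_sd) - 0.5 * _LOG_2PI
    )
    if params.beta.size:
        z = (params.beta - prior.coef_mean) / prior.coef_sd
        lp += float(
            -0.5 * np.dot(z, z)
            - params.beta.size * (math.log(prior.coef_sd) + 0.5 * _LOG_2PI)
        )
    lp += math.log(prior.re_sd_rate) - prior.re_sd_rate * params.sigma
    if params.b.size:
        lp += float(
            -0.5 * np.dot(params.b, params.b) / params.sigma**2
            - params.b.size * (math.log(params.sigma) + 0.5 * _LOG_2PI)
        )
    return lp


# ---------------------------------------------------------------------------
# sampler


def _make_logpost(spec: ModelSpec) -> tuple[Callable[[np.ndarray], float], int, int]:
    """Log posterior on the unconstrained vector θ = (α, β, log σ, z).

    Non-centered parameterization of the random intercepts, b = σ·z with
    z_j ~ Normal(0, 1), which removes the funnel between σ and b at the few
    observations per province this model sees.  The log-σ transform
    contributes the usual Jacobian term.  Returns (function, k, J).
    """
    k = spec.n_covariates
    J = spec.n_provinces
    prior = spec.prior
    cX, cprov = spec._cell_X, spec._cell_prov
    cs, cn = spec._cell_s, spec._cell_n
    im, isd = prior.intercept_mean, prior.intercept_sd
    cm, csd = prior.coef_mean, prior.coef_sd
    rate = prior.re_sd_rate

    def logpost(theta: np.ndarray) -> float:
        alpha = theta[0]
        beta = theta[1 : 1 + k]
        log_sigma = theta[1 + k]
        z = theta[2 + k :]
        sigma = math.exp(log_sigma)
        lp = -0.5 * ((alpha - im) / isd) ** 2
        if k:
            u = (beta - cm) / csd
            lp += -0.5 * float(np.dot(u, u))
        lp += -rate * sigma + log_sigma  # Exp(rate) prior + Jacobian d sigma/d log sigma
        if J:
            lp += -0.5 * float(np.dot(z, z))
        if cn.size:
            b = sigma * z
            eta = alpha + b[cprov] if k == 0 else alpha + cX @ beta + b[cprov]
            lp += float(np.dot(cs, eta) - np.dot(cn, np.logaddexp(0.0, eta)))
        return lp

    return logpost, k, J


@dataclass
class PosteriorDraws:
    """Post-warmup MCMC draws, kept per chain.

    ``draws[name]`` has shape (chains, iterations); parameter names are
    ``alpha``, ``beta[<covariate>]``, ``sigma`` and ``b[<province>]``.
    """

    draws: dict[str, np.ndarray]
    seed: int
    n_warmup: int
    acceptance: np.ndarray            # (chains,) mean acceptance rate
    covariate_names: tuple[str, ...] = ()
    province_labels: tuple[str, ...] = ()

    @property
    def param_names(self) -> list[str]:
        return list(self.draws)

    @property
    def n_chains(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    @property
    def n_iter(self) -> int:
        return next(iter(self.draws.values())).shape[1]

    @property
    def n_draws(self) -> int:
        return self.n_chains * self.n_iter

    def stacked(self, name: str) -> np.ndarray:
        """All chains concatenated, shape (chains*iterations,)."""
        return self.draws[name].reshape(-1)

    def param_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(alpha (S,), beta (S,k), sigma (S,), b (S,J)) over stacked draws."""
        alpha = self.stacked("alpha")
        beta = (
            np.column_stack([self.stacked(f"beta[{c}]") for c in self.covariate_names])
            if self.covariate_names else np.zeros((alpha.size, 0))
        )
        sigma = self.stacked("sigma")
        b = (
            np.column_stack([self.stacked(f"b[{p}]") for p in self.province_labels])
            if self.province_labels else np.zeros((alpha.size, 0))
        )
        return alpha, beta, sigma, b

    def to_dataframe(self) -> pd.DataFrame:
        frames = []
        for name, arr in self.draws.items():
            C, N = arr.shape
            frames.append(
                pd.DataFrame(
                    {
                        "chain": np.repeat(np.arange(C), N),
                        "iteration": np.tile(np.arange(N), C),
                        "parameter": name,
                        "value": arr.reshape(-1),
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    def save_csv(self, path: str | Path) -> None:
        df = self.to_dataframe()
        # shortest round-trip decimal form so reload is bit-identical
        df["value"] = df["value"].map(lambda v: repr(float(v)))
        df.to_csv(path, index=False)

    @classmethod
    def load_csv(cls, path: str | Path) -> "PosteriorDraws":
        df = pd.read_csv(path, float_precision="round_trip")
        draws: dict[str, np.ndarray] = {}
        for name, grp in df.groupby("parameter", sort=False):
            C = grp["chain"].max() + 1
            N = grp["iteration"].max() + 1
            arr = np.empty((C, N))
            arr[grp["chain"].to_numpy(), grp["iteration"].to_numpy()] = (
                grp["value"].to_numpy(float)
            )
            draws[name] = arr
        cov = tuple(
            n[5:-1] for n in draws if n.startswith("beta[")
        )
        provs = tuple(n[2:-1] for n in draws if n.startswith("b["))
        return cls(
            draws=draws, seed=-1, n_warmup=0,
            acceptance=np.full(next(iter(draws.values())).shape[0], np.nan),
            covariate_names=cov, province_labels=provs,
        )


def _run_chain(
    logpost: Callable[[np.ndarray], float],
    d: int,
    n_warmup: int,
    n_iter: int,
    rng: np.random.Generator,
    init: np.ndarray,
    k: int,
    J: int,
) -> tuple[np.ndarray, float]:
    """One componentwise adaptive RWM chain; returns kept draws and acceptance.

    Besides the per-coordinate updates, each iteration makes two
    likelihood-invariant group moves that target the posterior's stiff
    directions once the data are informative: a translation (α shifted by δ,
    every z_j moved by −δ/σ, so the linear predictor is unchanged) and a
    rescaling (log σ shifted by δ, every z_j scaled by e^{−δ}, so b = σz is
    unchanged; the deterministic map contributes a −Jδ log-Jacobian).
    Axis-aligned proposals alone mix these directions very slowly.
    """
    theta = init.copy()
    lp = logpost(theta)
    n_moves = d + (2 if J > 0 else 0)   # group moves adapted like coordinates
    log_scales = np.full(n_moves, math.log(0.5))
    kept = np.empty((n_iter, d))
    accepts = 0
    proposals = 0
    batch_acc = np.zeros(n_moves)
    batch_size = 50
    batch_no = 0
    total = n_warmup + n_iter
    for it in range(total):
        for j in range(d):
            prop = theta[j] + math.exp(log_scales[j]) * rng.standard_normal()
            old = theta[j]
            theta[j] = prop
            lp_new = logpost(theta)
            if math.log(rng.random()) < lp_new - lp:
                lp = lp_new
                if it >= n_warmup:
                    accepts += 1
                batch_acc[j] += 1
            else:
                theta[j] = old
            if it >= n_warmup:
                proposals += 1
        if J > 0:
            # translation move
            delta = math.exp(log_scales[d]) * rng.standard_normal()
            old_theta = theta.copy()
            sigma = math.exp(theta[1 + k])
            theta[0] += delta
            theta[2 + k :] -= delta / sigma
            lp_new = logpost(theta)
            if math.log(rng.random()) < lp_new - lp:
                lp = lp_new
                if it >= n_warmup:
                    accepts += 1
                batch_acc[d] += 1
            else:
                theta = old_theta
            if it >= n_warmup:
                proposals += 1
            # rescaling move (b = sigma * z held fixed)
            delta = math.exp(log_scales[d + 1]) * rng.standard_normal()
            old_theta = theta.copy()
            theta[1 + k] += delta
            theta[2 + k :] *= math.exp(-delta)
            lp_new = logpost(theta)
            if math.log(rng.random()) < lp_new - lp - J * delta:
                lp = lp_new
                if it >= n_warmup:
                    accepts += 1
                batch_acc[d + 1] += 1
            else:
                theta = old_theta
            if it >= n_warmup:
                proposals += 1
        if it < n_warmup and (it + 1) % batch_size == 0:
            batch_no += 1
            rates = batch_acc / batch_size
            # Robbins–Monro step toward ~35% acceptance per move
            log_scales += (rates - 0.35) / math.sqrt(batch_no)
            batch_acc[:] = 0.0
        if it >= n_warmup:
            kept[it - n_warmup] = theta
    return kept, accepts / max(proposals, 1)


def sample_posterior(
    spec: ModelSpec,
    n_chains: int = 4,
    n_warmup: int = 2000,
    n_iter: int = 2000,
    seed: int = 0,
) -> PosteriorDraws:
    """Draw from the posterior of the hierarchical model.

    Chains are seeded independently from ``(seed, chain_index)``; the run is
    bit-reproducible under a fixed seed.  Convergence is *not* checked here —
    call :func:`convergence_report` (as the pipeline does).
    """
    if n_chains < 2:
        raise ValidationError("need at least 2 chains for split-R-hat diagnostics")
    logpost, k, J = _make_logpost(spec)
    d = 2 + k + J
    prior = spec.prior
    chains = []
    acc = []
    for c in range(n_chains):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), c]))
        init = np.zeros(d)
        init[0] = prior.intercept_mean + 0.5 * rng.standard_normal()
        init[1 : 1 + k] = 0.25 * rng.standard_normal(k)
        init[1 + k] = math.log(0.5) + 0.3 * rng.standard_normal()
        init[2 + k :] = 0.1 * rng.standard_normal(J)
        kept, a = _run_chain(logpost, d, n_warmup, n_iter, rng, init, k, J)
        chains.append(kept)
        acc.append(a)
    stacked = np.stack(chains)                     # (C, N, d)
    cov_names = spec.covariate_names or tuple(f"x{i}" for i in range(k))
    prov_labels = spec.province_labels or tuple(str(j) for j in range(J))
    draws: dict[str, np.ndarray] = {"alpha": stacked[:, :, 0]}
    for i, name in enumerate(cov_names):
        draws[f"beta[{name}]"] = stacked[:, :, 1 + i]
    sigma = np.exp(stacked[:, :, 1 + k])
    draws["sigma"] = sigma
    for j, name in enumerate(prov_labels):
        draws[f"b[{name}]"] = sigma * stacked[:, :, 2 + k + j]
    return PosteriorDraws(
        draws=draws,
        seed=int(seed),
        n_warmup=int(n_warmup),
        acceptance=np.array(acc),
        covariate_names=tuple(cov_names),
        province_labels=tuple(prov_labels),
    )


# ---------------------------------------------------------------------------
# diagnostics


def _split_chains(arr: np.ndarray) -> np.ndarray:
    """(C, N) → (2C, N//2), dropping a trailing odd draw."""
    C, N = arr.shape
    half = N // 2
    return np.concatenate([arr[:, :half], arr[:, half : 2 * half]], axis=0)


def _rhat_single(arr: np.ndarray) -> float:
    """Split-chain potential scale reduction factor for one parameter."""
    sp = _split_chains(arr)
    m, n = sp.shape
    if n < 2:
        return float("nan")
    means = sp.mean(axis=1)
    variances = sp.var(axis=1, ddof=1)
    W = variances.mean()
    B = n * means.var(ddof=1)
    if W == 0.0:
        # identical constant chains: no evidence of non-convergence; constant
        # chains at different levels: unbounded disagreement
        return 1.0 if B == 0.0 else float("inf")
    var_plus = (n - 1) / n * W + B / n
    return float(math.sqrt(var_plus / W))


def _ess_single(arr: np.ndarray) -> float:
    """Effective sample size via chain-averaged autocorrelations.

    Autocovariances per split chain by FFT; correlations summed in Geyer
    pairs, truncated at the first negative pair sum.
    """
    sp = _split_chains(arr)
    m, n = sp.shape
    if n < 2:
        return float("nan")
    variances = sp.var(axis=1, ddof=1)
    W = variances.mean()
    B = n * sp.mean(axis=1).var(ddof=1) if m > 1 else 0.0
    var_plus = (n - 1) / n * W + B / n
    if var_plus == 0.0:
        return float("nan")
    # per-chain autocovariance via FFT
    centered = sp - sp.mean(axis=1, keepdims=True)
    size = 2 ** math.ceil(math.log2(2 * n))
    f = np.fft.rfft(centered, size, axis=1)
    acov = np.fft.irfft(f * np.conj(f), size, axis=1)[:, :n].real / n
    mean_acov = acov.mean(axis=0)
    rho = 1.0 - (W - mean_acov) / var_plus
    rho[0] = 1.0
    # Geyer initial positive sequence on pair sums
    tau = 0.0
    t = 0
    prev_pair = math.inf
    while t + 1 < n:
        pair = rho[t] + rho[t + 1]
        if pair < 0.0:
            break
        pair = min(pair, prev_pair)  # initial monotone sequence
        tau += pair
        prev_pair = pair
        t += 2
    tau = max(2.0 * tau - 1.0, 1.0 / math.log10(m * n + 10))
    return float(min(m * n / tau, m * n))


@dataclass(frozen=True)
class ConvergenceReport:
    """Split-R-hat and effective sample size per parameter plus a pass flag."""

    rhat: dict[str, float]
    ess: dict[str, float]
    passed: bool
    rhat_threshold: float
    ess_floor: float
    degenerate: tuple[str, ...] = ()

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parameter": list(self.rhat),
                "rhat": list(self.rhat.values()),
                "ess": [self.ess[p] for p in self.rhat],
            }
        )


def rhat(draws: PosteriorDraws) -> dict[str, float]:
    """Split-chain Gelman–Rubin statistic per parameter."""
    return {name: _rhat_single(arr) for name, arr in draws.draws.items()}


def ess(draws: PosteriorDraws) -> dict[str, float]:
    """Effective sample size per parameter."""
    return {name: _ess_single(arr) for name, arr in draws.draws.items()}


def convergence_report(
    draws: PosteriorDraws,
    rhat_threshold: float = 1.01,
    ess_floor: float = 400.0,
) -> ConvergenceReport:
    if draws.n_chains < 2 or draws.n_iter < 4:
        raise ValidationError("diagnostics need >= 2 chains and >= 4 draws per chain")
    degenerate = []
    rh = {}
    for name, arr in draws.draws.items():
        sp = _split_chains(arr)
        if np.all(sp.var(axis=1, ddof=1) == 0.0):
            degenerate.append(name)
            warnings.warn(
                f"parameter {name!r}: zero within-chain variance (degenerate chains)",
                stacklevel=2,
            )
        rh[name] = _rhat_single(arr)
    es = ess(draws)
    finite_rh = [v for v in rh.values() if np.isfinite(v)]
    finite_es = [v for v in es.values() if np.isfinite(v)]
    passed = bool(
        finite_rh
        and max(finite_rh) < rhat_threshold
        and finite_es
        and min(finite_es) >= ess_floor
    )
    return ConvergenceReport(
        rhat=rh, ess=es, passed=passed,
        rhat_threshold=rhat_threshold, ess_floor=ess_floor,
        degenerate=tuple(degenerate),
    )


# ---------------------------------------------------------------------------
# summaries


@dataclass(frozen=True)
class PosteriorSummary:
    """Posterior mean and equal-tailed credible interval per quantity."""

    level: float
    table: pd.DataFrame  # columns: quantity, mean, lower, upper

    def row(self, quantity: str) -> tuple[float, float, float]:
        r = self.table.set_index("quantity").loc[quantity]
        return float(r["mean"]), float(r["lower"]), float(r["upper"])


def summarize_vector(values: np.ndarray, level: float = 0.90) -> tuple[float, float, float]:
    """(mean, lower, upper) equal-tailed at ``level``, linear-interpolated quantiles."""
    if not 0.0 < level < 1.0:
        raise ValidationError(f"level must lie in (0,1), got {level}")
    v = np.asarray(values, float)
    if v.size == 0:
        raise ValidationError("cannot summarize an empty draw vector")
    a = (1.0 - level) / 2.0
    lo, hi = np.quantile(v, [a, 1.0 - a])
    return float(v.mean()), float(lo), float(hi)


def summarize(
    draws: PosteriorDraws,
    level: float = 0.90,
    functionals: Optional[dict[str, Callable[[PosteriorDraws], np.ndarray]]] = None,
) -> PosteriorSummary:
    """Summaries for every parameter plus any requested derived functionals."""
    rows = []
    for name in draws.param_names:
        m, lo, hi = summarize_vector(draws.stacked(name), level)
        rows.append((name, m, lo, hi))
    for name, fn in (functionals or {}).items():
        m, lo, hi = summarize_vector(np.asarray(fn(draws), float), level)
        rows.append((name, m, lo, hi))
    return PosteriorSummary(
        level=float(level),
        table=pd.DataFrame(rows, columns=["quantity", "mean", "lower", "upper"]),
    )


def probability_of_sparing(
    draws: PosteriorDraws,
    mode: str = "new_province",
    seed: int = 0,
) -> np.ndarray:
    """Per-draw probability of opioid-sparing prescribing.

    ``median_province``: invlogit(α), the probability at b = 0 (the median of
    the random-intercept distribution).  ``new_province``: invlogit(α + b*)
    with fresh b* ~ Normal(0, σ_draw), the marginal probability for a
    previously unseen province; this averages over geographic variability
    and is wider, hence the package's headline functional.
    """
    alpha = draws.stacked("alpha")
    if mode == "median_province":
        return invlogit(alpha)
    if mode == "new_province":
        sigma = draws.stacked("sigma")
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xB0B]))
        return invlogit(alpha + sigma * rng.standard_normal(alpha.size))
    raise ValidationError(f"unknown mode {mode!r}")
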