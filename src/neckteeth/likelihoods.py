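"""Model likelihoods: bivariate ordinal+binomial defense traits and the
zero-truncated multivariate Gaussian morphometrics, plus weakly informative
priors.

Pedestal classes follow a cumulative-logit model with two ordered
thresholds, P(class <= k) = logistic(tau_k - eta); neckteeth counts are a
quintuple binomial trial with logit link. The pedestal linear predictor
carries no intercept: the thresholds play that role and an intercept would
be unidentified against them. Both responses receive per-mother random
intercepts, reflecting the clutch structure of the experiments.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from scipy.special import gammaln, log_expit

from .design import DesignSpec, build_design_matrix

__all__ = [
    "DefenseParams",
    "MorphoParams",
    "PriorSpec",
    "ordinal_category_probs",
    "ordinal_loglik",
    "binomial_count_loglik",
    "defense_joint_loglik",
    "positive_orthant_logprob",
    "truncated_mvn_loglik",
    "morpho_loglik",
    "log_prior",
]

logger = logging.getLogger(__name__)

LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


def _check_tau(tau: Sequence[float]) -> np.ndarray:
    tau = np.asarray(tau, dtype=float)
    if tau.shape != (2,) or not tau[0] < tau[1]:
        raise ValueError(f"thresholds must satisfy tau1 < tau2, got {tau}")
    return tau


def ordinal_category_probs(eta, tau) -> np.ndarray:
    """Probabilities over (A, B, C) under the cumulative-logit model.

    ``eta`` may be scalar or an array; the last axis of the result indexes
    the three categories. Increasing ``eta`` shifts mass toward C.
    """
    tau = _check_tau(tau)
    eta = np.asarray(eta, dtype=float)
    lp = np.stack(
        [
            np.exp(log_expit(tau[0] - eta)),
            np.exp(log_expit(tau[1] - eta)) - np.exp(log_expit(tau[0] - eta)),
            np.exp(log_expit(eta - tau[1])),
        ],
        axis=-1,
    )
    return lp


def ordinal_loglik(category, eta, tau) -> np.ndarray:
    """Log probability of ordinal categories coded 0 (A), 1 (B), 2 (C).

    Numerically stable in the tails via log-logistic identities:
    log[s(b) - s(a)] = log s(b) + log s(-a) + log(1 - e^(a-b)) for a < b.
    """
    tau = _check_tau(tau)
    category = np.asarray(category)
    eta = np.asarray(eta, dtype=float)
    log_pa = log_expit(tau[0] - eta)
    log_pc = log_expit(eta - tau[1])
    log_pb = (
        log_expit(tau[1] - eta)
        + log_expit(eta - tau[0])
        + math.log1p(-math.exp(tau[0] - tau[1]))
    )
    out = np.select([category == 0, category == 1], [log_pa, log_pb], default=log_pc)
    return out


def binomial_count_loglik(k, eta, trials: int = 5) -> np.ndarray:
    """Binomial(trials, logistic(eta)) log-pmf of count ``k``."""
    k = np.asarray(k)
    if np.any((k < 0) | (k > trials)):
        raise ValueError(f"count outside 0..{trials}")
    eta = np.asarray(eta, dtype=float)
    log_binom = gammaln(trials + 1) - gammaln(k + 1) - gammaln(trials - k + 1)
    return log_binom + k * log_expit(eta) + (trials - k) * log_expit(-eta)


@dataclass
class DefenseParams:
    """Parameters of the bivariate defense-trait model.

    ``beta_n`` pairs with the full design matrix (intercept included);
    ``beta_p`` with the design matrix minus its intercept column. ``u_n``
    and ``u_p`` are per-mother random intercepts aligned with ``mothers``.
    """

    beta_n: np.ndarray
    beta_p: np.ndarray
    tau: np.ndarray
    mothers: tuple[str, ...]
    u_n: np.ndarray
    u_p: np.ndarray
    sigma_n: float = 1.0
    sigma_p: float = 1.0

    def __post_init__(self) -> None:
        self.beta_n = np.asarray(self.beta_n, dtype=float)
        self.beta_p = np.asarray(self.beta_p, dtype=float)
        self.tau = _check_tau(self.tau)
        self.u_n = np.asarray(self.u_n, dtype=float)
        self.u_p = np.asarray(self.u_p, dtype=float)
        if not (self.sigma_n > 0 and self.sigma_p > 0):
            raise ValueError("random-effect scales must be positive")
        if len(self.mothers) != len(self.u_n) or len(self.mothers) != len(self.u_p):
            raise ValueError("mothers and random-effect vectors must align")


def _mother_indices(records, mothers: Sequence[str]) -> np.ndarray:
    lookup = {m: i for i, m in enumerate(mothers)}
    idx = []
    for r in records:
        uid = r.mother_uid if hasattr(r, "mother_uid") else r["mother_uid"]
        if uid not in lookup:
            raise KeyError(f"unknown mother_uid {uid!r}: no random-effect entry")
        idx.append(lookup[uid])
    return np.asarray(idx, dtype=int)


def defense_joint_loglik(
    records,
    params: DefenseParams,
    design: DesignSpec,
    include_random_effect_prior: bool = True,
    trials: int = 5,
) -> float:
    """Joint log density of neckteeth counts and pedestal classes.

    Sums the binomial and cumulative-logit log probabilities with linear
    predictors X beta + u[mother]; when ``include_random_effect_prior`` the
    Normal(0, sigma) densities of the random intercepts are added, giving
    the joint over data and random effects.
    """
    records = list(records)
    X, names = build_design_matrix(records, design)
    midx = _mother_indices(records, params.mothers)
    k = np.array([r.neckteeth for r in records])
    ped = np.array([{"A": 0, "B": 1, "C": 2}[r.pedestal] for r in records])

    eta_n = X @ params.beta_n + params.u_n[midx]
    eta_p = X[:, 1:] @ params.beta_p + params.u_p[midx]
    total = float(
        np.sum(binomial_count_loglik(k, eta_n, trials=trials))
        + np.sum(ordinal_loglik(ped, eta_p, params.tau))
    )
    if include_random_effect_prior:
        total += float(
            np.sum(stats.norm.logpdf(params.u_n, scale=params.sigma_n))
            + np.sum(stats.norm.logpdf(params.u_p, scale=params.sigma_p))
        )
    return total


# ---------------------------------------------------------------------------
# Zero-truncated multivariate Gaussian morphometrics
# ---------------------------------------------------------------------------

def _check_cov(cov: np.ndarray) -> np.ndarray:
    cov = np.asarray(cov, dtype=float)
    if cov.ndim == 0:
        cov = cov.reshape(1, 1)
    if not np.allclose(cov, cov.T):
        raise ValueError("covariance must be symmetric")
    try:
        np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError("covariance must be positive definite") from exc
    return cov


def positive_orthant_logprob(mu, cov, abseps: float = 1e-6) -> float:
    """log P(Y > 0 componentwise) for Y ~ N(mu, cov).

    Univariate and independent cases use the normal CDF directly; the
    correlated case uses scipy's deterministic Genz quadrature.
    """
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    cov = _check_cov(cov)
    d = mu.shape[0]
    sd = np.sqrt(np.diag(cov))
    if d == 1 or np.allclose(cov, np.diag(np.diag(cov))):
        return float(np.sum(stats.norm.logcdf(mu / sd)))
    # fixed rng: the Genz quadrature is randomized, and likelihood values
    # must be reproducible for identical inputs
    p = stats.multivariate_normal.cdf(
        np.zeros(d), mean=-mu, cov=cov, abseps=abseps, releps=0.0,
        rng=np.random.default_rng(0),
    )
    p = min(max(float(p), 1e-300), 1.0)
    return math.log(p)


def truncated_mvn_loglik(y, mu, cov, truncated: bool = True) -> float:
    """Log density of the zero-truncated (positive-orthant) Gaussian.

    Returns -inf for observations outside the positive orthant. With
    ``truncated=False`` the normalizing constant is assumed negligible
    (valid when mu is many standard deviations inside the orthant, as for
    the morphometric traits measured here).
    """
    y = np.atleast_1d(np.asarray(y, dtype=float))
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    cov = _check_cov(cov)
    if np.any(y <= 0):
        return -math.inf
    base = float(stats.multivariate_normal(mean=mu, cov=cov).logpdf(y))
    if truncated:
        base -= positive_orthant_logprob(mu, cov)
    return base


@dataclass
class MorphoParams:
    """Parameters of the trivariate morphometric model.

    ``coef`` is (p, 3): one column per trait (body length, body width,
    spina length). ``U`` is (M, 3) per-mother random intercepts with scales
    ``sigma_u``; ``Sigma`` is the 3x3 residual covariance.
    """

    coef: np.ndarray
    mothers: tuple[str, ...]
    U: np.ndarray
    sigma_u: np.ndarray
    Sigma: np.ndarray

    def __post_init__(self) -> None:
        self.coef = np.asarray(self.coef, dtype=float)
        self.U = np.asarray(self.U, dtype=float)
        self.sigma_u = np.asarray(self.sigma_u, dtype=float)
        self.Sigma = _check_cov(self.Sigma)
        if self.U.shape != (len(self.mothers), 3):
            raise ValueError("U must be (n_mothers, 3)")
        if np.any(self.sigma_u <= 0):
            raise ValueError("sigma_u must be positive")


TRAIT_FIELDS = ("body_length", "body_width", "spina_length")


def morpho_loglik(
    records,
    params: MorphoParams,
    design: DesignSpec,
    truncated: bool = True,
    include_random_effect_prior: bool = True,
) -> float:
    """Sum of (marginal) truncated-Gaussian log densities over juveniles.

    Records with missing trait components contribute the marginal density
    of their observed sub-vector; records with all three traits missing are
    skipped (counted to the module logger).
    """
    records = list(records)
    X, _ = build_design_matrix(records, design)
    midx = _mother_indices(records, params.mothers)
    mu_all = X @ params.coef + params.U[midx]

    total = 0.0
    skipped = 0
    for i, r in enumerate(records):
        y = np.array(
            [np.nan if getattr(r, f) is None else getattr(r, f) for f in TRAIT_FIELDS],
            dtype=float,
        )
        obs = ~np.isnan(y)
        if not obs.any():
            skipped += 1
            continue
        sub = np.ix_(obs, obs)
        total += truncated_mvn_loglik(y[obs], mu_all[i][obs], params.Sigma[sub], truncated=truncated)
    if skipped:
        logger.info("morpho_loglik: skipped %d record(s) with all traits missing", skipped)
    if include_random_effect_prior:
        total += float(
            np.sum(stats.norm.logpdf(params.U, scale=params.sigma_u[None, :]))
        )
    return float(total)


# ---------------------------------------------------------------------------
# Priors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PriorSpec:
    """Weakly informative priors.

    Coefficients and ordered thresholds: Normal(0, 10). Random-effect
    scales and residual standard deviations: half-Normal(0, 10). Residual
    correlations: uniform over positive-definite correlation matrices.
    """

    coef_sd: float = 10.0
    threshold_sd: float = 10.0
    scale_sd: float = 10.0


def _normal_logpdf(x, sd: float) -> float:
    x = np.asarray(x, dtype=float)
    return float(np.sum(-0.5 * (x / sd) ** 2 - math.log(sd) - LOG_SQRT_2PI))


def _half_normal_logpdf(x, sd: float) -> float:
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        return -math.inf
    return _normal_logpdf(x, sd) + x.size * math.log(2.0)


def log_prior(params, priors: PriorSpec = PriorSpec()) -> float:
    """Log prior density for DefenseParams or MorphoParams.

    Thresholds violating the ordering constraint give -inf.
    """
    if isinstance(params, DefenseParams):
        if not params.tau[0] < params.tau[1]:
            return -math.inf
        return (
            _normal_logpdf(params.beta_n, priors.coef_sd)
            + _normal_logpdf(params.beta_p, priors.coef_sd)
            + _normal_logpdf(params.tau, priors.threshold_sd)
            + _half_normal_logpdf(np.array([params.sigma_n, params.sigma_p]), priors.scale_sd)
        )
    if isinstance(params, MorphoParams):
        sds = np.sqrt(np.diag(params.Sigma))
        return (
            _normal_logpdf(params.coef, priors.coef_sd)
            + _half_normal_logpdf(params.sigma_u, priors.scale_sd)
            + _half_normal_logpdf(sds, priors.scale_sd)
        )
    if np.isscalar(params) or isinstance(params, np.ndarray):
        return _normal_logpdf(params, priors.coef_sd)
    raise TypeError(f"unsupported parameter object: {type(params)!r}")
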