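"""Model classes: bivariate defense-trait model, trivariate morphometric
model, and the pooled kairomone-effectivity model.

Each model is constructed from a tidy table (or record collection), and
``fit`` returns a Results object carrying the posterior draws, convergence
diagnostics, credible intervals, Savage-Dickey evidence ratios, and a
summary table, in the spirit of statsmodels' Model/Results split.

Posterior computation
---------------------
The defense model (binomial-logit neckteeth + cumulative-logit pedestal,
per-mother random intercepts for each response) is sampled by blocked
slice-within-Gibbs: univariate slice updates for coefficients, thresholds,
and log random-effect scales; a vectorized slice update over the
conditionally independent mother intercepts; and an exact Gibbs
recentering move along the intercept-vs-random-effect (and
thresholds-vs-random-effect) direction, the classic slow direction of
hierarchical posteriors (an ancillarity-sufficiency interweaving step).

The morphometric model is Gaussian given the truncation constant, which at
the measured trait scales differs from one by far less than machine
epsilon, so fitting proceeds by conjugate Gibbs blocks for coefficients and
mother effects, Gibbs data augmentation for missing trait components, and
slice updates for the residual covariance (scale/correlation
decomposition) and random-effect scales.
"""
from __future__ import annotations

import logging
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, log_expit

from .data import EffectivityRecord, JuvenileRecord, juveniles_to_frame, effectivity_to_frame
from .design import DesignSpec, build_design_matrix
from .likelihoods import PriorSpec
from .sampling import PRESETS, PosteriorDraws, SamplerConfig, slice_update
from . import evidence as _evidence
from . import diagnostics as _diag

__all__ = [
    "DefenseTraitModel",
    "MorphometricModel",
    "EffectivityModel",
    "DefenseTraitResults",
    "MorphometricResults",
]

logger = logging.getLogger(__name__)

PED_CODE = {"A": 0, "B": 1, "C": 2}


def _resolve_config(config) -> SamplerConfig:
    if isinstance(config, str):
        return PRESETS[config]
    return config


def _vector_slice(g, v, width, rng, max_stepout=30, max_shrink=60):
    """Independent univariate slice updates for a vector of conditionally
    independent components; ``g`` maps a candidate vector to per-component
    conditional log densities."""
    m = v.size
    logg = g(v)
    level = logg - rng.exponential(size=m)
    left = v - width * rng.uniform(size=m)
    right = left + width
    for _ in range(max_stepout):
        active = g(left) > level
        if not active.any():
            break
        left[active] -= width[active] if np.ndim(width) else width
    for _ in range(max_stepout):
        active = g(right) > level
        if not active.any():
            break
        right[active] += width[active] if np.ndim(width) else width
    x = v.copy()
    accepted = np.zeros(m, dtype=bool)
    for _ in range(max_shrink):
        prop = np.where(accepted, x, left + rng.uniform(size=m) * (right - left))
        gp = g(prop)
        newly = ~accepted & (gp > level)
        x[newly] = prop[newly]
        accepted |= newly
        if accepted.all():
            break
        shrink_lo = ~accepted & (prop < v)
        shrink_hi = ~accepted & ~(prop < v)
        left[shrink_lo] = prop[shrink_lo]
        right[shrink_hi] = prop[shrink_hi]
    return x


class _BaseResults:
    """Posterior draws plus the diagnostic/evidence surface shared by all models."""

    def __init__(self, model, draws: PosteriorDraws):
        self.model = model
        self.draws = draws
        self._rhat: dict[str, float] | None = None
        self._ess: dict[str, float] | None = None

    @property
    def fixed_effect_names(self) -> list[str]:
        return list(self.model.fixed_effect_names)

    def rhat(self) -> dict[str, float]:
        if self._rhat is None:
            self._rhat = _diag.rhat_all(self.draws)
        return self._rhat

    def ess(self) -> dict[str, float]:
        if self._ess is None:
            self._ess = _diag.ess_all(self.draws)
        return self._ess

    def max_rhat(self) -> float:
        return max(self.rhat().values())

    def check_identifiability(self, rhat_threshold: float = 1.05) -> tuple[bool, list[str]]:
        return _diag.check_identifiability(self.draws, rhat_threshold)

    def credible_interval(self, parameter: str, level: float = 0.95) -> tuple[float, float]:
        return _diag.credible_interval(self.draws, parameter, level)

    def posterior_median(self, parameter: str) -> float:
        return float(np.median(self.draws.pooled(parameter)))

    def strong_effects(self, level: float = 0.95) -> dict[str, bool]:
        return _evidence.classify_strong_effects(
            self.draws, parameters=self.fixed_effect_names, level=level
        )

    def savage_dickey(self, parameter: str, point: float = 0.0):
        return _evidence.savage_dickey_ratio(
            self.draws, parameter, prior=self.model.priors, point=point
        )

    def summary(self) -> pd.DataFrame:
        return _evidence.effect_summary_table(
            self.draws, parameters=self.fixed_effect_names, prior=self.model.priors
        )

    def plot_forest(self, path=None):
        return _evidence.plot_forest(self.summary(), path=path)


# ===========================================================================
# Bivariate defense-trait model
# ===========================================================================

class DefenseTraitModel:
    """Hierarchical bivariate model of neckteeth counts and pedestal classes.

    Neckteeth: Binomial(5, logistic(X beta_N + u_N[mother])). Pedestal:
    cumulative logit with ordered thresholds tau1 < tau2 and linear
    predictor X' beta_P + u_P[mother] (no intercept; the thresholds are the
    intercepts). Mother intercepts are independent between responses with
    half-Normal(0,10) scale priors; coefficients and thresholds get
    Normal(0,10) priors.

    Parameters
    ----------
    data : DataFrame with columns mother_uid, neckteeth, pedestal and the
        factor columns, or an iterable of JuvenileRecord / EffectivityRecord.
    factors : factor columns entering the design (treatment coding,
        alphabetically first level as reference).
    max_interaction_order : highest interaction order retained.
    """

    response_labels = ("neckteeth", "pedestal")

    def __init__(
        self,
        data,
        factors: Sequence[str] = ("clone", "kairomone", "uvr"),
        max_interaction_order: int = 2,
        priors: PriorSpec = PriorSpec(),
        trials: int = 5,
        levels: Mapping[str, Sequence] | None = None,
    ) -> None:
        if isinstance(data, pd.DataFrame):
            frame = data.reset_index(drop=True)
        else:
            rows = list(data)
            if rows and isinstance(rows[0], JuvenileRecord):
                frame = juveniles_to_frame(rows)
            elif rows and isinstance(rows[0], EffectivityRecord):
                frame = effectivity_to_frame(rows)
            else:
                frame = pd.DataFrame(rows)
        if len(frame) == 0:
            raise ValueError("no records to fit")
        self.frame = frame
        self.priors = priors
        self.trials = trials
        self.spec = DesignSpec.from_frame(
            frame, list(factors), max_interaction_order, levels=levels
        )
        X, names = build_design_matrix(frame, self.spec)
        self.design_names = names

        # sort records by mother for contiguous reduceat segments
        mothers = sorted(frame["mother_uid"].astype(str).unique().tolist())
        self.mothers = tuple(mothers)
        lookup = {mm: i for i, mm in enumerate(mothers)}
        midx = frame["mother_uid"].astype(str).map(lookup).to_numpy()
        order = np.argsort(midx, kind="stable")
        self._X = X[order]
        self._midx = midx[order]
        self._k = frame["neckteeth"].to_numpy(dtype=int)[order]
        ped = frame["pedestal"].map(PED_CODE)
        if ped.isna().any():
            raise ValueError("pedestal values must be A/B/C")
        self._ped = ped.to_numpy(dtype=int)[order]
        self._starts = np.searchsorted(self._midx, np.arange(len(mothers)))
        self._log_binom = float(
            np.sum(
                gammaln(trials + 1)
                - gammaln(self._k + 1)
                - gammaln(trials - self._k + 1)
            )
        )

        p = X.shape[1]
        self.n_coef_n = p
        self.n_coef_p = p - 1
        self.param_names = (
            [f"neckteeth.{n}" for n in names]
            + [f"pedestal.{n}" for n in names[1:]]
            + ["tau[1]", "tau[2]", "sigma_u.neckteeth", "sigma_u.pedestal"]
            + [f"u_neckteeth[{m}]" for m in mothers]
            + [f"u_pedestal[{m}]" for m in mothers]
        )
        self.fixed_effect_names = (
            [f"neckteeth.{n}" for n in names] + [f"pedestal.{n}" for n in names[1:]]
        )

    # -- constructors ---------------------------------------------------
    @classmethod
    def from_records(cls, records, instar: int | None = None, **kwargs) -> "DefenseTraitModel":
        records = list(records)
        if instar is not None:
            records = [r for r in records if r.instar == instar]
        return cls(records, **kwargs)

    # -- conditional log-density pieces ----------------------------------
    def _bin_ll(self, eta: np.ndarray) -> np.ndarray:
        k = self._k
        return k * log_expit(eta) + (self.trials - k) * log_expit(-eta)

    def _ord_ll(self, eta: np.ndarray, tau: np.ndarray) -> np.ndarray:
        iA = self._ped == 0
        iB = self._ped == 1
        iC = self._ped == 2
        out = np.empty_like(eta)
        out[iA] = log_expit(tau[0] - eta[iA])
        out[iB] = (
            log_expit(tau[1] - eta[iB])
            + log_expit(eta[iB] - tau[0])
            + math.log1p(-math.exp(tau[0] - tau[1]))
        )
        out[iC] = log_expit(eta[iC] - tau[1])
        return out

    # -- fitting ----------------------------------------------------------
    def fit(self, config: SamplerConfig | str = "full_main") -> "DefenseTraitResults":
        config = _resolve_config(config)
        chains = [
            self._run_chain(np.random.default_rng(np.random.SeedSequence([config.seed, c])), config)
            for c in range(config.n_chains)
        ]
        draws = PosteriorDraws(
            self.param_names,
            np.stack(chains),
            config=config,
            meta={"model": type(self).__name__, "n_records": len(self._k)},
        )
        return DefenseTraitResults(self, draws)

    def _run_chain(self, rng: np.random.Generator, config: SamplerConfig) -> np.ndarray:
        X, Xp = self._X, self._X[:, 1:]
        midx, starts = self._midx, self._starts
        M = len(self.mothers)
        p, q = self.n_coef_n, self.n_coef_p
        n_fixed = p + q + 2  # coefficients + thresholds
        coef_sd2 = self.priors.coef_sd**2
        thr_sd2 = self.priors.threshold_sd**2
        scale_sd2 = self.priors.scale_sd**2

        bn = rng.normal(0.0, 0.5, p)
        bp = rng.normal(0.0, 0.5, q)
        t1 = rng.normal(-1.0, 0.3)
        tau = np.array([t1, t1 + abs(rng.normal(2.0, 0.3))])
        ls_n = math.log(0.5) + 0.3 * rng.standard_normal()
        ls_p = math.log(0.5) + 0.3 * rng.standard_normal()
        un = rng.normal(0.0, 0.3, M)
        up = rng.normal(0.0, 0.3, M)

        an = X @ bn
        ap = Xp @ bp

        dim = p + q + 4 + 2 * M
        n_iter, n_warm = config.n_iterations, config.n_warmup
        widths = np.ones(dim)
        w_un = np.full(M, 1.0)
        w_up = np.full(M, 1.0)
        retained = np.empty((n_iter - n_warm, dim))
        history = np.empty((min(n_warm, n_iter), dim)) if n_warm else None
        # adapted Cholesky factor for random-direction moves over the
        # fixed-effect + threshold block (identity scale until adapted)
        dir_chol = 0.5 * np.eye(n_fixed)
        if n_warm >= 40:
            step = max(50, n_warm // 10)
            adapt_at = sorted(set(range(step, n_warm, step)) | {n_warm - 1})
        else:
            adapt_at = []
        n_dir_moves = 16

        def pack() -> np.ndarray:
            return np.concatenate(
                [bn, bp, tau, [math.exp(ls_n), math.exp(ls_p)], un, up]
            )

        def fixed_logp(bn_c, bp_c, tau_c, eta_n_u, eta_p_u):
            if not tau_c[0] < tau_c[1]:
                return -math.inf
            ll = float(
                np.sum(self._bin_ll(X @ bn_c + eta_n_u))
                + np.sum(self._ord_ll(Xp @ bp_c + eta_p_u, tau_c))
            )
            prior = (
                -0.5 * float(bn_c @ bn_c + bp_c @ bp_c) / coef_sd2
                - 0.5 * float(tau_c @ tau_c) / thr_sd2
            )
            return ll + prior

        for it in range(n_iter):
            eta_n_u = un[midx]
            eta_p_u = up[midx]

            # The axis-aligned sweep over individual coefficients is the
            # costliest kernel and is largely redundant with the adapted
            # direction moves once warmup has calibrated them, so after
            # warmup it runs on every third iteration only (a deterministic
            # cycle of valid kernels).
            if it < n_warm or it % 3 == 0:
                # --- neckteeth coefficients ---
                cur_n = self._bin_ll(an + eta_n_u)
                for j in range(p):
                    xj = X[:, j]

                    def f(v, j=j, xj=xj):
                        eta = an + (v - bn[j]) * xj + eta_n_u
                        return float(np.sum(self._bin_ll(eta))) - 0.5 * v * v / coef_sd2

                    logf0 = float(np.sum(cur_n)) - 0.5 * bn[j] ** 2 / coef_sd2
                    new, _ = slice_update(f, bn[j], logf0, widths[j], rng)
                    if new != bn[j]:
                        an = an + (new - bn[j]) * xj
                        bn[j] = new
                        cur_n = self._bin_ll(an + eta_n_u)

                # --- pedestal coefficients ---
                cur_p = self._ord_ll(ap + eta_p_u, tau)
                for j in range(q):
                    xj = Xp[:, j]

                    def f(v, j=j, xj=xj):
                        eta = ap + (v - bp[j]) * xj + eta_p_u
                        return float(np.sum(self._ord_ll(eta, tau))) - 0.5 * v * v / coef_sd2

                    logf0 = float(np.sum(cur_p)) - 0.5 * bp[j] ** 2 / coef_sd2
                    new, _ = slice_update(f, bp[j], logf0, widths[p + j], rng)
                    if new != bp[j]:
                        ap = ap + (new - bp[j]) * xj
                        bp[j] = new
                        cur_p = self._ord_ll(ap + eta_p_u, tau)

                # --- thresholds (ordering enforced via -inf) ---
                eta_p_full = ap + eta_p_u
                for which in (0, 1):

                    def f(v, which=which):
                        cand = tau.copy()
                        cand[which] = v
                        if not cand[0] < cand[1]:
                            return -math.inf
                        return (
                            float(np.sum(self._ord_ll(eta_p_full, cand)))
                            - 0.5 * v * v / thr_sd2
                        )

                    logf0 = float(np.sum(self._ord_ll(eta_p_full, tau))) - 0.5 * tau[
                        which
                    ] ** 2 / thr_sd2
                    new, _ = slice_update(f, tau[which], logf0, widths[p + q + which], rng)
                    tau[which] = new

            # --- random-direction slice moves over the joint fixed block,
            #     along directions drawn from the adapted covariance:
            #     carries the sampler across correlated coefficient ridges
            #     that axis-aligned updates traverse slowly. Projections of
            #     the design matrix onto each direction are precomputed so
            #     a line evaluation is elementwise only. ---
            base_n = an + eta_n_u
            base_p = ap + eta_p_u
            for _ in range(n_dir_moves):
                direction = dir_chol @ rng.standard_normal(n_fixed)
                d_n, d_p, d_t = direction[:p], direction[p : p + q], direction[p + q :]
                proj_n = X @ d_n
                proj_p = Xp @ d_p
                c_coef1 = float(bn @ d_n + bp @ d_p)
                c_coef2 = float(d_n @ d_n + d_p @ d_p)
                c_thr1 = float(tau @ d_t)
                c_thr2 = float(d_t @ d_t)

                def f_dir(t):
                    tau_c = tau + t * d_t
                    if not tau_c[0] < tau_c[1]:
                        return -math.inf
                    ll = float(
                        np.sum(self._bin_ll(base_n + t * proj_n))
                        + np.sum(self._ord_ll(base_p + t * proj_p, tau_c))
                    )
                    prior = (
                        -(c_coef1 * t + 0.5 * c_coef2 * t * t) / coef_sd2
                        - (c_thr1 * t + 0.5 * c_thr2 * t * t) / thr_sd2
                    )
                    return ll + prior

                t_new, _ = slice_update(f_dir, 0.0, f_dir(0.0), 1.0, rng)
                if t_new != 0.0:
                    bn = bn + t_new * d_n
                    bp = bp + t_new * d_p
                    tau = tau + t_new * d_t
                    base_n = base_n + t_new * proj_n
                    base_p = base_p + t_new * proj_p
            an = X @ bn
            ap = Xp @ bp

            # --- mother intercepts, vectorized over conditionally
            #     independent components ---
            sig_n = math.exp(ls_n)
            sig_p = math.exp(ls_p)

            def g_un(v):
                ll = self._bin_ll(an + v[midx])
                return np.add.reduceat(ll, starts) - 0.5 * (v / sig_n) ** 2

            un = _vector_slice(g_un, un, w_un, rng)

            def g_up(v):
                ll = self._ord_ll(ap + v[midx], tau)
                return np.add.reduceat(ll, starts) - 0.5 * (v / sig_p) ** 2

            up = _vector_slice(g_up, up, w_up, rng)

            # --- interweaving recentering moves (exact Gibbs along the
            #     likelihood-invariant directions) ---
            prec = M / sig_n**2 + 1.0 / coef_sd2
            mean = (un.sum() / sig_n**2 - bn[0] / coef_sd2) / prec
            delta = mean + rng.standard_normal() / math.sqrt(prec)
            bn[0] += delta
            un -= delta
            an = an + delta

            # shifting all pedestal intercepts and both thresholds together
            # leaves tau_k - eta_p invariant; only the priors inform delta
            prec = M / sig_p**2 + 2.0 / thr_sd2
            mean = -(up.sum() / sig_p**2 + (tau[0] + tau[1]) / thr_sd2) / prec
            delta = mean + rng.standard_normal() / math.sqrt(prec)
            up += delta
            tau += delta

            # --- random-effect scales on the log scale ---
            ssq_n = float(np.sum(un**2))
            ssq_p = float(np.sum(up**2))

            def f_ls(v, ssq=ssq_n):
                s2 = math.exp(2.0 * v)
                return -M * v - 0.5 * ssq / s2 - 0.5 * s2 / scale_sd2 + v

            ls_n, _ = slice_update(
                f_ls, ls_n, f_ls(ls_n), widths[p + q + 2], rng
            )

            def f_lsp(v, ssq=ssq_p):
                s2 = math.exp(2.0 * v)
                return -M * v - 0.5 * ssq / s2 - 0.5 * s2 / scale_sd2 + v

            ls_p, _ = slice_update(
                f_lsp, ls_p, f_lsp(ls_p), widths[p + q + 3], rng
            )

            # --- ancillary rescaling: slice the scales again with the
            #     standardized effects u/sigma held fixed (non-centered
            #     parameterization), the standard cure for the scale/effect
            #     funnel of hierarchical posteriors ---
            sig_n = math.exp(ls_n)
            tilde_n = un / sig_n

            def f_anc_n(v):
                s = math.exp(v)
                eta = an + s * tilde_n[midx]
                return float(np.sum(self._bin_ll(eta))) - 0.5 * s * s / scale_sd2 + v

            ls_n, _ = slice_update(f_anc_n, ls_n, f_anc_n(ls_n), widths[p + q + 2], rng)
            un = math.exp(ls_n) * tilde_n

            sig_p = math.exp(ls_p)
            tilde_p = up / sig_p

            def f_anc_p(v):
                s = math.exp(v)
                eta = ap + s * tilde_p[midx]
                return float(np.sum(self._ord_ll(eta, tau))) - 0.5 * s * s / scale_sd2 + v

            ls_p, _ = slice_update(f_anc_p, ls_p, f_anc_p(ls_p), widths[p + q + 3], rng)
            up = math.exp(ls_p) * tilde_p

            # --- bookkeeping and warmup adaptation (widths and the
            #     direction covariance are frozen once warmup ends) ---
            state = pack()
            if it < n_warm:
                history[it] = state
                if it in adapt_at:
                    lo = max(0, it - max(100, it // 2))
                    tail = history[lo : it + 1]
                    spread = np.maximum(2.0 * tail.std(axis=0), 1e-3)
                    widths = spread.copy()
                    # scales were stored as sigma; width applies to log-sigma
                    widths[p + q + 2] = max(
                        2.0 * np.log(np.maximum(tail[:, p + q + 2], 1e-8)).std(), 0.05
                    )
                    widths[p + q + 3] = max(
                        2.0 * np.log(np.maximum(tail[:, p + q + 3], 1e-8)).std(), 0.05
                    )
                    w_un = spread[p + q + 4 : p + q + 4 + M].copy()
                    w_up = spread[p + q + 4 + M :].copy()
                    # expanding window for the direction covariance so that
                    # slowly discovered ridges keep stretching it
                    half = history[max(0, it // 4) : it + 1, :n_fixed]
                    cov = np.cov(half.T) + 1e-6 * np.eye(n_fixed)
                    try:
                        dir_chol = np.linalg.cholesky(cov)
                    except np.linalg.LinAlgError:
                        pass
            else:
                retained[it - n_warm] = state
        return retained


class DefenseTraitResults(_BaseResults):
    """Posterior summary surface for the bivariate defense model."""


# ===========================================================================
# Pooled kairomone-effectivity model
# ===========================================================================

class EffectivityModel(DefenseTraitModel):
    """Bivariate defense model for the effectivity trial: a single 3-level
    treatment factor (control / PAR / UVR), all exposure durations pooled.

    PAR and UVR label the light exposure of the kairomone medium; both carry
    kairomone, the control does not. The scientific contrasts are therefore
    kairomone-vs-control, (PAR+UVR)/2 - control on the linear predictor
    scale, and UVR-vs-PAR.
    """

    def __init__(self, data, **kwargs):
        kwargs.setdefault("factors", ("treatment",))
        kwargs.setdefault("max_interaction_order", 1)
        kwargs.setdefault("levels", {"treatment": ("control", "PAR", "UVR")})
        super().__init__(data, **kwargs)

    def fit(self, config: SamplerConfig | str = "full_effectivity") -> "EffectivityResults":
        base = super().fit(config)
        return EffectivityResults(self, base.draws)


class EffectivityResults(DefenseTraitResults):
    CONTRASTS = {
        "kairomone_vs_control": {"treatment[PAR]": 0.5, "treatment[UVR]": 0.5},
        "uvr_vs_par": {"treatment[PAR]": -1.0, "treatment[UVR]": 1.0},
    }

    def contrast_draws(self, response: str, weights: Mapping[str, float]) -> np.ndarray:
        out = None
        for col, w in weights.items():
            vals = w * self.draws.pooled(f"{response}.{col}")
            out = vals if out is None else out + vals
        return out

    def contrast_ci(
        self, response: str, contrast: str, level: float = 0.95
    ) -> tuple[float, float]:
        pooled = self.contrast_draws(response, self.CONTRASTS[contrast])
        alpha = (1 - level) / 2
        lo, hi = np.quantile(pooled, [alpha, 1 - alpha])
        return float(lo), float(hi)

    def contrast_is_strong(self, response: str, contrast: str, level: float = 0.95) -> bool:
        lo, hi = self.contrast_ci(response, contrast, level)
        return lo > 0 or hi < 0

    def contrast_savage_dickey(self, response: str, contrast: str, point: float = 0.0):
        weights = self.CONTRASTS[contrast]
        pooled = self.contrast_draws(response, weights)
        prior_sd = self.model.priors.coef_sd * math.sqrt(
            sum(w * w for w in weights.values())
        )
        return _evidence.savage_dickey_ratio(
            pooled,
            parameter=f"{response}:{contrast}",
            prior=prior_sd,
            point=point,
        )


# ===========================================================================
# Trivariate morphometric model
# ===========================================================================

TRAIT_COLUMNS = ("body_length_mm", "body_width_mm", "spina_length_mm")
TRAIT_NAMES = ("body_length", "body_width", "spina_length")


class MorphometricModel:
    """Zero-truncated trivariate Gaussian model of body length, body width,
    and spina length with per-mother, per-trait random intercepts.

    The truncation constant is treated as 1 during fitting (the trait means
    sit tens of residual standard deviations inside the positive orthant);
    the exact orthant correction is available in
    :func:`neckteeth.likelihoods.truncated_mvn_loglik` and agrees to well
    below any tolerance used here. Records with all three traits missing
    are dropped with a logged count; partially missing records are handled
    by Gibbs data augmentation, equivalent to the marginal sub-vector
    likelihood.
    """

    def __init__(
        self,
        data,
        factors: Sequence[str] = ("clone", "instar", "kairomone", "uvr"),
        max_interaction_order: int = 3,
        priors: PriorSpec = PriorSpec(),
        levels: Mapping[str, Sequence] | None = None,
    ) -> None:
        if isinstance(data, pd.DataFrame):
            frame = data.reset_index(drop=True)
        else:
            frame = juveniles_to_frame(list(data))
        Y = frame[list(TRAIT_COLUMNS)].to_numpy(dtype=float)
        keep = ~np.all(np.isnan(Y), axis=1)
        n_dropped = int((~keep).sum())
        if n_dropped:
            logger.info("dropping %d record(s) with all traits missing", n_dropped)
        frame = frame.loc[keep].reset_index(drop=True)
        if len(frame) == 0:
            raise ValueError("no records with any observed trait")
        self.n_dropped_all_missing = n_dropped
        self.frame = frame
        self.priors = priors
        self.spec = DesignSpec.from_frame(frame, list(factors), max_interaction_order, levels=levels)
        X, names = build_design_matrix(frame, self.spec)
        self.design_names = names

        mothers = sorted(frame["mother_uid"].astype(str).unique().tolist())
        self.mothers = tuple(mothers)
        lookup = {mm: i for i, mm in enumerate(mothers)}
        midx = frame["mother_uid"].astype(str).map(lookup).to_numpy()
        order = np.argsort(midx, kind="stable")
        self._X = X[order]
        self._Y = frame[list(TRAIT_COLUMNS)].to_numpy(dtype=float)[order]
        self._midx = midx[order]
        self._starts = np.searchsorted(self._midx, np.arange(len(mothers)))
        self._nm = np.bincount(self._midx, minlength=len(mothers)).astype(float)
        self._miss = np.isnan(self._Y)

        p = X.shape[1]
        corr_pairs = [("body_length", "body_width"), ("body_length", "spina_length"),
                      ("body_width", "spina_length")]
        self.param_names = (
            [f"{t}.{n}" for t in TRAIT_NAMES for n in names]
            + [f"sigma_u.{t}" for t in TRAIT_NAMES]
            + [f"resid_sd.{t}" for t in TRAIT_NAMES]
            + [f"resid_corr[{a},{b}]" for a, b in corr_pairs]
            + [f"u_{t}[{m}]" for t in TRAIT_NAMES for m in mothers]
        )
        self.fixed_effect_names = [f"{t}.{n}" for t in TRAIT_NAMES for n in names]

    @classmethod
    def from_records(cls, records, **kwargs) -> "MorphometricModel":
        return cls(list(records), **kwargs)

    def fit(self, config: SamplerConfig | str = "full_main") -> "MorphometricResults":
        config = _resolve_config(config)
        chains = [
            self._run_chain(np.random.default_rng(np.random.SeedSequence([config.seed, c])), config)
            for c in range(config.n_chains)
        ]
        draws = PosteriorDraws(
            self.param_names,
            np.stack(chains),
            config=config,
            meta={
                "model": type(self).__name__,
                "n_records": int(self._Y.shape[0]),
                "n_dropped_all_missing": self.n_dropped_all_missing,
            },
        )
        return MorphometricResults(self, draws)

    # ------------------------------------------------------------------
    def _run_chain(self, rng: np.random.Generator, config: SamplerConfig) -> np.ndarray:
        X, miss = self._X, self._miss
        midx, starts, nm = self._midx, self._starts, self._nm
        n, p = X.shape
        M = len(self.mothers)
        coef_sd2 = self.priors.coef_sd**2
        scale_sd2 = self.priors.scale_sd**2
        XtX = X.T @ X

        # missingness patterns for imputation
        patterns: list[tuple[np.ndarray, np.ndarray]] = []
        if miss.any():
            uniq, inv = np.unique(miss, axis=0, return_inverse=True)
            for gi, pat in enumerate(uniq):
                if pat.any():
                    patterns.append((pat, np.where(inv == gi)[0]))

        # initial values: column means / small jitter
        col_mean = np.array(
            [np.nanmean(self._Y[:, t]) for t in range(3)]
        )
        Y = self._Y.copy()
        for t in range(3):
            Y[np.isnan(Y[:, t]), t] = col_mean[t]
        B = np.zeros((p, 3))
        B[0] = col_mean + 0.02 * rng.standard_normal(3)
        U = rng.normal(0.0, 0.01, (M, 3))
        log_su = np.log(0.02) + 0.2 * rng.standard_normal(3)
        log_sd = np.log([0.035, 0.02, 0.05]) + 0.2 * rng.standard_normal(3)
        rho = np.array([0.5, 0.2, 0.1]) + 0.05 * rng.standard_normal(3)

        def make_sigma(log_sd, rho):
            corr = np.array(
                [[1.0, rho[0], rho[1]], [rho[0], 1.0, rho[2]], [rho[1], rho[2], 1.0]]
            )
            sd = np.exp(log_sd)
            return corr * np.outer(sd, sd), corr

        n_iter, n_warm = config.n_iterations, config.n_warmup
        n_scalar = 9  # 3 log_su + 3 log_sd + 3 rho
        widths = np.full(n_scalar, 0.2)
        dim = 3 * p + 3 + 3 + 3 + 3 * M
        retained = np.empty((n_iter - n_warm, dim))
        history = np.empty((min(n_warm, n_iter), n_scalar)) if n_warm else None

        Sigma, corr = make_sigma(log_sd, rho)

        for it in range(n_iter):
            Sigma, corr = make_sigma(log_sd, rho)
            if np.linalg.eigvalsh(corr)[0] <= 1e-8:
                rho = np.array([0.5, 0.2, 0.1])
                Sigma, corr = make_sigma(log_sd, rho)
            Sinv = np.linalg.inv(Sigma)
            mu = X @ B + U[midx]

            # --- impute missing trait components ---
            for pat, rows in patterns:
                obs = ~pat
                if obs.any():
                    Soo = Sigma[np.ix_(obs, obs)]
                    Smo = Sigma[np.ix_(pat, obs)]
                    gain = Smo @ np.linalg.inv(Soo)
                    cond_cov = Sigma[np.ix_(pat, pat)] - gain @ Smo.T
                    resid_obs = self._Y[np.ix_(rows, np.where(obs)[0])] - mu[
                        np.ix_(rows, np.where(obs)[0])
                    ]
                    cond_mean = mu[np.ix_(rows, np.where(pat)[0])] + resid_obs @ gain.T
                else:
                    cond_cov = Sigma
                    cond_mean = mu[rows][:, pat]
                L = np.linalg.cholesky(np.atleast_2d(cond_cov))
                z = rng.standard_normal((len(rows), int(pat.sum())))
                Y[np.ix_(rows, np.where(pat)[0])] = cond_mean + z @ L.T

            # --- coefficients: conjugate Gaussian draw with the mother
            #     effects integrated out (Woodbury per mother), which
            #     removes the slow B<->U alternation entirely.
            #     vec ordering is trait-major: [B[:,0], B[:,1], B[:,2]] ---
            su2 = np.exp(2.0 * log_su)
            D = np.diag(su2)
            prec = np.kron(Sinv, XtX) + np.eye(3 * p) / coef_sd2
            lin = (X.T @ Y @ Sinv).T.reshape(-1)
            s_m = np.stack(
                [np.add.reduceat(X[:, j], starts) for j in range(p)], axis=1
            )  # (M, p): per-mother design-row sums
            T_m = np.stack(
                [np.add.reduceat(Y[:, t], starts) for t in range(3)], axis=1
            )  # (M, 3)
            W_by_n: dict[float, np.ndarray] = {}
            for n_m in np.unique(nm):
                W = np.linalg.solve(Sigma + n_m * D, D @ Sinv)
                W_by_n[n_m] = 0.5 * (W + W.T)
            W_all = np.stack([W_by_n[n_m] for n_m in nm])  # (M,3,3)
            # precision correction: - sum_m kron(W_m, s_m s_m^T)
            for n_m, W in W_by_n.items():
                sel = nm == n_m
                ssT = np.einsum("mi,mj->ij", s_m[sel], s_m[sel])
                prec -= np.kron(W, ssT)
            WT = np.einsum("mab,mb->ma", W_all, T_m)  # (M,3)
            lin -= np.einsum("ma,mj->aj", WT, s_m).reshape(-1)
            prec = 0.5 * (prec + prec.T)
            Lp = np.linalg.cholesky(prec)
            mean = np.linalg.solve(prec, lin)
            z = rng.standard_normal(3 * p)
            bvec = mean + np.linalg.solve(Lp.T, z)
            B = bvec.reshape(3, p).T

            # --- mother effects given coefficients: conjugate per mother ---
            E = Y - X @ B
            S_m = np.stack(
                [np.add.reduceat(E[:, t], starts) for t in range(3)], axis=1
            )  # (M, 3)
            prec_m = nm[:, None, None] * Sinv[None, :, :] + np.diag(1.0 / su2)[None, :, :]
            lin_m = S_m @ Sinv  # (M,3); Sinv symmetric
            mean_m = np.linalg.solve(prec_m, lin_m[:, :, None])[:, :, 0]
            Lm = np.linalg.cholesky(prec_m)
            z = rng.standard_normal((M, 3, 1))
            U = mean_m + np.linalg.solve(np.transpose(Lm, (0, 2, 1)), z)[:, :, 0]

            # --- random-effect scales: centered slice, then an ancillary
            #     rescaling with u/sigma fixed to break the scale funnel ---
            for t in range(3):
                ssq = float(np.sum(U[:, t] ** 2))

                def f_ls(v, ssq=ssq):
                    s2 = math.exp(2.0 * v)
                    return -M * v - 0.5 * ssq / s2 - 0.5 * s2 / scale_sd2 + v

                log_su[t], _ = slice_update(f_ls, log_su[t], f_ls(log_su[t]), widths[t], rng)

            E = Y - X @ B
            Ut = U / np.exp(log_su)[None, :]
            for t in range(3):

                def f_anc(v, t=t):
                    # full Gaussian loglik with U[:,t] = exp(v) * tilde_t;
                    # other traits' effects held at current values
                    Ucand = U.copy()
                    Ucand[:, t] = math.exp(v) * Ut[:, t]
                    Ec = E - Ucand[midx]
                    ll = -0.5 * float(np.einsum("ij,jk,ik->", Ec, Sinv, Ec))
                    s = math.exp(v)
                    return ll - 0.5 * s * s / scale_sd2 + v

                log_su[t], _ = slice_update(f_anc, log_su[t], f_anc(log_su[t]), widths[t], rng)
                U[:, t] = math.exp(log_su[t]) * Ut[:, t]

            # --- residual covariance: slice on log-sds and correlations ---
            E = Y - X @ B - U[midx]
            S = E.T @ E

            def sigma_logp(log_sd_c, rho_c):
                corr_c = np.array(
                    [
                        [1.0, rho_c[0], rho_c[1]],
                        [rho_c[0], 1.0, rho_c[2]],
                        [rho_c[1], rho_c[2], 1.0],
                    ]
                )
                det = np.linalg.det(corr_c)
                if det <= 1e-10 or np.abs(rho_c).max() >= 1.0:
                    return -math.inf
                sd_c = np.exp(log_sd_c)
                Sig = corr_c * np.outer(sd_c, sd_c)
                Sinv_c = np.linalg.inv(Sig)
                logdet = math.log(det) + 2.0 * float(np.sum(log_sd_c))
                ll = -0.5 * n * logdet - 0.5 * float(np.sum(Sinv_c * S))
                prior = float(np.sum(-0.5 * sd_c**2 / scale_sd2 + log_sd_c))
                return ll + prior

            for t in range(3):

                def f_sd(v, t=t):
                    cand = log_sd.copy()
                    cand[t] = v
                    return sigma_logp(cand, rho)

                log_sd[t], _ = slice_update(
                    f_sd, log_sd[t], f_sd(log_sd[t]), widths[3 + t], rng
                )
            for t in range(3):

                def f_rho(v, t=t):
                    cand = rho.copy()
                    cand[t] = v
                    return sigma_logp(log_sd, cand)

                rho[t], _ = slice_update(f_rho, rho[t], f_rho(rho[t]), widths[6 + t], rng)

            # --- bookkeeping ---
            scalar_state = np.concatenate([log_su, log_sd, rho])
            if it < n_warm:
                history[it] = scalar_state
                if it == n_warm - 1 and n_warm >= 20:
                    tail = history[n_warm // 2 : n_warm]
                    widths = np.maximum(2.0 * tail.std(axis=0), 0.02)
            else:
                state = np.concatenate(
                    [
                        B.T.reshape(-1),  # trait-major to match param_names
                        np.exp(log_su),
                        np.exp(log_sd),
                        rho,
                        U.T.reshape(-1),
                    ]
                )
                retained[it - n_warm] = state
        return retained


class MorphometricResults(_BaseResults):
    """Posterior summary surface for the morphometric model."""
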