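"""Savage-Dickey evidence ratios, "strong effect" classification, and
effect summary tables.

For a point null hypothesis nested in the alternative, the Bayes factor
BF01 equals the posterior density divided by the prior density at the null
value (the Savage-Dickey density ratio). Ratios above 1 favor the null
(no effect); ratios below 1 favor the alternative. The posterior density
at the test point is estimated from pooled post-warmup draws by Gaussian
kernel density estimation with Silverman bandwidth; a normal-approximation
fallback is provided.

An effect is classified "strong" when its 95% central credible interval
excludes zero; an endpoint exactly at zero counts as including it.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .likelihoods import PriorSpec
from .sampling import PosteriorDraws

__all__ = [
    "EvidenceResult",
    "savage_dickey_ratio",
    "classify_strong_effects",
    "effect_summary_table",
    "plot_forest",
]

MIN_DRAWS = 100


@dataclass(frozen=True)
class EvidenceResult:
    """Savage-Dickey evidence ratio with the densities it is built from."""

    parameter: str
    evidence_ratio: float
    posterior_density_at_point: float
    prior_density_at_point: float
    point: float = 0.0


def _prior_sd(prior) -> float:
    if isinstance(prior, PriorSpec):
        return prior.coef_sd
    return float(prior)


def savage_dickey_ratio(
    draws,
    parameter: str | None = None,
    prior: PriorSpec | float = PriorSpec(),
    point: float = 0.0,
    method: str = "kde",
) -> EvidenceResult:
    """Evidence ratio BF01 = posterior(point) / prior(point).

    ``draws`` is a :class:`PosteriorDraws` (with ``parameter`` naming the
    coefficient) or a plain array of pooled draws. The prior is the
    Normal(0, coef_sd) coefficient prior, or a bare standard deviation for
    derived linear combinations.
    """
    if isinstance(draws, PosteriorDraws):
        if parameter is None:
            raise ValueError("parameter name required with PosteriorDraws input")
        pooled = draws.pooled(parameter)
    else:
        pooled = np.asarray(draws, dtype=float).reshape(-1)
    if pooled.size < MIN_DRAWS:
        raise ValueError(
            f"need >= {MIN_DRAWS} draws for a reliable density estimate, got {pooled.size}"
        )
    sd = _prior_sd(prior)
    prior_density = float(stats.norm.pdf(point, loc=0.0, scale=sd))
    if method == "kde":
        if np.std(pooled) == 0.0:
            # degenerate draws: density is a point mass
            post_density = math.inf if pooled[0] == point else 0.0
        else:
            kde = stats.gaussian_kde(pooled, bw_method="silverman")
            post_density = float(kde(point)[0])
    elif method == "normal":
        mu, sigma = float(np.mean(pooled)), float(np.std(pooled))
        post_density = float(stats.norm.pdf(point, loc=mu, scale=max(sigma, 1e-12)))
    else:
        raise ValueError(f"unknown method {method!r}")
    ratio = post_density / prior_density
    return EvidenceResult(
        parameter=parameter or "derived",
        evidence_ratio=float(ratio),
        posterior_density_at_point=post_density,
        prior_density_at_point=prior_density,
        point=point,
    )


def _interval(pooled: np.ndarray, level: float) -> tuple[float, float]:
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(pooled, [alpha, 1.0 - alpha], method="linear")
    return float(lo), float(hi)


def classify_strong_effects(
    draws: PosteriorDraws,
    parameters: Sequence[str] | None = None,
    level: float = 0.95,
) -> dict[str, bool]:
    """True iff the central credible interval excludes 0 (strictly)."""
    parameters = list(parameters) if parameters is not None else list(draws.names)
    flags = {}
    for name in parameters:
        lo, hi = _interval(draws.pooled(name), level)
        flags[name] = bool(lo > 0.0 or hi < 0.0)
    return flags


def effect_summary_table(
    draws: PosteriorDraws,
    parameters: Sequence[str] | None = None,
    prior: PriorSpec | float = PriorSpec(),
    point: float = 0.0,
) -> pd.DataFrame:
    """One row per fixed effect: median, 50% and 95% CIs, strong flag,
    Savage-Dickey evidence ratio. Row order follows the design columns."""
    parameters = list(parameters) if parameters is not None else list(draws.names)
    rows = []
    for name in parameters:
        pooled = draws.pooled(name)
        lo50, hi50 = _interval(pooled, 0.50)
        lo95, hi95 = _interval(pooled, 0.95)
        ev = savage_dickey_ratio(pooled, parameter=name, prior=prior, point=point)
        rows.append(
            {
                "parameter": name,
                "median": float(np.median(pooled)),
                "ci50_low": lo50,
                "ci50_high": hi50,
                "ci95_low": lo95,
                "ci95_high": hi95,
                "strong": bool(lo95 > 0.0 or hi95 < 0.0),
                "evidence_ratio": ev.evidence_ratio,
            }
        )
    return pd.DataFrame(rows)


def plot_forest(summary: pd.DataFrame, path=None):
    """Forest plot of posterior medians with 50% (thick) and 95% (thin)
    credible intervals; strong effects drawn in red."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(summary)
    fig, ax = plt.subplots(figsize=(7, max(2.0, 0.32 * n + 1)))
    ys = np.arange(n)[::-1]
    for y, (_, row) in zip(ys, summary.iterrows()):
        color = "crimson" if row["strong"] else "gray"
        ax.plot([row["ci95_low"], row["ci95_high"]], [y, y], color=color, lw=1)
        ax.plot([row["ci50_low"], row["ci50_high"]], [y, y], color=color, lw=3)
        ax.plot(row["median"], y, "o", color=color, ms=4)
    ax.axvline(0.0, color="k", lw=0.8, ls="--")
    ax.set_yticks(ys)
    ax.set_yticklabels(summary["parameter"])
    ax.set_xlabel("effect (log-odds / mm)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return path
    return fig
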