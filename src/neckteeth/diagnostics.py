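"""Convergence and identifiability diagnostics.

Rank-normalized split-R-hat and effective sample size follow the
Vehtari et al. recommendations as implemented in ArviZ. The workflow
mirrors the analysis design: a model variant whose parameters exceed
R-hat > 1.05 is treated as unidentifiable (overfitted), and the highest
remaining interaction order is dropped before refitting.
"""
from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np

from .sampling import PosteriorDraws

__all__ = [
    "split_rhat",
    "effective_sample_size",
    "rhat_all",
    "ess_all",
    "check_identifiability",
    "credible_interval",
]


def _chains(draws: PosteriorDraws, parameter: str) -> np.ndarray:
    arr = draws.get(parameter)
    if arr.shape[0] < 2:
        raise ValueError("split-R-hat needs >= 2 chains")
    if arr.shape[1] < 4:
        raise ValueError("split-R-hat needs >= 4 draws per chain")
    return arr


def _is_constant(arr: np.ndarray) -> bool:
    return bool(np.all(arr == arr.flat[0]))


def split_rhat(draws: PosteriorDraws, parameter: str) -> float:
    """Rank-normalized split-R-hat for one parameter.

    A parameter that is constant across all chains and draws returns 1.0
    with a warning, so identifiability screening never crashes on
    degenerate chains.
    """
    arr = _chains(draws, parameter)
    if _is_constant(arr):
        warnings.warn(f"parameter {parameter!r} is constant; R-hat defined as 1.0")
        return 1.0
    import arviz as az

    return float(az.rhat(az.convert_to_dataset({"x": arr}), method="rank")["x"].values)


def effective_sample_size(draws: PosteriorDraws, parameter: str) -> float:
    """Bulk effective sample size; constant chains are degenerate (0, warned)."""
    arr = _chains(draws, parameter)
    if _is_constant(arr):
        warnings.warn(f"parameter {parameter!r} is constant; ESS degenerate (0)")
        return 0.0
    import arviz as az

    return float(az.ess(az.convert_to_dataset({"x": arr}), method="bulk")["x"].values)


def rhat_all(draws: PosteriorDraws) -> dict[str, float]:
    """Rank-normalized split-R-hat for every parameter (vectorized)."""
    import arviz as az

    out: dict[str, float] = {}
    variable, constant = [], []
    for n in draws.names:
        (constant if _is_constant(draws.get(n)) else variable).append(n)
    if variable:
        ds = az.convert_to_dataset({n: draws.get(n) for n in variable})
        res = az.rhat(ds, method="rank")
        out.update({n: float(res[n].values) for n in variable})
    for n in constant:
        out[n] = 1.0
    return {n: out[n] for n in draws.names}


def ess_all(draws: PosteriorDraws) -> dict[str, float]:
    import arviz as az

    out: dict[str, float] = {}
    variable, constant = [], []
    for n in draws.names:
        (constant if _is_constant(draws.get(n)) else variable).append(n)
    if variable:
        ds = az.convert_to_dataset({n: draws.get(n) for n in variable})
        res = az.ess(ds, method="bulk")
        out.update({n: float(res[n].values) for n in variable})
    for n in constant:
        out[n] = 0.0
    return {n: out[n] for n in draws.names}


def check_identifiability(
    draws: PosteriorDraws, rhat_threshold: float = 1.05
) -> tuple[bool, list[str]]:
    """Flag the fit as unidentifiable when any parameter's R-hat exceeds the threshold.

    The comparison is strict (> threshold), so a parameter at exactly the
    threshold passes. Returns (passed, offending parameter names).
    """
    rhats = rhat_all(draws)
    offending = [n for n, r in rhats.items() if r > rhat_threshold]
    return (len(offending) == 0, offending)


def credible_interval(
    draws: PosteriorDraws, parameter: str, level: float = 0.95
) -> tuple[float, float]:
    """Central credible interval from pooled empirical quantiles.

    Uses the linear-interpolation quantile convention; endpoints near zero
    decide the "strong effect" classification, so the convention matters
    and is fixed here.
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level}")
    pooled = draws.pooled(parameter)
    if pooled.size == 0:
        raise ValueError("no draws available")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(pooled, [alpha, 1.0 - alpha], method="linear")
    return float(lo), float(hi)
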