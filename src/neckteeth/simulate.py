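"""Synthetic data with the statistical structure of the two experiments.

The generator emulates (a) the kairomone-effectivity trial — 3 medium
treatments (control, PAR-exposed kairomone, UVR-exposed kairomone) x 4
exposure durations, 2 mothers and 10 juveniles per cell — and (b) the main
2-clone x kairomone x UVR factorial experiment with maternal clustering,
instar-1/instar-2 repeated scoring, >= 50% UVR mortality before instar 2,
and the missing clone-P5 instar-1 +kairomone/+UVR cell.

True parameter defaults reproduce the reported qualitative effect
structure: kairomone induces instar-2 neckteeth and pedestals, UVR suppresses
pedestal development (strongest in instar 1) and shrinks all three
morphometric traits, and instar-1 neckteeth are canalized at 1-3 teeth
regardless of treatment. PAR- and UVR-exposed kairomone media share
identical trait-generating parameters (no kairomone-degradation effect).

Randomness is seeded per clone-x-treatment-x-mother cell via
SeedSequence(seed, cell key), so adding a treatment or mother leaves the
draws of other cells unchanged.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from .data import (
    EffectivityRecord,
    JuvenileRecord,
    make_mother_uid,
)
from .design import DesignSpec, build_design_matrix
from .likelihoods import ordinal_category_probs

__all__ = [
    "DefenseTruth",
    "MorphoTruth",
    "EffectivityTruth",
    "GeneratorConfig",
    "default_true_params",
    "default_defense_truths",
    "default_morpho_truth",
    "default_effectivity_truth",
    "simulate_main_experiment",
    "simulate_effectivity_experiment",
    "defense_cell_etas",
]

TRAITS = ("body_length", "body_width", "spina_length")


@dataclass(frozen=True)
class DefenseTruth:
    """True coefficients of the bivariate defense model, keyed by design column.

    ``beta_n`` is on the neckteeth (binomial-logit) scale and includes the
    intercept; ``beta_p`` is on the pedestal cumulative-logit scale and has
    no intercept (the thresholds ``tau`` play that role). Unlisted columns
    are zero.
    """

    beta_n: Mapping[str, float]
    beta_p: Mapping[str, float]
    tau: tuple[float, float]
    sigma_n: float = 0.5
    sigma_p: float = 0.5

    def __post_init__(self) -> None:
        if not self.tau[0] < self.tau[1]:
            raise ValueError("tau must be ordered")
        if self.sigma_n < 0 or self.sigma_p < 0:
            raise ValueError("random-effect scales must be >= 0")


@dataclass(frozen=True)
class MorphoTruth:
    """True trivariate morphometric model: per-trait coefficients (mm),
    per-mother effect scales, and residual correlation structure."""

    coef: Mapping[str, Mapping[str, float]]
    sigma_u: tuple[float, float, float] = (0.015, 0.010, 0.020)
    resid_sd: tuple[float, float, float] = (0.035, 0.020, 0.050)
    resid_corr: tuple[float, float, float] = (0.7, 0.3, 0.2)  # (lw, ls, ws)

    @property
    def Sigma(self) -> np.ndarray:
        sd = np.asarray(self.resid_sd)
        r_lw, r_ls, r_ws = self.resid_corr
        corr = np.array([[1.0, r_lw, r_ls], [r_lw, 1.0, r_ws], [r_ls, r_ws, 1.0]])
        return corr * np.outer(sd, sd)


@dataclass(frozen=True)
class EffectivityTruth:
    """Trait-generating parameters for the effectivity trial (UNI clone,
    instar 2). PAR and UVR kairomone media are exchangeable by construction;
    the control induces (almost) nothing."""

    eta_n_control: float = -3.0
    eta_n_kairomone: float = 0.0
    eta_p_control: float = 0.0
    eta_p_kairomone: float = 3.0
    tau: tuple[float, float] = (2.0, 4.0)
    sigma_n: float = 0.5
    sigma_p: float = 0.5


def default_defense_truths() -> dict[int, DefenseTruth]:
    """Instar-specific true defense coefficients (treatment coding, reference
    clone P5 / -kairomone / -UVR)."""
    # Magnitudes are chosen so every design cell keeps non-negligible
    # probability on at least two outcome categories: degenerate cells
    # (e.g., all-A pedestals) would leave coefficients identified only by
    # their prior, which no finite experiment of this design could recover.
    instar1 = DefenseTruth(
        beta_n={
            "Intercept": -0.4,
            "clone[UNI]": 0.0,
            "kairomone": 0.2,
            "uvr": 0.15,
            "clone[UNI]:kairomone": 0.1,
            "clone[UNI]:uvr": -0.35,
            "kairomone:uvr": -0.15,
        },
        beta_p={
            "clone[UNI]": 0.1,
            "kairomone": 3.0,
            "uvr": -1.8,
            "clone[UNI]:kairomone": 0.2,
            "clone[UNI]:uvr": 0.2,
            "kairomone:uvr": -0.2,
        },
        tau=(0.0, 3.5),
    )
    instar2 = DefenseTruth(
        beta_n={
            "Intercept": -3.0,
            "clone[UNI]": 0.2,
            "kairomone": 2.4,
            "uvr": -0.3,
            "clone[UNI]:kairomone": 0.4,
            "clone[UNI]:uvr": -0.8,
            "kairomone:uvr": -0.3,
        },
        beta_p={
            "clone[UNI]": 0.2,
            "kairomone": 2.5,
            "uvr": -1.2,
            "clone[UNI]:kairomone": 0.3,
            "clone[UNI]:uvr": -0.3,
            "kairomone:uvr": -0.3,
        },
        tau=(1.5, 3.5),
    )
    return {1: instar1, 2: instar2}


def default_morpho_truth() -> MorphoTruth:
    """Trait means calibrated to the printed ranges: instar-1 body length
    0.55-0.8 mm, instar-2 0.75-1.0 mm, UVR shrinking every trait."""
    return MorphoTruth(
        coef={
            "body_length": {
                "Intercept": 0.670,
                "clone[UNI]": 0.010,
                "instar[2]": 0.200,
                "kairomone": 0.000,
                "uvr": -0.045,
                "instar[2]:uvr": 0.005,
            },
            "body_width": {
                "Intercept": 0.360,
                "clone[UNI]": 0.005,
                "instar[2]": 0.090,
                "kairomone": 0.000,
                "uvr": -0.025,
            },
            "spina_length": {
                "Intercept": 0.450,
                "clone[UNI]": 0.000,
                "instar[2]": 0.010,
                "kairomone": 0.000,
                "uvr": -0.050,
                "instar[2]:uvr": 0.030,
            },
        }
    )


def default_effectivity_truth() -> EffectivityTruth:
    return EffectivityTruth()


def default_true_params(instar: int) -> tuple[DefenseTruth, MorphoTruth]:
    """Documented true coefficient sets whose signs reproduce the reported
    qualitative effect structure, per instar."""
    if instar not in (1, 2):
        raise ValueError(f"instar must be 1 or 2, got {instar}")
    return default_defense_truths()[instar], default_morpho_truth()


@dataclass(frozen=True)
class GeneratorConfig:
    """Design sizes, calibration ranges, true parameters, and seed."""

    clones: tuple[str, ...] = ("P5", "UNI")
    mothers_per_treatment: int = 6
    offspring_per_mother: tuple[int, int] = (5, 10)
    uvr_instar2_mortality: float = 0.55
    include_missing_cell: bool = True
    body_length_ranges: Mapping[int, tuple[float, float]] = field(
        default_factory=lambda: {1: (0.55, 0.80), 2: (0.75, 1.00)}
    )
    morpho_missing_prob: float = 0.10
    defense_truths: Mapping[int, DefenseTruth] = field(default_factory=default_defense_truths)
    morpho_truth: MorphoTruth = field(default_factory=default_morpho_truth)
    effectivity_truth: EffectivityTruth = field(default_factory=default_effectivity_truth)
    effectivity_mothers_per_cell: int = 2
    effectivity_offspring_per_mother: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.clones:
            raise ValueError("need at least one clone")
        if self.mothers_per_treatment < 1:
            raise ValueError("mothers_per_treatment must be >= 1")
        if not 0.0 <= self.uvr_instar2_mortality <= 1.0:
            raise ValueError("uvr_instar2_mortality must be a probability")
        if not 0.0 <= self.morpho_missing_prob <= 1.0:
            raise ValueError("morpho_missing_prob must be a probability")
        lo, hi = self.offspring_per_mother
        if not 1 <= lo <= hi:
            raise ValueError("offspring_per_mother must be a valid integer range")
        for instar, (a, b) in self.body_length_ranges.items():
            if not b > a > 0:
                raise ValueError(f"body_length range for instar {instar} must have positive width")

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        """Load the scalar design fields from a flat YAML mapping; true
        parameters keep their documented defaults."""
        raw = yaml.safe_load(open(path)) or {}
        kwargs = {}
        for key in (
            "mothers_per_treatment",
            "uvr_instar2_mortality",
            "include_missing_cell",
            "morpho_missing_prob",
            "seed",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        if "clones" in raw:
            kwargs["clones"] = tuple(raw["clones"])
        if "offspring_per_mother" in raw:
            kwargs["offspring_per_mother"] = tuple(raw["offspring_per_mother"])
        if "body_length_ranges" in raw:
            kwargs["body_length_ranges"] = {
                int(k): tuple(v) for k, v in raw["body_length_ranges"].items()
            }
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# Linear predictors per design cell
# ---------------------------------------------------------------------------

def _coef_vector(coefs: Mapping[str, float], names: Sequence[str], what: str) -> np.ndarray:
    unknown = set(coefs) - set(names)
    if unknown:
        raise ValueError(f"unknown design column(s) in {what}: {sorted(unknown)}")
    return np.array([coefs.get(n, 0.0) for n in names])


def _cell_frame(clones: Sequence[str]) -> pd.DataFrame:
    rows = [
        {"clone": c, "kairomone": k, "uvr": u}
        for c in clones
        for k in (False, True)
        for u in (False, True)
    ]
    return pd.DataFrame(rows)


def defense_cell_etas(
    config: GeneratorConfig, instar: int
) -> dict[tuple[str, bool, bool], tuple[float, float]]:
    """(eta_neckteeth, eta_pedestal) per (clone, kairomone, uvr) cell,
    excluding mother effects — the analytic calibration oracle hook."""
    truth = config.defense_truths[instar]
    frame = _cell_frame(config.clones)
    spec = DesignSpec.from_frame(
        frame, ["clone", "kairomone", "uvr"], max_interaction_order=2,
        levels={"kairomone": (False, True), "uvr": (False, True)},
    )
    X, names = build_design_matrix(frame, spec)
    bn = _coef_vector(truth.beta_n, names, "beta_n")
    bp = _coef_vector(truth.beta_p, names[1:], "beta_p")
    eta_n = X @ bn
    eta_p = X[:, 1:] @ bp
    return {
        (row.clone, bool(row.kairomone), bool(row.uvr)): (float(eta_n[i]), float(eta_p[i]))
        for i, row in enumerate(frame.itertuples())
    }


def _morpho_cell_means(config: GeneratorConfig) -> dict[tuple[str, int, bool, bool], np.ndarray]:
    truth = config.morpho_truth
    rows = [
        {"clone": c, "instar": i, "kairomone": k, "uvr": u}
        for c in config.clones
        for i in (1, 2)
        for k in (False, True)
        for u in (False, True)
    ]
    frame = pd.DataFrame(rows)
    spec = DesignSpec.from_frame(
        frame, ["clone", "instar", "kairomone", "uvr"], max_interaction_order=3,
        levels={"instar": (1, 2), "kairomone": (False, True), "uvr": (False, True)},
    )
    X, names = build_design_matrix(frame, spec)
    B = np.column_stack(
        [_coef_vector(truth.coef[t], names, f"morpho coef ({t})") for t in TRAITS]
    )
    mu = X @ B
    return {
        (row.clone, int(row.instar), bool(row.kairomone), bool(row.uvr)): mu[i]
        for i, row in enumerate(frame.itertuples())
    }


# ---------------------------------------------------------------------------
# Simulators
# ---------------------------------------------------------------------------

def _draw_pedestal(eta_p: float, tau, rng: np.random.Generator) -> str:
    probs = ordinal_category_probs(eta_p, tau)
    return "ABC"[int(np.searchsorted(np.cumsum(probs), rng.random()))]


def _draw_morpho(
    mu: np.ndarray,
    chol: np.ndarray,
    bl_range: tuple[float, float],
    rng: np.random.Generator,
    max_tries: int = 1000,
) -> np.ndarray:
    """Rejection sampling into the printed body-length range and the
    positive orthant; clips in the (vanishingly rare) exhaustion case."""
    lo, hi = bl_range
    for _ in range(max_tries):
        y = mu + chol @ rng.standard_normal(3)
        if lo <= y[0] <= hi and np.all(y > 0):
            return y
    y = np.abs(mu + chol @ rng.standard_normal(3))
    y[0] = np.clip(y[0], lo, hi)
    return y


def simulate_main_experiment(config: GeneratorConfig = GeneratorConfig()) -> list[JuvenileRecord]:
    """Per-juvenile records of the main clone x kairomone x UVR experiment.

    Each mother carries instar- and response-specific random intercepts
    shared by her offspring (maternal clustering). Every juvenile yields an
    instar-1 row; survivors yield an instar-2 row with the same mother_uid.
    Under +UVR a juvenile fails to reach instar 2 with probability
    ``uvr_instar2_mortality``; without UVR all juveniles survive.
    """
    etas = {instar: defense_cell_etas(config, instar) for instar in (1, 2)}
    taus = {instar: config.defense_truths[instar].tau for instar in (1, 2)}
    morpho_mu = _morpho_cell_means(config)
    chol = np.linalg.cholesky(config.morpho_truth.Sigma)
    sigma_u = np.asarray(config.morpho_truth.sigma_u)

    records: list[JuvenileRecord] = []
    lo_off, hi_off = config.offspring_per_mother
    for ci, clone in enumerate(config.clones):
        for kair in (False, True):
            for uvr in (False, True):
                for m in range(1, config.mothers_per_treatment + 1):
                    ss = np.random.SeedSequence(
                        entropy=config.seed, spawn_key=(1, ci, int(kair), int(uvr), m)
                    )
                    rng = np.random.default_rng(ss)
                    uid = make_mother_uid(clone, kair, uvr, m)
                    u_def = {
                        instar: (
                            rng.normal(0.0, config.defense_truths[instar].sigma_n),
                            rng.normal(0.0, config.defense_truths[instar].sigma_p),
                        )
                        for instar in (1, 2)
                    }
                    u_morpho = rng.normal(0.0, sigma_u)
                    n_off = int(rng.integers(lo_off, hi_off + 1))
                    for _ in range(n_off):
                        survived = (not uvr) or (
                            rng.random() >= config.uvr_instar2_mortality
                        )
                        for instar in (1, 2):
                            if instar == 2 and not survived:
                                continue
                            eta_n, eta_p = etas[instar][(clone, kair, uvr)]
                            un, up = u_def[instar]
                            k = int(rng.binomial(5, expit(eta_n + un)))
                            ped = _draw_pedestal(eta_p + up, taus[instar], rng)
                            y = _draw_morpho(
                                morpho_mu[(clone, instar, kair, uvr)] + u_morpho,
                                chol,
                                config.body_length_ranges[instar],
                                rng,
                            )
                            lengths = [float(v) for v in y]
                            if instar == 2 and rng.random() < config.morpho_missing_prob:
                                # corrupted photograph: all lengths lost, or
                                # only the spina tip unreadable
                                if rng.random() < 0.5:
                                    lengths = [None, None, None]
                                else:
                                    lengths[2] = None
                            if (
                                config.include_missing_cell
                                and instar == 1
                                and clone == "P5"
                                and kair
                                and uvr
                            ):
                                continue
                            records.append(
                                JuvenileRecord(
                                    clone=clone,
                                    kairomone=kair,
                                    uvr=uvr,
                                    instar=instar,
                                    mother_uid=uid,
                                    neckteeth=k,
                                    pedestal=ped,
                                    body_length=lengths[0],
                                    body_width=lengths[1],
                                    spina_length=lengths[2],
                                    survived_to_instar2=survived if instar == 1 else True,
                                )
                            )
    return records


def simulate_effectivity_experiment(
    config: GeneratorConfig = GeneratorConfig(),
) -> list[EffectivityRecord]:
    """Records of the kairomone-effectivity trial: 3 treatments x 4 exposure
    durations, 2 mothers x 5 offspring per cell (10 juveniles per cell)."""
    truth = config.effectivity_truth
    records: list[EffectivityRecord] = []
    for ti, treatment in enumerate(("control", "PAR", "UVR")):
        kair = treatment != "control"
        eta_n = truth.eta_n_kairomone if kair else truth.eta_n_control
        eta_p = truth.eta_p_kairomone if kair else truth.eta_p_control
        for hours in (2, 4, 6, 8):
            for m in range(1, config.effectivity_mothers_per_cell + 1):
                ss = np.random.SeedSequence(
                    entropy=config.seed, spawn_key=(2, ti, hours, m)
                )
                rng = np.random.default_rng(ss)
                un = rng.normal(0.0, truth.sigma_n)
                up = rng.normal(0.0, truth.sigma_p)
                uid = f"UNI.{treatment}.{hours}h.{m}"
                for _ in range(config.effectivity_offspring_per_mother):
                    k = int(rng.binomial(5, expit(eta_n + un)))
                    ped = _draw_pedestal(eta_p + up, truth.tau, rng)
                    records.append(
                        EffectivityRecord(
                            treatment=treatment,
                            exposure_hours=hours,
                            mother_uid=uid,
                            neckteeth=k,
                            pedestal=ped,
                        )
                    )
    return records
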