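"""End-to-end orchestration: simulate or ingest data, fit the three model
families, and emit diagnostics, effect tables, hypothesis tests, figures,
and a run manifest.

The layout of a run directory::

    run/
      juveniles.csv / effectivity.csv      the analyzed tables
      manifest.json                        config, seeds, artifact list, status
      <model>/draws.csv + draws.json       posterior draws + sidecar
      <model>/effects.csv                  effect summary table
      <model>/diagnostics.json             R-hat / ESS / gate result
      <model>/forest.png                   forest plot
      effectivity/hypotheses.csv           Savage-Dickey contrasts
      induction_scores.csv                 descriptive Tollrian-score summary

Simulate mode writes the CSV and re-reads it before fitting, so an ingest
run on a generator-written file reproduces the simulate run bit for bit.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import (
    read_effectivity_table,
    read_juvenile_table,
    tollrian_induction_score,
    write_effectivity_table,
    write_juvenile_table,
)
from .models import DefenseTraitModel, EffectivityModel, MorphometricModel
from .sampling import PRESETS, SamplerConfig
from .simulate import GeneratorConfig, simulate_effectivity_experiment, simulate_main_experiment

__all__ = ["RunConfig", "ConvergenceError", "run_effectivity_analysis", "run_main_analysis", "make_report"]

logger = logging.getLogger(__name__)


class ConvergenceError(RuntimeError):
    """A final (reduced) model failed the identifiability screen."""


@dataclass
class RunConfig:
    """Configuration of a pipeline run."""

    out_dir: Path
    mode: str = "simulate"  # or "ingest"
    juveniles_path: Path | None = None
    effectivity_path: Path | None = None
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    preset: str = "full"  # "full" or a reduced testing preset
    seed: int = 0
    rhat_threshold: float = 1.05

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        if self.mode not in ("simulate", "ingest"):
            raise ValueError(f"mode must be simulate or ingest, got {self.mode!r}")
        if self.mode == "ingest":
            for p in (self.juveniles_path, self.effectivity_path):
                if p is not None and not Path(p).exists():
                    raise FileNotFoundError(p)

    def sampler(self, which: str) -> SamplerConfig:
        if self.preset == "full":
            base = PRESETS["full_effectivity" if which == "effectivity" else "full_main"]
        else:
            base = PRESETS[self.preset]
        return dataclasses.replace(base, seed=self.seed)

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(open(path)) or {}
        gen_raw = raw.pop("generator", {})
        gen = GeneratorConfig(**gen_raw) if gen_raw else GeneratorConfig()
        kwargs = {**raw, **overrides}
        kwargs.setdefault("generator", gen)
        return cls(**kwargs)


def _write_model_artifacts(outdir: Path, name: str, results, rhat_threshold: float) -> dict:
    mdir = outdir / name
    mdir.mkdir(parents=True, exist_ok=True)
    results.draws.save(mdir / "draws.csv", mdir / "draws.json")
    summary = results.summary()
    summary.to_csv(mdir / "effects.csv", index=False)
    results.plot_forest(mdir / "forest.png")
    passed, offending = results.check_identifiability(rhat_threshold)
    diag = {
        "max_rhat": results.max_rhat(),
        "min_ess": min(results.ess().values()),
        "rhat_threshold": rhat_threshold,
        "identifiable": passed,
        "offending_parameters": offending,
        "n_retained_draws": results.draws.n_retained,
    }
    (mdir / "diagnostics.json").write_text(json.dumps(diag, indent=2))
    return {
        "name": name,
        "identifiable": passed,
        "offending_parameters": offending,
        "max_rhat": diag["max_rhat"],
        "artifacts": [
            str(mdir / f) for f in ("draws.csv", "draws.json", "effects.csv", "diagnostics.json", "forest.png")
        ],
    }


def _write_manifest(outdir: Path, payload: dict) -> None:
    (outdir / "manifest.json").write_text(json.dumps(payload, indent=2, default=str))


def fit_with_reduction(
    model_factory,
    max_order_start: int,
    sampler_config: SamplerConfig,
    rhat_threshold: float = 1.05,
    min_order: int = 1,
):
    """The interaction-reduction workflow: fit, and if any parameter's
    R-hat exceeds the threshold (unidentifiable, overfitted), drop the
    highest interaction order and refit. Returns (results, order_used)."""
    order = max_order_start
    while True:
        results = model_factory(order).fit(sampler_config)
        passed, offending = results.check_identifiability(rhat_threshold)
        if passed:
            return results, order
        if order <= min_order:
            raise ConvergenceError(
                f"model unidentifiable at minimum interaction order; offending: {offending}"
            )
        logger.info(
            "interaction order %d unidentifiable (%s); reducing to %d",
            order, ", ".join(offending[:5]), order - 1,
        )
        order -= 1


def run_effectivity_analysis(config: RunConfig) -> dict:
    """Fit the pooled 3-treatment bivariate model to the effectivity trial
    and test kairomone-vs-control and UVR-vs-PAR contrasts."""
    outdir = Path(config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    csv_path = outdir / "effectivity.csv"
    if config.mode == "simulate":
        gen = dataclasses.replace(config.generator, seed=config.seed)
        write_effectivity_table(simulate_effectivity_experiment(gen), csv_path)
    else:
        csv_path = Path(config.effectivity_path)
    records = read_effectivity_table(csv_path)

    model = EffectivityModel(records)
    results = model.fit(config.sampler("effectivity"))
    entry = _write_model_artifacts(outdir, "effectivity", results, config.rhat_threshold)

    hyp_rows = []
    for response in ("neckteeth", "pedestal"):
        for contrast in ("kairomone_vs_control", "uvr_vs_par"):
            ev = results.contrast_savage_dickey(response, contrast)
            lo, hi = results.contrast_ci(response, contrast)
            hyp_rows.append(
                {
                    "response": response,
                    "contrast": contrast,
                    "ci95_low": lo,
                    "ci95_high": hi,
                    "strong": results.contrast_is_strong(response, contrast),
                    "evidence_ratio": ev.evidence_ratio,
                }
            )
    pd.DataFrame(hyp_rows).to_csv(outdir / "effectivity" / "hypotheses.csv", index=False)
    entry["artifacts"].append(str(outdir / "effectivity" / "hypotheses.csv"))

    manifest = {
        "kind": "effectivity",
        "mode": config.mode,
        "seed": config.seed,
        "preset": config.preset,
        "data": str(csv_path),
        "n_records": len(records),
        "models": [entry],
    }
    _write_manifest(outdir, manifest)
    if not entry["identifiable"]:
        raise ConvergenceError(
            f"effectivity model failed the convergence gate: {entry['offending_parameters']}"
        )
    return manifest


def run_main_analysis(config: RunConfig) -> dict:
    """Fit the per-instar defense models and the joint morphometric model
    to the main experiment, plus a descriptive induction-score summary."""
    outdir = Path(config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    csv_path = outdir / "juveniles.csv"
    if config.mode == "simulate":
        gen = dataclasses.replace(config.generator, seed=config.seed)
        write_juvenile_table(simulate_main_experiment(gen), csv_path)
    else:
        csv_path = Path(config.juveniles_path)
    records = read_juvenile_table(csv_path)

    sampler = config.sampler("main")
    entries = []
    failures = []
    results_by_name = {}
    for instar in (1, 2):
        model = DefenseTraitModel.from_records(records, instar=instar)
        results = model.fit(sampler)
        name = f"defense_instar{instar}"
        entry = _write_model_artifacts(outdir, name, results, config.rhat_threshold)
        entries.append(entry)
        results_by_name[name] = results
        if not entry["identifiable"]:
            failures.append(name)

    morpho = MorphometricModel.from_records(records)
    results = morpho.fit(sampler)
    entry = _write_model_artifacts(outdir, "morphometrics", results, config.rhat_threshold)
    entries.append(entry)
    results_by_name["morphometrics"] = results
    if not entry["identifiable"]:
        failures.append("morphometrics")

    # descriptive appendix: Tollrian induction scores per design cell
    frame = pd.read_csv(csv_path)
    frame["induction_score"] = [
        tollrian_induction_score(int(k), str(p))
        for k, p in zip(frame["neckteeth"], frame["pedestal"])
    ]
    scores = (
        frame.groupby(["clone", "instar", "kairomone", "uvr"])["induction_score"]
        .agg(["mean", "std", "count"])
        .reset_index()
    )
    scores.to_csv(outdir / "induction_scores.csv", index=False, float_format="%.4f")

    manifest = {
        "kind": "main",
        "mode": config.mode,
        "seed": config.seed,
        "preset": config.preset,
        "data": str(csv_path),
        "n_records": len(records),
        "models": entries,
        "failed_models": failures,
    }
    _write_manifest(outdir, manifest)
    if failures:
        raise ConvergenceError(f"model(s) failed the convergence gate: {failures}")
    return manifest


def make_report(run_dir) -> Path:
    """Collate a completed run into a single human-readable markdown report.

    Missing artifacts are listed, not fatal; regenerating the report from
    the same run directory yields identical content.
    """
    run_dir = Path(run_dir)
    manifest_path = run_dir / "manifest.json"
    lines = ["# Analysis run report", ""]
    missing: list[str] = []
    if not manifest_path.exists():
        lines.append("manifest.json is missing; no run metadata available.")
        report = run_dir / "report.md"
        report.write_text("\n".join(lines) + "\n")
        return report
    manifest = json.loads(manifest_path.read_text())
    lines += [
        f"- kind: {manifest.get('kind')}",
        f"- mode: {manifest.get('mode')}",
        f"- seed: {manifest.get('seed')}",
        f"- preset: {manifest.get('preset')}",
        f"- records analyzed: {manifest.get('n_records')}",
        "",
    ]
    for entry in manifest.get("models", []):
        name = entry["name"]
        lines.append(f"## Model: {name}")
        status = "converged" if entry.get("identifiable") else "FAILED convergence gate"
        lines.append(f"- status: {status} (max R-hat {entry.get('max_rhat'):.4f})")
        if not entry.get("identifiable"):
            lines.append(
                f"- offending parameters: {', '.join(entry.get('offending_parameters', []))}"
            )
        effects = run_dir / name / "effects.csv"
        if effects.exists():
            table = pd.read_csv(effects)
            lines.append("")
            lines.append(table.to_markdown(index=False, floatfmt=".3f"))
        else:
            missing.append(str(effects))
        hyp = run_dir / name / "hypotheses.csv"
        if hyp.exists():
            lines.append("")
            lines.append("### Hypothesis tests (Savage-Dickey)")
            lines.append(pd.read_csv(hyp).to_markdown(index=False, floatfmt=".3f"))
        lines.append("")
    scores = run_dir / "induction_scores.csv"
    if scores.exists():
        lines.append("## Tollrian induction scores (descriptive)")
        lines.append("")
        lines.append(pd.read_csv(scores).to_markdown(index=False, floatfmt=".2f"))
        lines.append("")
    if missing:
        lines.append("## Missing artifacts")
        lines += [f"- {m}" for m in missing]
        lines.append("")
    report = run_dir / "report.md"
    report.write_text("\n".join(lines) + "\n")
    return report
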