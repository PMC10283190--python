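"""End-to-end runner: simulate or load data, fit the requested families,
diagnose, compare, and write every artifact with full provenance.

A single global seed fans out deterministically to per-stage seeds
(data generation, one per fitted family) through ``numpy``'s
``SeedSequence`` spawning, so each stage can be reproduced in isolation
and identical configurations yield byte-identical artifacts.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import __version__
from .data import HierarchicalCountData
from .descriptives import dispersion_check, vpc, weighted_summary, zero_histogram
from .families import Family
from .mcmc import SamplerConfig, diagnostics, run_mcmc
from .model import HierarchicalCountModel, ModelSpec, PriorConfig
from .selection import compare, fit_ic
from .simulate import scaled_presets, simulate_dataset

log = logging.getLogger("vaxcount.pipeline")

ALL_FAMILIES = (Family.POISSON, Family.NB, Family.ZIP, Family.ZINB)
PRESETS = ("full", "dhs-like", "desk", "tiny")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run."""

    input: str  # preset name or CSV path
    output_dir: str
    seed: int = 0
    models: tuple[Family, ...] = ALL_FAMILIES
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    priors: PriorConfig | None = None
    count_formula: tuple[str, ...] | None = None  # None = all covariates

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError("at least one model family is required")
        object.__setattr__(self, "models", tuple(Family(m) for m in self.models))

    def to_dict(self) -> dict:
        return {
            "input": self.input,
            "output_dir": self.output_dir,
            "seed": self.seed,
            "models": [m.value for m in self.models],
            "sampler": self.sampler.to_dict(),
            "priors": self.priors.to_dict() if self.priors else None,
            "count_formula": list(self.count_formula) if self.count_formula else None,
        }


def validate_input(path: str | Path) -> HierarchicalCountData:
    """Load a dataset CSV, reporting every schema violation at once."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    data = HierarchicalCountData.from_csv(path)  # raises DataValidationError
    return data


def stage_seeds(seed: int, models: tuple[Family, ...]) -> dict[str, int]:
    """Deterministic per-stage seeds derived from the global seed."""
    children = np.random.SeedSequence(seed).spawn(1 + len(models))
    seeds = {"data": int(children[0].generate_state(1)[0] % 2**31)}
    for m, ss in zip(models, children[1:]):
        seeds[m.value] = int(ss.generate_state(1)[0] % 2**31)
    return seeds


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; returns the artifact manifest (also written to disk)."""
    t0 = time.time()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed, config.models)
    manifest: dict = {
        "config": config.to_dict(),
        "stage_seeds": seeds,
        "package_version": __version__,
        "artifacts": {},
        "stages": [],
    }

    # -- data ---------------------------------------------------------------
    if config.input in PRESETS:
        design, truth = scaled_presets(config.input)
        data = simulate_dataset(design, truth, seed=seeds["data"])
        log.info("simulated preset %r: %d children", config.input, data.n)
    else:
        data = validate_input(config.input)
        log.info("loaded %s: %d children", config.input, data.n)
    data.to_csv(out / "dataset.csv")
    manifest["artifacts"]["dataset"] = "dataset.csv"
    manifest["stages"].append({"stage": "data", "n": data.n, "seconds": round(time.time() - t0, 2)})

    # -- descriptives ---------------------------------------------------------
    weighted_summary(data.y, data.weights, by_year=data.df["year"].to_numpy()).to_csv(
        out / "summary.csv")
    zero_histogram(data.y, data.weights, max_count=data.meta.get("max_count", 9)).to_csv(
        out / "outcome_histogram.csv", index=False)
    disp = dispersion_check(data.y, data.weights)
    (out / "dispersion.json").write_text(json.dumps(disp.__dict__, indent=2))
    manifest["artifacts"]["summary"] = "summary.csv"

    # -- fits ----------------------------------------------------------------
    count_formula = (tuple(config.count_formula) if config.count_formula
                     else tuple(data.covariate_names))
    results = []
    failed = []
    for fam in config.models:
        t1 = time.time()
        spec = ModelSpec(family=fam, count_formula=count_formula)
        sampler = replace(config.sampler, seed=seeds[fam.value])
        draws = run_mcmc(data, spec, priors=config.priors, config=sampler)
        draws.to_csv(out / f"draws_{fam.value}.csv")
        report = diagnostics(draws)
        report.table.to_csv(out / f"diagnostics_{fam.value}.csv", index=False)
        if report.flagged:
            log.warning("%s: %d flagged parameters", fam.value, len(report.flagged))
            failed.append(fam.value)
        ic = fit_ic(draws, data, spec)
        (out / f"ic_{fam.value}.json").write_text(json.dumps(ic.summary(), indent=2))
        if fam.has_dispersion or fam is Family.POISSON:
            model = HierarchicalCountModel(data, spec)
            vpc(draws, model).to_csv(out / f"vpc_{fam.value}.csv")
        results.append(ic)
        manifest["stages"].append({
            "stage": f"fit_{fam.value}",
            "retained_draws": draws.n_chains * draws.n_draws,
            "flagged_parameters": len(report.flagged),
            "seconds": round(time.time() - t1, 2),
        })
        log.info("fitted %s in %.1fs", fam.value, time.time() - t1)

    # -- comparison ----------------------------------------------------------
    if len(results) >= 2:
        table = compare(results)
        table.table.to_csv(out / "comparison.csv", index=False)
        (out / "comparison.txt").write_text(table.to_text() + "\n")
        manifest["artifacts"]["comparison"] = "comparison.csv"
        manifest["selected_model"] = table.winner

    manifest["convergence_flagged"] = failed
    manifest["total_seconds"] = round(time.time() - t0, 2)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
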