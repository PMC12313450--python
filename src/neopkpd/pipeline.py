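"""End-to-end runs: population -> regimens -> simulation -> exposure metrics,
and the external-evaluation battery, with tidy CSV outputs and a JSON
run manifest (seed, config hash, versions) sufficient to reproduce the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import __version__
from .dataset import ObservationDataset
from .evaluation import (
    individual_predict,
    npde,
    pcvpc,
    population_predict,
    prediction_error_metrics,
)
from .exposure import (
    DEFAULT_FRACTION_GRID,
    DEFAULT_MIC_GRID,
    PROTEIN_BOUND_PCT,
    PTA_WINDOW,
    TOXICITY_THRESHOLDS,
    binding_sensitivity,
    pta_grid,
    toxicity_frame,
    toxicity_summary,
)
from .model import ModelSpec, individual_parameters, load_model_spec
from .population import generate_population, load_growth_reference, population_frame
from .regimens import DoseSchedule, load_regimen_catalog, resolve_regimen
from .simulate import ConcentrationProfile, default_time_grid, simulate_profile

logger = logging.getLogger(__name__)


class RunConfig(BaseModel):
    """Configuration of a PTA/toxicity simulation run."""

    drug: str = "benzylpenicillin"
    model: str = ""  # bundled name or YAML path; defaults to the drug name
    regimens: list[str] = Field(default_factory=list)  # catalog names; default: all for drug
    regimen_catalog: Optional[str] = None
    growth_reference: Optional[str] = None
    ga_min: int = 24
    ga_max: int = 42
    n_per_week: int = 500
    seed: int = 12345
    mic_grid: list[float] = Field(default_factory=lambda: list(DEFAULT_MIC_GRID))
    fraction_grid: list[float] = Field(default_factory=lambda: list(DEFAULT_FRACTION_GRID))
    multipliers: list[float] = Field(default_factory=lambda: [1.0, 4.0])
    bound_pct: Optional[float] = None  # default: drug-specific constant
    binding_sweep: list[float] = Field(default_factory=list)
    toxicity_thresholds: list[float] = Field(default_factory=list)
    window_h: float = 48.0
    grid_step_h: float = 0.05


def simulate_regimen_profiles(
    subjects,
    spec: ModelSpec,
    rules,
    window_h: float = 48.0,
    grid_step_h: float = 0.05,
) -> list[ConcentrationProfile]:
    """Simulate every subject on one regimen (no residual error: PTA concerns
    true concentration-time courses, not measurements)."""
    grid = default_time_grid(window_h, grid_step_h)
    profiles = []
    for s in subjects:
        schedule = (
            rules(s, window_h) if callable(rules) else resolve_regimen(s, rules, window_h)
        )
        params = individual_parameters(s, spec, eta=s.eta)
        profiles.append(simulate_profile(params, schedule, grid))
    return profiles


@dataclass
class PtaRunResult:
    pta_table: pd.DataFrame
    toxicity_table: pd.DataFrame
    binding_table: Optional[pd.DataFrame]
    population: pd.DataFrame
    manifest: dict


def run_pta(config: RunConfig, out_dir: Optional[str | Path] = None) -> PtaRunResult:
    """Execute the full simulation pipeline for one drug.

    The virtual population (and its random-effect draws) is generated once
    and shared across regimens, so regimen contrasts are paired. Writes
    ``pta.csv``, ``toxicity.csv``, ``population.csv`` (+ ``binding_sensitivity.csv``)
    and ``manifest.json`` when ``out_dir`` is given.
    """
    t0 = time.time()
    spec = load_model_spec(config.model or config.drug)
    ref = load_growth_reference(config.growth_reference) if config.growth_reference \
        else load_growth_reference()
    catalog = load_regimen_catalog(config.regimen_catalog) if config.regimen_catalog \
        else load_regimen_catalog()
    names = config.regimens or [
        key.split("/")[0] for key in catalog if key.endswith(f"/{config.drug}")
    ]
    bound = config.bound_pct if config.bound_pct is not None else PROTEIN_BOUND_PCT[config.drug]
    thresholds = config.toxicity_thresholds or TOXICITY_THRESHOLDS[config.drug]

    subjects = generate_population(
        config.ga_min, config.ga_max, config.n_per_week, ref, config.seed, model_spec=spec
    )
    logger.info("generated %d subjects (%d/GA week)", len(subjects), config.n_per_week)
    from .model import subject_covariates, warn_if_extrapolating

    warn_if_extrapolating(spec, subject_covariates(subjects[0]))  # youngest GA stratum

    pta_frames, tox_frames, binding_frames = [], [], []
    for name in names:
        rules = catalog[f"{name}/{config.drug}"]
        profiles = simulate_regimen_profiles(
            subjects, spec, rules, config.window_h, config.grid_step_h
        )
        logger.info("regimen %s: simulated %d profiles", name, len(profiles))
        g = pta_grid(
            profiles,
            config.mic_grid,
            config.fraction_grid,
            config.multipliers,
            bound,
            window=(PTA_WINDOW[0], config.window_h),
            regimen=name,
        )
        pta_frames.append(g)
        for thr in thresholds:
            tox = toxicity_summary(profiles, thr, subjects, window=(0.0, config.window_h))
            tox_frames.append(toxicity_frame(tox, regimen=name))
        if config.binding_sweep:
            b = binding_sensitivity(
                profiles, config.binding_sweep, bound,
                config.mic_grid, config.fraction_grid, config.multipliers,
                window=(PTA_WINDOW[0], config.window_h),
            )
            b["regimen"] = name
            binding_frames.append(b)

    result = PtaRunResult(
        pta_table=pd.concat(pta_frames, ignore_index=True),
        toxicity_table=pd.concat(tox_frames, ignore_index=True),
        binding_table=pd.concat(binding_frames, ignore_index=True) if binding_frames else None,
        population=population_frame(subjects),
        manifest=_manifest(config, t0, n_subjects=len(subjects), regimens=names),
    )
    if out_dir is not None:
        _write_outputs(out_dir, result)
    return result


def run_evaluation(
    dataset: ObservationDataset,
    model: str,
    n_sim: int = 1000,
    seed: int = 0,
    out_dir: Optional[str | Path] = None,
) -> dict:
    """External-evaluation battery: prediction-error report, GOF table,
    pcVPC and NPDE tables; all stochastic diagnostics seeded."""
    if dataset.n_observations == 0:
        raise ValueError("dataset contains no observations; nothing to evaluate")
    t0 = time.time()
    spec = load_model_spec(model)
    pred = population_predict(dataset, spec)
    dv = np.concatenate([dataset.subject(sid).dv for sid in dataset.subject_ids])
    report = prediction_error_metrics(pred, dv)
    gof = individual_predict(dataset, spec)
    vpc = pcvpc(dataset, spec, n_sim=n_sim, seed=seed)
    nd = npde(dataset, spec, n_sim=n_sim, seed=seed)
    out = {
        "prediction_errors": report,
        "gof": gof,
        "pcvpc": vpc,
        "npde": nd,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        report.per_observation.to_csv(out_dir / "prediction_errors.csv", index=False)
        gof.to_csv(out_dir / "gof.csv", index=False)
        vpc.table.to_csv(out_dir / "pcvpc.csv", index=False)
        nd.per_observation.to_csv(out_dir / "npde.csv", index=False)
        summary = {
            "ppe_median": report.ppe_median,
            "appe_median": report.appe_median,
            "nrmse": report.nrmse,
            "p10": report.p10,
            "p20": report.p20,
            "p30": report.p30,
            "npde_mean": nd.mean,
            "npde_variance": nd.variance,
            "pcvpc_coverage": vpc.coverage,
            "n_sim": n_sim,
            "seed": seed,
            "model": model,
            "runtime_s": round(time.time() - t0, 2),
            "version": __version__,
        }
        (out_dir / "manifest.json").write_text(json.dumps(summary, indent=2))
    return out


def _manifest(config: RunConfig, t0: float, **extra) -> dict:
    payload = config.model_dump_json()
    return {
        "config": json.loads(payload),
        "config_sha256": hashlib.sha256(payload.encode()).hexdigest(),
        "seed": config.seed,
        "version": __version__,
        "runtime_s": round(time.time() - t0, 2),
        **extra,
    }


def _write_outputs(out_dir: str | Path, result: PtaRunResult) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    result.pta_table.to_csv(out_dir / "pta.csv", index=False)
    result.toxicity_table.to_csv(out_dir / "toxicity.csv", index=False)
    result.population.to_csv(out_dir / "population.csv", index=False)
    if result.binding_table is not None:
        result.binding_table.to_csv(out_dir / "binding_sensitivity.csv", index=False)
    result.manifest["runtime_s"] = result.manifest.get("runtime_s")
    (out_dir / "manifest.json").write_text(json.dumps(result.manifest, indent=2))
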