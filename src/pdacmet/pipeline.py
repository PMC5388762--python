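"""Pipeline orchestration: configuration, stage execution and run manifests.

Ties the library stages together in dependency order — sample initial
conditions, reduce the parameter space by identifiability, run global
sensitivity, fit velocities and growth parameters, validate, screen — and
writes every artifact with provenance (configuration hash, seed, stage) so a
run can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .estimation import (
    FoldChangeDataset,
    GrowthDataset,
    fit_growth_parameters,
    fit_reaction_velocities,
)
from .identifiability import run_identifiability
from .network import load_network, load_reference_network
from .sampling import gaussian_initial_conditions, lhs_initial_conditions, load_reference_bounds
from .screens import combination_screen, knockdown_dose_response, nutrient_grid
from .sensitivity import efast
from .simulate import Protocol, baseline_directions, detect_flux_reversals, simulate
from .synth import make_ground_truth, simulate_training_dataset

__all__ = ["PipelineConfig", "run_pipeline", "STAGES"]

STAGES = ("synth", "sample", "identify", "sensitivity", "fit", "simulate", "screen")


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run.

    Defaults are scaled down from the full-scale design so that a complete
    run finishes on a laptop; the full-scale counts are noted per field.
    """

    network: str | None = None  # None -> packaged reference configuration
    output_dir: str = "pdacmet_run"
    stages: Sequence[str] = ("synth", "sample", "identify", "fit", "simulate", "screen")
    seed: int = 0
    # sampling (full design: 100 LHS sets, 50 kept for estimation)
    n_lhs: int = 100
    n_estimation_subset: int = 50
    n_gaussian: int = 1000
    # identifiability
    n_identifiability_ics: int = 6
    identifiability_threshold: float = 0.95
    # sensitivity (full design would use hundreds of samples per curve)
    efast_samples: int = 65
    efast_resamples: int = 1
    efast_parameters: Sequence[str] | None = None
    # estimation (full design: 50 particles, 2 x 2500 iterations, 100 restarts)
    pso_particles: int = 20
    pso_iterations: int = 30
    pso_runs: int = 1
    fit_parameters: Sequence[str] | None = None
    growth_restarts: int = 10
    # datasets (paths to CSV tables; when omitted the synth stage must run)
    fold_change_data: str | None = None
    growth_data: str | None = None
    # synthetic study
    synth_perturbation: float = 0.2
    synth_noise_cv: float = 0.0
    # screens
    screen_targets: Sequence[str] = ("GLUT1", "GOT2")
    dose_response_target: str = "GOT1"
    dose_levels: Sequence[float] = (0.05, 0.25, 0.5, 0.75, 0.85, 1.0)
    grid_glucose: Sequence[float] = (0.0, 3.5, 35.0)
    grid_glutamine: Sequence[float] = (0.0, 0.6, 6.0)
    akt_level: float = 1.0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        cfg = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(cfg) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        cfg.update(overrides)
        return cls(**cfg)

    def validate(self) -> None:
        bad = [s for s in self.stages if s not in STAGES]
        if bad:
            raise ValueError(f"unknown stages {bad}; valid stages are {STAGES}")
        for attr in ("network", "fold_change_data", "growth_data"):
            path = getattr(self, attr)
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"{attr} path does not exist: {path}")

    def content_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the requested stages in dependency order.

    Returns the run manifest (also written to ``manifest.json``), listing the
    executed stages, their seeds and the artifact files produced.  Any stage
    failure raises, leaving the partial outputs and a diagnostic entry in
    the manifest on disk.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "stages": [],
        "artifacts": {},
        "config": asdict(config),
    }
    rng = np.random.default_rng(config.seed)

    model = load_network(config.network) if config.network else load_reference_network()

    def save_table(name: str, df: pd.DataFrame) -> None:
        path = out / f"{name}.csv"
        df.to_csv(path, index=isinstance(df.index, pd.MultiIndex) or df.index.name is not None)
        manifest["artifacts"][name] = str(path)

    fc_data = None
    growth_data = None
    if config.fold_change_data:
        fc_data = FoldChangeDataset.from_frame(pd.read_csv(config.fold_change_data))
    if config.growth_data:
        growth_data = GrowthDataset.from_frame(pd.read_csv(config.growth_data))

    ordered = [s for s in STAGES if s in config.stages]
    ic_subset = None
    try:
        for stage in ordered:
            stage_seed = int(rng.integers(0, 2**31 - 1))
            if stage == "synth":
                truth, gp = make_ground_truth(
                    model, config.synth_perturbation, seed=stage_seed
                )
                study = simulate_training_dataset(
                    truth, noise_cv=config.synth_noise_cv, seed=stage_seed
                )
                fc_data = fc_data or study.fold_changes
                growth_data = growth_data or study.growth
                save_table("synthetic_fold_changes", study.fold_changes.to_frame())
                save_table("synthetic_growth", study.growth.to_frame())
                save_table("synthetic_validation_growth", study.validation_growth.to_frame())
            elif stage == "sample":
                bounds = load_reference_bounds()
                lhs = lhs_initial_conditions(bounds, config.n_lhs, seed=stage_seed)
                save_table("lhs_initial_conditions", lhs)
                keep = np.random.default_rng(stage_seed + 1).choice(
                    len(lhs), size=min(config.n_estimation_subset, len(lhs)), replace=False
                )
                ic_subset = lhs.iloc[np.sort(keep)].reset_index(drop=True)
                save_table("estimation_initial_conditions", ic_subset)
                baseline = {m.id: m.initial_concentration for m in model.metabolites}
                mc = gaussian_initial_conditions(baseline, config.n_gaussian, seed=stage_seed + 2)
                save_table("gaussian_initial_conditions", mc)
            elif stage == "identify":
                if ic_subset is None:
                    bounds = load_reference_bounds()
                    ic_subset = lhs_initial_conditions(
                        bounds, config.n_identifiability_ics, seed=stage_seed
                    )
                ics = ic_subset.iloc[: config.n_identifiability_ics]
                model, reports = run_identifiability(
                    model, ics, threshold=config.identifiability_threshold
                )
                save_table(
                    "identifiability_report",
                    pd.concat([r.table for r in reports], ignore_index=True),
                )
                manifest["free_velocities_after_identifiability"] = model.free_velocity_count()
            elif stage == "sensitivity":
                params = config.efast_parameters
                if params is None:
                    # default: velocities of the reference-knockdown pathway
                    params = [f"{r}.Vf" for r in ("GOT1", "GLS", "OXPHOS")
                              if r in model.reaction_ids]
                res = efast(
                    model,
                    parameter_names=list(params),
                    n_samples=config.efast_samples,
                    n_resamples=config.efast_resamples,
                    seed=stage_seed,
                )
                save_table("efast_indices", res.table)
            elif stage == "fit":
                if fc_data is None or growth_data is None:
                    raise ValueError(
                        "fit stage requires fold-change and growth datasets "
                        "(run the synth stage or provide data paths)"
                    )
                names = list(config.fit_parameters) if config.fit_parameters else None
                vel_fit = fit_reaction_velocities(
                    model,
                    fc_data,
                    parameter_names=names,
                    n_particles=config.pso_particles,
                    n_iterations=config.pso_iterations,
                    n_runs=config.pso_runs,
                    seed=stage_seed,
                )
                from .estimation import apply_velocity_values

                apply_velocity_values(model, vel_fit.parameter_names, vel_fit.parameters)
                save_table(
                    "fitted_velocities",
                    pd.DataFrame(
                        {"parameter": vel_fit.parameter_names, "value": vel_fit.parameters,
                         "wssr": vel_fit.wssr, "seed": vel_fit.seed}
                    ),
                )
                gp, gfit = fit_growth_parameters(
                    model,
                    growth_data,
                    n_restarts=config.growth_restarts,
                    seed=stage_seed + 1,
                )
                model.meta["growth"] = gp.to_dict()
                save_table(
                    "fitted_growth_parameters",
                    pd.DataFrame(
                        {"parameter": gfit.parameter_names, "value": gfit.parameters,
                         "wssr": gfit.wssr, "seed": gfit.seed}
                    ),
                )
            elif stage == "simulate":
                traj = simulate(model, Protocol.complete_media())
                save_table("control_trajectory", traj.to_tidy_frame())
                kd_ref = model.meta.get(
                    "knockdown_reference", {"reaction": "GOT1", "alpha": 0.85}
                )
                kd = simulate(
                    model,
                    Protocol.complete_media(
                        knockdowns=[(kd_ref["reaction"], float(kd_ref["alpha"]), 0.0)]
                    ),
                )
                save_table("knockdown_trajectory", kd.to_tidy_frame())
                save_table("knockdown_flux_matrix", kd.flux_matrix_frame())
                signs = baseline_directions(model)
                reversals = detect_flux_reversals(kd, signs, deadband=1e-6)
                save_table(
                    "flux_reversals",
                    pd.DataFrame(
                        [
                            {"reaction": rid, "start_min": a, "end_min": b}
                            for rid, intervals in reversals
                            for a, b in intervals
                        ]
                    ),
                )
            elif stage == "screen":
                dr = knockdown_dose_response(
                    model, config.dose_response_target, config.dose_levels
                )
                save_table("dose_response", dr.to_frame())
                reference = str(
                    model.meta.get("knockdown_reference", {"reaction": "GOT1"})["reaction"]
                )
                frames = []
                for target in config.screen_targets:
                    frames.append(combination_screen(model, target, reference=reference).to_frame())
                save_table("combination_screens", pd.concat(frames, ignore_index=True))
                grid = nutrient_grid(model, config.grid_glucose, config.grid_glutamine)
                save_table("nutrient_grid", grid)
            manifest["stages"].append({"name": stage, "seed": stage_seed})
    except Exception as exc:
        manifest["error"] = {"stage": stage, "message": str(exc)}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
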