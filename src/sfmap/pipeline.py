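"""End-to-end pipeline: ingest → markers → map → classify → calibrate → assign.

The declarative config (YAML/JSON, validated with pydantic) names either
real input tables plus a marker file, or a simulation block; a single seed
governs every random choice. Outputs are delimited tables, a map image, a
summary JSON and a manifest with the config hash for provenance.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from . import __version__
from .calibrate import (
    DEFAULT_FDR_TARGET,
    DEFAULT_FIXED_CUTOFFS,
    ThresholdSet,
    assign,
    calibrate_thresholds,
    summarize,
)
from .classify import ClassifierSpec, TrainedClassifier, score_all, tune_and_train
from .errors import ConfigurationError, PipelineError
from .ingest import build_profiles, read_profile_table, read_psm_table, write_profile_table
from .markers import MarkerSet, intersect_with_profiles, load_markers
from .simulate import SimulationConfig, default_templates, simulate_dataset
from .spatial_map import MapCoordinates, pca_project, render_map

logger = logging.getLogger(__name__)


class InputsBlock(BaseModel):
    psm_table: Optional[str] = None
    profile_table: Optional[str] = None
    pre_normalized: bool = False


class SimulationBlock(BaseModel):
    n_markers_per_class: int = 20
    n_unknowns_per_class: int = 100
    n_noise_proteins: int = 10
    frac_rep1_only: float = 0.05
    psm_per_protein: int = 4
    psm_noise_concentration: float = 200.0
    template_concentration: float = 60.0


class NormalizationBlock(BaseModel):
    renormalize_after_median: bool = True


class ClassifierBlock(BaseModel):
    cost_grid: list[float] = Field(default_factory=lambda: [2.0**k for k in range(-4, 5)])
    gamma_grid: list[float] = Field(default_factory=lambda: [2.0**k for k in range(-4, 5)])
    cv_outer_rounds: int = 100
    cv_inner_folds: int = 5


class CalibrationBlock(BaseModel):
    mode: Literal["fdr", "fixed"] = "fdr"
    fdr_target: float = DEFAULT_FDR_TARGET
    fixed_cutoffs: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_FIXED_CUTOFFS)
    )
    annotation: Optional[str] = None  # held-out labeled table for FDR mode
    annotation_fraction: float = 0.5  # simulation mode: share of non-markers annotated


class PipelineConfig(BaseModel):
    inputs: Optional[InputsBlock] = None
    simulation: Optional[SimulationBlock] = None
    markers: Optional[str] = None
    normalization: NormalizationBlock = Field(default_factory=NormalizationBlock)
    classifier: ClassifierBlock = Field(default_factory=ClassifierBlock)
    calibration: CalibrationBlock = Field(default_factory=CalibrationBlock)
    pca_scale: bool = False
    seed: int = 0
    output_dir: str = "results/run"

    @field_validator("seed")
    @classmethod
    def _seed_range(cls, v: int) -> int:
        if not 0 <= v < 2**31:
            raise ValueError("seed must lie in [0, 2^31)")
        return v

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.model_validate(raw or {})

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    profiles: pd.DataFrame
    dropped: list[str]
    markers: MarkerSet
    training_markers: MarkerSet
    coordinates: MapCoordinates
    classifier: TrainedClassifier
    scores: pd.DataFrame
    thresholds: ThresholdSet
    assignments: pd.DataFrame
    summary: dict
    truth: Optional[pd.DataFrame]
    annotation: dict[str, str]
    manifest: dict


def _simulation_config(block: SimulationBlock, seed: int) -> SimulationConfig:
    return SimulationConfig(
        templates=default_templates(block.template_concentration),
        n_markers_per_class=block.n_markers_per_class,
        n_unknowns_per_class=block.n_unknowns_per_class,
        n_noise_proteins=block.n_noise_proteins,
        frac_rep1_only=block.frac_rep1_only,
        psm_per_protein=block.psm_per_protein,
        psm_noise_concentration=block.psm_noise_concentration,
        seed=seed,
    )


def _load_annotation(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path)
    required = {"protein_id", "class"}
    if not required.issubset(df.columns):
        raise PipelineError(f"annotation table must have columns {sorted(required)}")
    from .markers import normalize_id

    return {
        normalize_id(pid): str(label).strip()
        for pid, label in zip(df["protein_id"], df["class"])
    }


def _sample_annotation(
    truth: pd.DataFrame, markers: MarkerSet, profiles: pd.DataFrame,
    fraction: float, seed: int,
) -> dict[str, str]:
    """Seeded held-out labeled sample of non-marker proteins (simulation mode)."""
    pool = truth[
        ~truth["protein_id"].isin(markers.entries)
        & truth["protein_id"].isin(profiles.index)
    ].sort_values("protein_id")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 211]))
    n = int(round(fraction * len(pool)))
    chosen = rng.choice(len(pool), size=n, replace=False)
    sub = pool.iloc[np.sort(chosen)]
    return dict(zip(sub["protein_id"], sub["true_label"]))


def run_pipeline(
    config: PipelineConfig | str | Path, write: bool = True
) -> PipelineResult:
    """Execute the full analysis. With ``write``, persist all outputs.

    Stages: (1) obtain a PSM or profile table (simulated or read), (2)
    normalize/aggregate/merge to both-replicate profiles, (3) validate the
    marker set against the data, (4) PCA map, (5) class-weighted SVM, (6)
    threshold calibration (FDR or fixed mode), (7) assignment + summary.
    """
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_file(config)
    if config.simulation is None and config.inputs is None:
        raise ConfigurationError("config needs an 'inputs' or a 'simulation' block")

    truth = None
    if config.simulation is not None:
        sim = simulate_dataset(_simulation_config(config.simulation, config.seed))
        psm_df = sim.psm_table
        markers = sim.markers
        truth = sim.truth
        profiles, dropped = build_profiles(
            psm_df, renormalize=config.normalization.renormalize_after_median
        )
    else:
        if config.markers is None:
            raise ConfigurationError("real-data runs require a 'markers' file")
        markers = load_markers(config.markers)
        if config.inputs.psm_table:
            psm_df = read_psm_table(config.inputs.psm_table)
            profiles, dropped = build_profiles(
                psm_df, renormalize=config.normalization.renormalize_after_median
            )
        elif config.inputs.profile_table:
            profiles, dropped = read_profile_table(
                config.inputs.profile_table,
                pre_normalized=config.inputs.pre_normalized,
            )
        else:
            raise ConfigurationError("inputs block names neither psm_table nor profile_table")

    training_markers, missing = intersect_with_profiles(markers, profiles.index)
    coordinates = pca_project(profiles, scale=config.pca_scale)

    spec = ClassifierSpec(
        cost_grid=tuple(config.classifier.cost_grid),
        gamma_grid=tuple(config.classifier.gamma_grid),
        cv_outer_rounds=config.classifier.cv_outer_rounds,
        cv_inner_folds=config.classifier.cv_inner_folds,
        seed=config.seed,
    )
    trained = tune_and_train(profiles, training_markers, spec)
    scores = score_all(trained, profiles)

    annotation: dict[str, str] = {}
    if config.calibration.mode == "fixed":
        thresholds = ThresholdSet.fixed(config.calibration.fixed_cutoffs)
    else:
        if config.calibration.annotation:
            annotation = _load_annotation(config.calibration.annotation)
        elif truth is not None:
            annotation = _sample_annotation(
                truth, training_markers, profiles,
                config.calibration.annotation_fraction, config.seed,
            )
        else:
            raise ConfigurationError(
                "FDR calibration on real data requires a held-out 'annotation' table"
            )
        thresholds = calibrate_thresholds(
            scores, annotation, config.calibration.fdr_target,
            classes=training_markers.classes,
        )

    assignments = assign(scores, thresholds, training_markers)
    summary = summarize(assignments, classes=training_markers.classes)
    summary["thresholds"] = thresholds.to_dict()
    summary["config_hash"] = config.config_hash()

    manifest = {
        "sfmap_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_proteins": int(len(profiles)),
        "n_dropped_single_replicate": len(dropped),
        "n_training_markers": len(training_markers),
        "markers_missing_from_data": missing,
        "classifier": trained.summary(),
        "calibration_mode": config.calibration.mode,
    }

    result = PipelineResult(
        profiles=profiles, dropped=dropped, markers=markers,
        training_markers=training_markers, coordinates=coordinates,
        classifier=trained, scores=scores, thresholds=thresholds,
        assignments=assignments, summary=summary, truth=truth,
        annotation=annotation, manifest=manifest,
    )
    if write:
        _write_outputs(result, config)
    return result


def _write_outputs(result: PipelineResult, config: PipelineConfig) -> None:
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_profile_table(result.profiles, outdir / "profiles.csv")
    (outdir / "dropped_proteins.txt").write_text(
        "\n".join(result.dropped) + ("\n" if result.dropped else "")
    )
    result.coordinates.to_csv(outdir / "pca_coordinates.csv")
    render_map(result.coordinates, result.training_markers, result.assignments,
               outdir / "map.png")
    result.scores.to_csv(outdir / "scores.csv")
    result.assignments.to_csv(outdir / "assignments.csv", index=False)
    if result.truth is not None:
        result.truth.to_csv(outdir / "truth.csv", index=False)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(result.summary, fh, indent=2)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2)
    logger.info("pipeline outputs written to %s", outdir)
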