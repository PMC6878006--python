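"""Synthetic density-gradient co-fractionation data with known ground truth.

Emulates the structure of a 10-fraction × 2-replicate isobaric-tag
experiment on a cyanobacterial cell: each subcellular compartment is a
characteristic relative-abundance profile across the gradient (membranes
sediment deep, soluble material stays light, ribosomal subunits in
between), proteins of one compartment co-fractionate around that template,
and each protein is observed through several noisy PSM-level reporter
vectors per replicate.

Profiles are compositional (nonnegative, sum-to-one), so all sampling is
Dirichlet: a protein's per-replicate profile ~ Dirichlet(concentration ×
template), each PSM ~ Dirichlet(psm_noise_concentration × profile) scaled
by a log-normal total intensity. "Noise" proteins are drawn from a flat
low-concentration Dirichlet and model unclassifiable/mixed-location
profiles; a configurable fraction of non-marker proteins appears in one
replicate only, stressing the both-replicates merge rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .ingest import N_CHANNELS, REPORTER_COLS, REPLICATES
from .markers import CLASSES, MarkerSet

_PROFILE_FLOOR = 1e-12  # Dirichlet parameters must stay strictly positive


@dataclass(frozen=True)
class CompartmentTemplate:
    """Expected fractionation profile of one compartment.

    ``concentration`` is the Dirichlet concentration controlling
    within-class dispersion: larger values give tighter clusters.
    """

    name: str
    mean_profile: np.ndarray
    concentration: float

    def __post_init__(self) -> None:
        profile = np.asarray(self.mean_profile, dtype=float)
        object.__setattr__(self, "mean_profile", profile)
        if profile.shape != (N_CHANNELS,):
            raise ConfigurationError(
                f"template {self.name!r}: mean_profile must have length {N_CHANNELS}"
            )
        if np.any(profile < 0):
            raise ConfigurationError(f"template {self.name!r}: negative entries")
        if abs(profile.sum() - 1.0) > 1e-9:
            raise ConfigurationError(f"template {self.name!r}: profile must sum to 1")
        if not self.concentration > 0:
            raise ConfigurationError(f"template {self.name!r}: concentration must be > 0")


@dataclass(frozen=True)
class SimulationConfig:
    templates: Sequence[CompartmentTemplate]
    n_markers_per_class: int = 20
    n_unknowns_per_class: int = 100
    n_noise_proteins: int = 10
    frac_rep1_only: float = 0.05
    psm_per_protein: int = 4
    psm_noise_concentration: float = 200.0
    noise_concentration: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.templates) < 2:
            raise ConfigurationError("at least 2 compartment templates are required")
        names = [t.name for t in self.templates]
        if len(set(names)) != len(names):
            raise ConfigurationError(f"duplicate template names: {names}")
        if self.n_markers_per_class < 2:
            raise ConfigurationError(
                "n_markers_per_class must be >= 2 (classifier needs >=2 per class)"
            )
        for name in ("n_unknowns_per_class", "n_noise_proteins"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be nonnegative")
        if not 0 <= self.frac_rep1_only < 1:
            raise ConfigurationError("frac_rep1_only must lie in [0, 1)")
        if self.psm_per_protein < 1:
            raise ConfigurationError("psm_per_protein must be >= 1")
        if not self.psm_noise_concentration > 0:
            raise ConfigurationError("psm_noise_concentration must be > 0")


@dataclass(frozen=True)
class SimulatedDataset:
    """PSM table + marker set + per-protein ground truth."""

    psm_table: pd.DataFrame
    markers: MarkerSet
    truth: pd.DataFrame  # columns: protein_id, true_label, is_marker

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "psms": outdir / "psms.csv",
            "markers": outdir / "markers.csv",
            "truth": outdir / "truth.csv",
        }
        self.psm_table.to_csv(paths["psms"], index=False)
        self.markers.to_frame().to_csv(paths["markers"], index=False)
        self.truth.to_csv(paths["truth"], index=False)
        return paths


def default_templates(concentration: float = 60.0) -> list[CompartmentTemplate]:
    """Five compartment templates with distinct peak fractions.

    Peak positions follow the qualitative picture from gradient immunoblots:
    soluble material in the light fractions, ribosomal subunits at
    intermediate densities, plasma membrane deeper, thylakoid membrane in
    the heaviest fractions. Shapes are smooth bumps (discretized Gaussians,
    floored and renormalized) — real profiles are unimodal along the
    gradient with heavy overlap between neighbouring compartments.
    """
    peaks = {
        "soluble": 1.5,
        "small_ribosomal": 3.5,
        "large_ribosomal": 5.5,
        "PM": 7.2,
        "TM": 9.0,
    }
    width = 1.1
    templates = []
    channels = np.arange(1, N_CHANNELS + 1, dtype=float)
    for name in CLASSES:
        bump = np.exp(-0.5 * ((channels - peaks[name]) / width) ** 2) + 1e-3
        templates.append(
            CompartmentTemplate(name, bump / bump.sum(), concentration)
        )
    return templates


def _draw_profile(rng: np.random.Generator, template: np.ndarray, conc: float) -> np.ndarray:
    alpha = np.maximum(conc * template, _PROFILE_FLOOR)
    profile = rng.dirichlet(alpha)
    profile = np.maximum(profile, _PROFILE_FLOOR)
    return profile / profile.sum()


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate one full synthetic experiment (byte-reproducible per seed)."""
    rng = np.random.default_rng(config.seed)

    # Enumerate proteins with their generating template (None = flat noise).
    proteins: list[tuple[str, str, bool]] = []  # (id, true_label, is_marker)
    for t in config.templates:
        for i in range(config.n_markers_per_class):
            proteins.append((f"{t.name.lower()}_m{i:03d}", t.name, True))
        for i in range(config.n_unknowns_per_class):
            proteins.append((f"{t.name.lower()}_u{i:03d}", t.name, False))
    for i in range(config.n_noise_proteins):
        proteins.append((f"noise_{i:03d}", "noise", False))

    templates = {t.name: t for t in config.templates}
    flat = np.full(N_CHANNELS, 1.0 / N_CHANNELS)

    psm_rows: list[dict] = []
    truth_rows: list[dict] = []
    for pid, label, is_marker in proteins:
        # Whole-replicate dropout stresses the both-replicates rule; markers
        # are exempt so the training set always survives the merge.
        rep1_only = (
            not is_marker and rng.random() < config.frac_rep1_only
        )
        replicates = REPLICATES[:1] if rep1_only else REPLICATES
        if label == "noise":
            mean, conc = flat, config.noise_concentration
        else:
            t = templates[label]
            mean, conc = t.mean_profile, t.concentration
        for rep in replicates:
            profile = _draw_profile(rng, mean, conc)
            for _ in range(config.psm_per_protein):
                psm = rng.dirichlet(
                    np.maximum(config.psm_noise_concentration * profile, _PROFILE_FLOOR)
                )
                total = rng.lognormal(mean=np.log(1e5), sigma=0.5)
                row = {"protein_group_id": pid, "replicate": rep}
                row.update(dict(zip(REPORTER_COLS, psm * total)))
                psm_rows.append(row)
        truth_rows.append(
            {"protein_id": pid, "true_label": label, "is_marker": is_marker}
        )

    psm_table = pd.DataFrame(psm_rows, columns=["protein_group_id", "replicate", *REPORTER_COLS])
    truth = pd.DataFrame(truth_rows, columns=["protein_id", "true_label", "is_marker"])
    marker_entries = {pid: label for pid, label, is_m in proteins if is_m}
    class_names = tuple(t.name for t in config.templates)
    markers = MarkerSet(marker_entries, classes=class_names)
    return SimulatedDataset(psm_table, markers, truth)
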