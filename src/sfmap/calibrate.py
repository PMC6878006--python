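"""Per-compartment score thresholds and final assignments.

Two modes are supported. In FDR mode, each class receives the smallest
score cutoff at which the empirical false-discovery rate — the fraction of
annotated proteins predicted into that class, at or above the cutoff, whose
annotation disagrees — does not exceed a target (default 7.5%). In fixed
mode the user supplies per-class cutoffs directly (defaults 0.75 for the
membrane and ribosomal classes, 0.65 for the soluble class). Proteins whose
winning score falls below their class cutoff are reported "unclassified";
curated markers always keep their curated label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import CalibrationError
from .markers import CLASSES, MarkerSet

logger = logging.getLogger(__name__)

UNCLASSIFIED = "unclassified"
#: Sentinel cutoff that no score on [0, 1] can reach ("class assigns nothing").
UNATTAINABLE = 1.0 + 1e-6

DEFAULT_FIXED_CUTOFFS: dict[str, float] = {
    "TM": 0.75,
    "PM": 0.75,
    "soluble": 0.65,
    "small_ribosomal": 0.75,
    "large_ribosomal": 0.75,
}

DEFAULT_FDR_TARGET = 0.075


@dataclass(frozen=True)
class ThresholdSet:
    thresholds: Mapping[str, float]
    fdr_target: float | None
    method: str  # "fdr" or "fixed"

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "fdr_target": self.fdr_target,
            "thresholds": {k: float(v) for k, v in self.thresholds.items()},
        }

    @classmethod
    def fixed(cls, cutoffs: Mapping[str, float] | None = None) -> "ThresholdSet":
        return cls(dict(cutoffs or DEFAULT_FIXED_CUTOFFS), None, "fixed")


def calibrate_thresholds(
    scores: pd.DataFrame,
    annotation: Mapping[str, str],
    fdr_target: float = DEFAULT_FDR_TARGET,
    classes: tuple[str, ...] = CLASSES,
) -> ThresholdSet:
    """Choose per-class cutoffs meeting the target empirical FDR.

    ``scores`` is the output of :func:`sfmap.classify.score_all` (indexed by
    protein_id); ``annotation`` maps a held-out labeled subset of proteins to
    their known compartment (labels outside ``classes``, e.g. "noise", count
    as discordant for every class). Candidate cutoffs per class are the
    observed scores of annotated proteins predicted into that class, plus
    1.0; the smallest candidate whose selection has FDR <= fdr_target wins
    (an empty selection trivially satisfies the constraint). A class with no
    annotated predictions gets the unattainable sentinel and a warning.
    """
    if not 0 < fdr_target < 1:
        raise CalibrationError("fdr_target must lie in (0, 1)")
    annotated = {k: v for k, v in annotation.items() if k in scores.index}
    per_class_n = pd.Series(list(annotated.values())).value_counts() if annotated else pd.Series(dtype=int)
    for cls in classes:
        if per_class_n.get(cls, 0) < 2:
            logger.warning("class %s has < 2 annotated proteins with scores", cls)

    thresholds: dict[str, float] = {}
    for cls in classes:
        ids = [p for p in annotated if scores.at[p, "predicted_class"] == cls]
        if not ids:
            logger.warning("class %s: no annotated predictions; threshold unattainable", cls)
            thresholds[cls] = UNATTAINABLE
            continue
        s = np.array([scores.at[p, "score"] for p in ids], dtype=float)
        wrong = np.array([annotated[p] != cls for p in ids])
        candidates = np.append(np.unique(s), 1.0)
        chosen = None
        for t in candidates:  # ascending; first satisfying = smallest
            sel = s >= t
            n_sel = int(sel.sum())
            fdr = wrong[sel].sum() / n_sel if n_sel else 0.0
            if fdr <= fdr_target:
                chosen = float(t)
                break
        if chosen is None:
            logger.warning("class %s: no cutoff attains FDR <= %g", cls, fdr_target)
            chosen = UNATTAINABLE
        thresholds[cls] = chosen
    return ThresholdSet(thresholds, fdr_target, "fdr")


def assign(
    scores: pd.DataFrame,
    thresholds: ThresholdSet,
    markers: MarkerSet | None = None,
) -> pd.DataFrame:
    """Apply per-class cutoffs; below-cutoff proteins become "unclassified".

    Markers are forced to their curated label regardless of score, matching
    the convention that reported compartment counts include the markers
    themselves.
    """
    missing = set(scores["predicted_class"].unique()) - set(thresholds.thresholds)
    if missing:
        raise CalibrationError(f"no threshold for predicted class(es): {sorted(missing)}")
    out = scores[["predicted_class", "score"]].copy()
    out["threshold"] = out["predicted_class"].map(thresholds.thresholds).astype(float)
    out["final_label"] = np.where(
        out["score"] >= out["threshold"], out["predicted_class"], UNCLASSIFIED
    )
    marker_entries = markers.entries if markers is not None else {}
    out["is_marker"] = out.index.isin(marker_entries)
    if marker_entries:
        forced = out.index.intersection(list(marker_entries))
        out.loc[forced, "final_label"] = [marker_entries[p] for p in forced]
    out = out.reset_index().rename(columns={out.index.name or "index": "protein_id"})
    return out[["protein_id", "final_label", "predicted_class", "score", "threshold", "is_marker"]]


def summarize(assignments: pd.DataFrame, classes: tuple[str, ...] = CLASSES) -> dict:
    """Per-label counts (markers included) plus the total."""
    counts = {cls: 0 for cls in (*classes, UNCLASSIFIED)}
    if not assignments.empty:
        observed = assignments["final_label"].value_counts()
        for label, n in observed.items():
            counts[label] = int(n)
    return {"counts": counts, "total": int(len(assignments))}
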