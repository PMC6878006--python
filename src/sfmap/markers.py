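"""Curated marker sets defining the five subcellular training classes.

Markers are proteins of established residence — thylakoid membrane (TM),
plasma membrane (PM), soluble (cytosolic + thylakoid-lumen + periplasmic),
and the small and large ribosomal subunits — used as labeled training data
for the profile classifier. The "soluble" label deliberately aggregates the
finer soluble sub-compartments; an optional free-text ``subannotation``
column may record them but is ignored by the classifier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import MarkerError

logger = logging.getLogger(__name__)

#: Canonical class vocabulary, in fixed display order.
CLASSES: tuple[str, ...] = (
    "TM",
    "PM",
    "soluble",
    "small_ribosomal",
    "large_ribosomal",
)


def normalize_id(protein_id: str) -> str:
    """Normalize a protein identifier: trim whitespace, case-fold.

    CyanoBase locus tags (slr0488, sll1276, ...) are case-insensitive in
    practice; cross-database ID mapping is out of scope.
    """
    return str(protein_id).strip().casefold()


@dataclass(frozen=True)
class MarkerSet:
    """Mapping from protein ID to one of the training-class labels."""

    entries: Mapping[str, str]
    classes: tuple[str, ...] = CLASSES

    def __post_init__(self) -> None:
        bad = {c for c in self.entries.values() if c not in self.classes}
        if bad:
            raise MarkerError(f"unknown marker class label(s): {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self.entries

    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in self.classes}
        for label in self.entries.values():
            counts[label] += 1
        return counts

    def restrict(self, protein_ids: Iterable[str]) -> "MarkerSet":
        keep = set(protein_ids)
        return MarkerSet(
            {p: c for p, c in self.entries.items() if p in keep}, self.classes
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"protein_id": list(self.entries), "class": list(self.entries.values())}
        )


def load_markers(path: str | Path, classes: tuple[str, ...] = CLASSES) -> MarkerSet:
    """Read a marker table (CSV/TSV: protein_id, class[, subannotation]).

    Duplicate rows restating the same protein/class pair are tolerated
    (loading is idempotent and order-independent); a protein listed under
    two different classes is an error naming the protein, as are empty or
    out-of-vocabulary class labels.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    required = {"protein_id", "class"}
    if not required.issubset(df.columns):
        raise MarkerError(f"marker table must have columns {sorted(required)}")

    entries: dict[str, str] = {}
    for _, row in df.iterrows():
        pid = normalize_id(row["protein_id"])
        label = row["class"]
        if pd.isna(label) or str(label).strip() == "":
            raise MarkerError(f"empty class label for marker {pid!r}")
        label = str(label).strip()
        if label not in classes:
            raise MarkerError(f"unknown class {label!r} for marker {pid!r}")
        if pid in entries and entries[pid] != label:
            raise MarkerError(
                f"marker {pid!r} listed with conflicting classes "
                f"{entries[pid]!r} and {label!r}"
            )
        entries[pid] = label
    return MarkerSet(entries, classes)


def intersect_with_profiles(
    markers: MarkerSet, profile_ids: Iterable[str], min_per_class: int = 2
) -> tuple[MarkerSet, list[str]]:
    """Restrict markers to proteins with measured profiles.

    Returns the training subset and the sorted list of markers missing from
    the data. A class left with fewer than ``min_per_class`` represented
    markers makes training/calibration impossible and is a hard error.
    """
    available = {normalize_id(p) for p in profile_ids}
    training = markers.restrict(available)
    missing = sorted(set(markers.entries) - set(training.entries))
    counts = training.class_counts()
    too_small = {c: n for c, n in counts.items() if n < min_per_class}
    if too_small:
        raise MarkerError(
            "marker class(es) with fewer than "
            f"{min_per_class} profiled members: {too_small}"
        )
    if missing:
        logger.warning("%d marker protein(s) absent from profile data", len(missing))
    logger.info("training markers per class: %s", counts)
    return training, missing
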