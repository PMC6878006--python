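"""2-D PCA organelle map of the combined fractionation profiles.

Proteins that co-fractionate have similar 20-dimensional profiles and land
close together on the first two principal components; compartments appear
as clusters. Profiles are compositional on a common scale, so the map uses
mean-centering only by default (no unit-variance scaling).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .errors import PipelineError
from .ingest import profile_matrix
from .markers import CLASSES, MarkerSet

logger = logging.getLogger(__name__)

#: Stable class → color map (matplotlib named colors); unclassified is gray.
CLASS_COLORS = {
    "TM": "tab:green",
    "PM": "tab:brown",
    "soluble": "tab:blue",
    "small_ribosomal": "tab:orange",
    "large_ribosomal": "tab:purple",
}


@dataclass(frozen=True)
class MapCoordinates:
    coords: pd.DataFrame  # index protein_id; columns pc1, pc2
    explained_variance: tuple[float, float]

    def to_csv(self, path: str | Path) -> None:
        self.coords.to_csv(path)


def pca_project(profiles: pd.DataFrame, scale: bool = False) -> MapCoordinates:
    """Project combined profiles onto their top two principal components.

    Deterministic sign convention: each component is flipped so that its
    largest-magnitude loading is positive, making coordinates reproducible
    across runs and platforms.
    """
    X = profile_matrix(profiles)
    if X.shape[0] < 3:
        raise PipelineError("PCA map needs at least 3 proteins")
    if np.allclose(X.var(axis=0), 0.0):
        raise PipelineError("profiles are constant; PCA undefined")
    if scale:
        sd = X.std(axis=0, ddof=0)
        X = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    pca = PCA(n_components=2, svd_solver="full")
    scores = pca.fit_transform(X)
    for k in range(2):
        loading = pca.components_[k]
        if loading[np.argmax(np.abs(loading))] < 0:
            scores[:, k] *= -1.0
    coords = pd.DataFrame(scores, index=profiles.index.copy(), columns=["pc1", "pc2"])
    ev = tuple(float(v) for v in pca.explained_variance_ratio_[:2])
    logger.info("PCA map: explained variance %.1f%% / %.1f%%", 100 * ev[0], 100 * ev[1])
    return MapCoordinates(coords, ev)


def render_map(
    coordinates: MapCoordinates,
    markers: MarkerSet | None,
    assignments: pd.DataFrame | None,
    path: str | Path,
) -> Path:
    """Scatter the organelle map to PNG or SVG.

    Unclassified (or unassigned) proteins are gray circles; assigned
    proteins are colored by final label and markers are emphasized with a
    black edge.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = Path(path)
    if path.suffix.lower() not in {".png", ".svg"}:
        raise PipelineError(f"unsupported image format {path.suffix!r} (use .png/.svg)")
    if coordinates.coords.empty:
        raise PipelineError("cannot render an empty map")

    coords = coordinates.coords
    labels = pd.Series("unclassified", index=coords.index)
    if assignments is not None and not assignments.empty:
        final = assignments.set_index("protein_id")["final_label"]
        labels.loc[labels.index.intersection(final.index)] = final
    marker_ids = set(markers.entries) if markers is not None else set()

    fig, ax = plt.subplots(figsize=(7, 6))
    gray = labels == "unclassified"
    ax.scatter(
        coords.loc[gray, "pc1"], coords.loc[gray, "pc2"],
        s=12, c="lightgray", label="unclassified", zorder=1,
    )
    for cls in (markers.classes if markers is not None else CLASSES):
        sel = labels == cls
        if not sel.any():
            continue
        color = CLASS_COLORS.get(cls, "tab:red")
        is_marker = coords.index.isin(marker_ids) & sel
        plain = sel & ~is_marker
        ax.scatter(coords.loc[plain, "pc1"], coords.loc[plain, "pc2"],
                   s=14, c=color, label=cls, zorder=2)
        ax.scatter(coords.loc[is_marker, "pc1"], coords.loc[is_marker, "pc2"],
                   s=26, c=color, edgecolors="black", linewidths=0.6,
                   label=f"{cls} (marker)", zorder=3)
    ev = coordinates.explained_variance
    ax.set_xlabel(f"PC1 ({100 * ev[0]:.1f}% variance)")
    ax.set_ylabel(f"PC2 ({100 * ev[1]:.1f}% variance)")
    ax.legend(fontsize=7, loc="best")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
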