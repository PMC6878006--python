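#!/usr/bin/env python
"""PCA organelle map of the merged profiles.

Projects the 20-dimensional combined profiles onto their top two principal
components (centering only, deterministic sign convention) — proteins that
co-fractionate cluster together. Writes results/pca_coordinates.csv and a
marker-colored map image under scratch/figures/.
"""

import sys
from pathlib import Path

from sfmap import load_markers, pca_project, render_map
from sfmap.ingest import read_merged_profiles

if not Path("results/profiles.csv").exists():
    sys.exit("missing results/profiles.csv — run analysis/02_build_profiles.py first")

profiles = read_merged_profiles("results/profiles.csv")
markers = load_markers("results/synthetic/markers.csv")

coords = pca_project(profiles)
coords.to_csv("results/pca_coordinates.csv")
Path("scratch/figures").mkdir(parents=True, exist_ok=True)
marker_assign = markers.to_frame().rename(columns={"class": "final_label"})
render_map(coords, markers, marker_assign, "scratch/figures/map_markers.png")

ev1, ev2 = coords.explained_variance
print(f"PC1 explains {100*ev1:.1f}% of variance, PC2 {100*ev2:.1f}%")
print("wrote results/pca_coordinates.csv and scratch/figures/map_markers.png")
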