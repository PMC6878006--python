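#!/usr/bin/env python
"""Dataset-level comparisons on the reference run.

Two illustrations of the comparison machinery: (a) coverage overlap between
the protein lists quantified in each replicate (the same set arithmetic
used to compare two independent studies), and (b) concordance between
FDR-calibrated and fixed-cutoff assignment modes, as a label-by-label
contingency table.
"""

import json
import sys
from pathlib import Path

import pandas as pd

from sfmap import ThresholdSet, assign, concordance, load_markers, overlap
from sfmap.ingest import read_merged_profiles

for needed in ("results/synthetic/psms.csv", "results/scores.csv",
               "results/assignments.csv"):
    if not Path(needed).exists():
        sys.exit(f"missing {needed} — run earlier analysis scripts first")

psms = pd.read_csv("results/synthetic/psms.csv")
rep_lists = {
    rep: psms.loc[psms["replicate"] == rep, "protein_group_id"].unique()
    for rep in ("rep1", "rep2")
}
cov = overlap(rep_lists["rep1"], rep_lists["rep2"])
print(f"replicate coverage: {cov.n_both} proteins in both, "
      f"{cov.n_only_a} only in rep1, {cov.n_only_b} only in rep2")

scores = pd.read_csv("results/scores.csv", index_col="protein_id")
markers = load_markers("results/synthetic/markers.csv")
profiles = read_merged_profiles("results/profiles.csv")
training = markers.restrict(profiles.index)

fdr_assignments = pd.read_csv("results/assignments.csv")
fixed_assignments = assign(scores, ThresholdSet.fixed(), training)

conc = concordance(fdr_assignments, fixed_assignments)
print(f"FDR-mode vs fixed-cutoff assignments over {conc.n_shared} shared proteins:")
print(conc.table.to_string())

report = {"replicate_overlap": cov.to_dict(), "mode_concordance": conc.to_dict()}
json.dump(report, open("results/comparison_report.json", "w"), indent=2, default=int)
print("wrote results/comparison_report.json")
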