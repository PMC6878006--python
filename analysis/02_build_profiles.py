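#!/usr/bin/env python
"""Normalize PSMs and build merged both-replicate protein profiles.

Each spectrum becomes a ratio-to-sum composition, PSMs are aggregated to
per-protein channel-wise medians (renormalized), and only proteins
quantified in both replicates are kept. Reads results/synthetic/psms.csv
(run 01_simulate.py first); writes results/profiles.csv.
"""

import sys
from pathlib import Path

from sfmap import build_profiles, read_psm_table
from sfmap.ingest import write_profile_table

psm_path = Path("results/synthetic/psms.csv")
if not psm_path.exists():
    sys.exit("missing results/synthetic/psms.csv — run analysis/01_simulate.py first")

psms = read_psm_table(psm_path)
profiles, dropped = build_profiles(psms)
write_profile_table(profiles, "results/profiles.csv")

print(f"{profiles.shape[0]} proteins quantified in both replicates "
      f"({len(dropped)} dropped as single-replicate)")
print("each profile: 20 values (rep1 block + rep2 block), blocks sum to 1")
print("wrote results/profiles.csv")
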