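# sfmap — subcellular fraction mapping from gradient co-fractionation

`sfmap` assigns proteins to subcellular compartments from their quantitative
behaviour across a density gradient (LOPIT-style spatial proteomics). It was
built around the design of a whole-cell cyanobacterial mapping experiment:
a sucrose gradient is cut into 10 fractions, each fraction is labeled with
one channel of an isobaric 10-plex tag, and every identified spectrum
carries a 10-channel reporter vector describing where along the gradient
that protein sits. Proteins that live in the same compartment co-fractionate,
so their profiles cluster — and a classifier trained on proteins of known
residence can place the rest.

The pipeline:

1. **Ingest** — each PSM reporter vector is normalized to its sum
   (`x_i / Σx`), per-protein profiles are channel-wise medians of the
   normalized PSMs (renormalized), and only proteins quantified in **both**
   biological replicates are kept, giving one 20-dimensional profile per
   protein (rep1 ∥ rep2).
2. **Markers** — a curated table maps proteins of established residence to
   one of five classes: thylakoid membrane (TM), plasma membrane (PM),
   soluble, small ribosomal subunit, large ribosomal subunit.
3. **Map** — PCA (centering only) of the combined profiles for
   visualization.
4. **Classify** — an RBF-kernel SVM with class weights
   `w_c ∝ 1/n_c` (mean-normalized) is tuned by repeated stratified 80/20
   rounds with inner k-fold grid search over (C, γ), then refit on all
   markers. Every protein receives per-class Platt probabilities; the
   winning probability is its confidence score on [0, 1].
5. **Calibrate & assign** — per class, the smallest score cutoff whose
   empirical false-discovery rate on a held-out annotated set stays ≤ a
   target (default 7.5%) — or fixed cutoffs (0.75 for the membrane and
   ribosomal classes, 0.65 for soluble). Below-cutoff proteins are
   "unclassified"; markers keep their curated label.
6. **Compare** — set overlap between protein lists and label-by-label
   concordance between assignment tables.

A Dirichlet-based generator simulates complete experiments (compartment
templates → protein profiles → PSM-level replicates, with whole-replicate
dropout and flat-profile "noise" proteins) so the entire pipeline is
testable with known ground truth and no downloads.

## Worked example

```sh
python analysis/01_simulate.py
python analysis/02_build_profiles.py
python analysis/03_map_pca.py
python analysis/04_classify_assign.py
python analysis/05_compare.py
```

On the reference run (seed 7: 5 classes, 20 markers + 100 unknowns each,
10 noise proteins) this prints:

```
simulated 610 proteins (100 markers, 10 noise)
578 proteins quantified in both replicates (32 dropped as single-replicate)
PC1 explains 44.5% of variance, PC2 28.6%
chosen C=0.25, gamma=1.0; held-out marker macro-F1 = 1.000
per-class thresholds: {'TM': 0.245, 'PM': 0.266, 'soluble': 0.276,
                       'small_ribosomal': 0.304, 'large_ribosomal': 0.359}
assignment counts: {'TM': 116, 'PM': 113, 'soluble': 116,
                    'small_ribosomal': 115, 'large_ribosomal': 118,
                    'unclassified': 0}
measured FDR among assigned non-markers: 2.09% (target 7.5%)
```

Reading this: all 100 held-out marker evaluations classified perfectly
(macro-F1 1.0), the calibrated cutoffs are low because the annotated
hold-out set shows almost no discordance, and the realized error among
assigned non-marker proteins (2.1%) is well inside the 7.5% target.

The same pipeline runs from a single config file:

```sh
sfm simulate --seed 7 --outdir results/synthetic     # standalone generator
sfm run config.yaml                                  # full pipeline
sfm compare results/assignments.csv other.csv        # overlap + concordance
sfm render results/pca_coordinates.csv --assignments results/assignments.csv --out map.png
```

with `config.yaml` like:

```yaml
simulation: {}            # or: inputs: {psm_table: psms.csv} plus markers: markers.csv
calibration: {mode: fdr, fdr_target: 0.075}
seed: 7
output_dir: results/run
```

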