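# Methods

## The model

A protein's subcellular residence is inferred from its co-fractionation
behaviour: after density-gradient separation of a lysed cell, material from
one compartment concentrates in a characteristic band of fractions, and
every resident protein inherits that distribution. With 10 gradient
fractions labeled by a 10-plex isobaric tag, each peptide-spectrum match
(PSM) yields a 10-channel reporter vector proportional to the protein's
abundance per fraction. The analysis treats these vectors as compositions:
only the *relative* distribution along the gradient is informative, so each
spectrum is divided by its reporter sum.

Per protein and replicate, the profile is the channel-wise median of its
normalized PSMs. Medians of sum-to-one vectors need not sum to one, so the
median vector is renormalized (a config switch, on by default; turning it
off leaves profiles on a near-compositional scale and mainly affects
distance-based steps). Two biological replicates are required: proteins
seen in only one are dropped (logged), and surviving proteins carry a
20-dimensional combined profile (replicate blocks concatenated). The two
replicate profiles of one protein are treated as independent draws around
the same compartment signature; no cross-replicate normalization is
applied.

## Classification

Five training classes: thylakoid membrane (TM), plasma membrane (PM),
soluble (aggregating cytosolic, thylakoid-lumen and periplasmic proteins),
small and large ribosomal subunits. Marker proteins of known residence are
the only labeled data; a class with fewer than two profiled markers aborts
the run, since neither stratified tuning nor calibration is possible.

The classifier is an RBF-kernel SVM with per-class weights inversely
proportional to class frequency, normalized to mean 1 — so error on a
10-member ribosomal class costs as much as error on a 400-member soluble
class. Hyperparameters (C, γ) come from a log₂ grid (default 2⁻⁴…2⁴ each;
desk-scale runs use a reduced 4×3 grid) searched by repeated stratified
partitioning: each of `cv_outer_rounds` (default 100) rounds splits the
markers 80/20, scores every grid pair by `cv_inner_folds`-fold (default 5)
macro-F1 inside the 80% block, and evaluates the round's inner winner on
the 20% hold-out. The reported CV macro-F1 is the mean of those hold-out
scores (a nested, approximately unbiased estimate); the final pair
maximizes mean inner macro-F1 across rounds, with ties broken toward
smaller C, then smaller γ (smoother models). The model is refit on all
markers with the chosen pair.

Confidence scores are pairwise-coupled Platt probabilities from the SVM.
The predicted class is defined as the argmax of the per-class
probabilities (not the raw SVM vote, which can disagree with the coupled
probabilities in rare ties), so `score = max(per-class scores)` holds
exactly and scores live on [0, 1].

## Threshold calibration

Per class c, candidate cutoffs are the observed scores of annotated
proteins predicted into c, plus 1.0. The calibrated threshold is the
smallest candidate t such that, among annotated predicted-c proteins with
score ≥ t, the fraction whose annotation differs from c is ≤ the FDR
target (default 7.5%). An empty selection counts as satisfying the
constraint (no discoveries, no false ones); a class with no annotated
predictions gets an unattainable sentinel (1 + 10⁻⁶) and assigns nothing.
Because the satisfying set only shrinks as the target tightens, thresholds
are monotone in the target; this and exact agreement with exhaustive
search are enforced by tests.

The annotation must be held out from training: reusing training markers
would underestimate FDR, since the classifier fits them. In simulated runs
the pipeline samples a seeded fraction (default 50%) of non-marker
proteins and annotates them with ground truth — noise proteins carry the
label "noise", which counts as discordant for every class, exercising the
false-discovery side. Real-data runs must supply an annotation table
explicitly.

Fixed-cutoff mode bypasses calibration with per-class cutoffs (defaults
0.75 for TM/PM/ribosomal, 0.65 for soluble). Proteins scoring below their
class cutoff are "unclassified"; markers always keep their curated label,
so summary counts include the markers themselves.

## Synthetic data generator

Everything is Dirichlet because profiles are compositional:

- each compartment template is a smooth discretized bump over the 10
  channels with a distinct peak fraction (soluble lightest → TM heaviest),
  floored at 10⁻³ and renormalized;
- protein profile per replicate ~ Dirichlet(concentration × template);
  template concentration defaults to 60, chosen a priori to give realistic
  within-class spread — held-out marker recall in the 0.9–1.0 range —
  rather than trivially separable clusters;
- PSM reporter vector ~ Dirichlet(psm_concentration × profile), default
  200, scaled by a log-normal total intensity (median 10⁵, σ = 0.5 in log
  space) to mimic spectrum-to-spectrum intensity variation;
- "noise" proteins ~ symmetric Dirichlet (flat template, total
  concentration 10): diffuse profiles resembling no compartment, modelling
  unclassifiable or mixed-location behaviour;
- a fraction (default 5%) of non-marker proteins appears in replicate 1
  only. Markers are exempt so the training set always survives the
  both-replicates rule; subjecting markers to dropout would only shrink
  the training set, which the marker-validation stage already guards.

Defaults mirror the reference design: 5 classes × (20 markers + 100
unknowns) + 10 noise proteins, 4 PSMs per protein per replicate. All
randomness flows from one integer seed through `numpy`'s Generator, making
output byte-identical across runs.

What the generator does **not** emulate: chromatographic tailing or
channel bleed (isotopic impurity of tags), missing individual channels,
peptide-level effects (shared peptides, protein inference), between-class
profile correlation beyond template overlap, and multi-localized proteins
with genuinely bimodal profiles. Passing tests therefore demonstrate the
statistical machinery is correct under the intended data model, not that
real-instrument artifacts are handled.

## Numerical choices

- Compositional invariants are asserted at 10⁻⁹; write/read round-trips at
  10⁻¹²  (tables are written at full float precision).
- Dirichlet parameters are floored at 10⁻¹² to keep them strictly
  positive when templates or sampled profiles underflow.
- PCA uses the full SVD solver; each component is sign-fixed so its
  largest-magnitude loading is positive, making coordinates deterministic
  across platforms. Centering only, by default: profiles already share a
  common scale, and variance scaling would inflate noisy low-abundance
  channels (switchable).
- Grid-search ties are resolved deterministically (smallest C, then γ);
  inner fold counts shrink to the smallest class size when a class is
  smaller than the requested fold count.
- In the zero-noise limit, all within-class scores coincide up to ~10⁻⁸
  float noise, so a data-derived threshold would sit exactly on a tie;
  degenerate-limit checks use fixed-cutoff mode.

## Desk-scale problem sizes

The reference analyses and tests run the full design (610 proteins, ~4,800
PSM rows) with the reduced 4×3 hyperparameter grid and 100 tuning rounds —
about 20 s on one CPU; the zero-noise and calibration cross-checks are
smaller still. These sizes are the package's chosen reference conditions;
everything scales to larger tables through the same interfaces.

## Known limitations

- Exactly two replicates; the both-replicates rule is not configurable to
  other designs.
- No multi-localization modelling: a genuinely dual-resident protein will
  either land in one class or fall below threshold.
- FDR control is per class and empirical; with few annotated proteins in a
  class the threshold estimate is coarse (a warning is logged below 2).
- The "soluble" class is a deliberate aggregate; finer soluble
  sub-compartments are out of scope.
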