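# Methods

This note records the models implemented in `immunorad`, the design
choices that were genuinely open, the numerical conventions, and what
the synthetic-data experiments do and do not demonstrate.

## Enrichment scoring

Enrichment of a metagene set in one sample uses the weighted
running-sum statistic over that sample's expression ranking
(descending; ties broken by gene id for determinism). `P_hit`
accumulates |x|^w over set members, normalized by the members' total
weight; `P_miss` accumulates 1/(N − N_hit) over non-members; the score
is the running difference at its maximum magnitude, signed. The weight
exponent defaults to w = 1 (the classic weighted statistic); w = 0 is
used in analytic tests because it bounds ES in [−1, 1] and makes the
statistic scale-free. A set containing every ranked gene is degenerate
and scores +1 by convention. When the most positive and most negative
running-sum extremes tie exactly in magnitude, the reported sign is
decided by floating-point rounding; the test suite compares magnitudes
in that measure-zero case.

Normalization to NES divides ES by the mean |ES| of size-matched
random gene sets drawn from the same ranking (default 1000
permutations, seeded; 200 in the pipeline runs — see problem sizes).
Scoring is per sample, so a gene-set permutation null is the natural
choice; a phenotype-label permutation null is not defined for a single
sample. Levels are binarized per subset at the cohort median (strictly
above → high, ties → low); no threshold is reported in the source
analyses, and the median split is the only choice that guarantees both
classes for downstream classification. Immunogram scores are a
per-subset min–max rescaling of NES onto [0, 5]; a zero NES range maps
everything to 2.5 with a warning.

## Immunophenotype groups

The five groups are defined on the (CTL, aDC, Treg, MDSC) level
quadruple by priority rules: all-low → G1; all-high → G5; CTL-high ∧
Treg-low ∧ MDSC-low → G3 (aDC unconstrained); CTL-low ∧ MDSC-high →
G2; residual → G4. The ordering makes the mapping total over all 16
combinations; the verbal definition of G4 ("CTL high, others mixed")
overlaps other rules, so G4 is implemented as the residual class and
every label records which rule fired.

Cohort grouping clusters the 4-dimensional NES vectors with Ward
linkage on Euclidean distances and cuts the tree at K = 5
(deterministic; a seeded k-means alternative is available). Clusters
are labelled by their majority level pattern through the same rule
table (per-subset majority, ties to low). With the default group mix
the rarest group (G3, 6.5%) does not always emerge as its own cluster
at n = 100; this is a property of the clustering step, not of the rule
table.

## Radiomics

Volumes are resampled by trilinear interpolation (nearest-neighbour
for masks) to 0.75 × 0.75 × 3.0 mm. Intensity normalization z-scores
against a reference region, clips at ±3 SD and maps onto [0, 1]; the
pipeline uses the whole field of view as the reference so that the
ROI's level *relative to its surround* survives normalization (a
tumor-ROI reference would erase exactly the between-patient intensity
differences the models need). The operation is exactly idempotent when
no voxel reaches the clip.

The wavelet stage is a single-level 3D separable DWT (PyWavelets),
default Haar — orthonormal, so Parseval's identity holds and the
transform is testable against hand computations; the family is
configurable. Sub-bands are labelled LLL…HHH with one L/H letter per
axis in (x, y, z) order. Band-level ROI masks are the decimated
(every-second-voxel) masks.

Gray levels are quantized to 32 equal-width bins within the ROI.
Run-length and co-occurrence matrices are computed per direction over
the 13 unique directions of the 3D 26-neighbourhood, and features are
averaged over directions (averaging feature values, not merging
matrices — the two differ and the choice is stated for that reason).
Runs break at ROI boundaries and gray-level changes; co-occurrence
uses distance 1, symmetric and normalized per direction. IMC1 uses
entropies in bits and returns 0 with a warning when max(HX, HY) = 0.
Shape features use voxel-count volume, exposed-face surface area, and
sphericity π^{1/3}(6V)^{2/3}/A.

Feature names follow `<band>_<transform>_<feature>` with band `none`
for the undecomposed volume. The `transform` slot is a named
pre-transform hook (default identity, named `none`); a SIFT-style
intensity transform can be registered under its own name without
changing the naming scheme, but no particular definition is assumed.

## Feature filter

Stage 1 removes a feature iff its missing-or-zero fraction strictly
exceeds 0.90. Stage 2 computes Spearman correlations between each
feature and each metagene-catalog gene present on both expression
platforms, per platform, over the shared samples; under the default
`per_set_median` strategy a feature survives iff for at least one gene
set the per-gene median correlation has the same sign on both
platforms with magnitude ≥ 0.2 on both (strategies `per_gene_all` and
`overall` are available; the consistency principle does not pin down
the statistic, so it is exposed as an option). Stage 3, per subset,
requires random-forest mean-decrease-in-Gini importance > 0 (500
trees, √p features per split, seeded) and information gain > 0 and ≥
the cutoff — the mean of the positive gains, falling back to the
median if the mean admits none — with survivors ranked by descending
gain. Information gain is H(Y) − H(Y|X) in bits with X discretized
into 10 equal-width bins. Every stage writes a kept/removed ledger
with one reason per feature.

## Models

One binary logistic model per subset, selected features as predictors,
level (0 low / 1 high) as response. Features are standardized
internally and the fit carries an L2 ridge with weight 1.0 on the
standardized scale (sklearn `C = 1`), solved by Newton iterations;
coefficients are mapped back to raw scale. The ridge default was
chosen after a direct comparison: with the ~35–50 collinear selected
features, a vanishing ridge (ε = 1e-6) produces a separating,
max-margin-like fit whose boundary is pinned by the ~10% of
median-split training labels that disagree with the underlying state —
measured hold-out subset accuracy 0.83–0.90 and predicted-group
accuracy 0.60 — whereas the unit ridge reaches 0.91–0.98 and 0.87 on
the same data. ε-scale ridge remains available via the `ridge`
parameter. Evaluation is leave-one-out: n refits, held-out accuracy,
and rank-based (Mann–Whitney) AUC; single-class folds are skipped with
a warning and reported.

Per-feature significance is a likelihood-ratio χ² (full model vs
dropped-feature refit, 1 df). Because "explanatory power" has no
single definition, two quantities are reported side by side: the LR
χ²/p per feature, and an importance ratio — the feature's
|standardized coefficient| share of the model total, summing to 1.

Prediction thresholds each subset probability at 0.5; the binary
quadruple maps through the rule table to a predicted group
(`source = rule_mapped`). Samples with missing features are skipped
with a logged reason.

## Survival

Kaplan–Meier estimation and log-rank tests are delegated to lifelines
behind a typed surface; the test suite checks both against an
independent risk-set-table implementation. The median is the smallest
observed time with S(t) ≤ 0.5, undefined (NaN) when the curve never
reaches 0.5. Ties share a risk set (the standard convention). The
prognosis population is restricted to IDH wild-type patients.

## Synthetic cohorts

The generator plants a known truth at every level so each stage has a
recoverable target.

* **Groups** are drawn with the observed-cohort proportions
  (0.377, 0.162, 0.065, 0.130, 0.266 for G1…G5) and each group fixes a
  canonical state quadruple consistent with the rule table; G4 is
  (CTL high, Treg high, others low).
* **Expression**: per-gene log-normal baselines (log2-means uniform in
  [3, 8], biological SD 0.5 shared across platforms); a "high" state
  adds `effect_size` (default 2.0) to the log-mean of that set's genes
  on both platforms; platform-specific Gaussian noise (SD 0.3) and a
  per-sample microarray offset are added on top. Metagene sets have
  5/51/26/58 genes plus 200 background genes.
* **Images**: an ellipsoidal ROI (random radii, 30–42% of each axis)
  over a Gaussian background. Four monotone knobs, one per subset:
  CTL raises the ROI mean (+0.8); MDSC coarsens the blockwise-constant
  texture field (block 2→4 voxels in-plane), lengthening gray-level
  runs; aDC raises the block-field amplitude (0.35→0.70), i.e. ROI
  contrast; Treg adds an exponential bright tail (amplitude 0.45),
  i.e. ROI skewness. The CTL/MDSC directions mirror the reported
  image–immune associations; the aDC/Treg knobs exist so all four
  subset models are learnable, without claiming biological realism.
  ADC volumes carry the same latent structure on an inverted, noisier
  intensity scale. Amplitudes were fixed once to give clearly
  supra-noise signals.
* **Survival**: exponential with the configured group medians
  (408/266/867/330/357 days); independent uniform censoring whose
  window is solved per group so the expected censored fraction equals
  the configured rate (default 20%). Independence matters: censoring
  at a fraction of the subject's own death time biases Kaplan–Meier
  medians upward by ~10–20% and was rejected for that reason.
* One RNG stream per cohort, seeded from the config; identical seeds
  give bit-identical cohorts.

What the generator does *not* emulate: MR physics, tumor-shape
realism, scanner/site effects, probe-level microarray artifacts,
non-exponential hazards, or informative censoring. Passing tests
therefore demonstrate the pipeline's correctness and its statistical
behaviour under a controlled signal model — not clinical performance
on real cohorts.

## Problem sizes

Pipeline runs default to 200 NES permutations (the statistic is stable
well below the 1000-permutation default of the standalone function)
and 24 × 24 × 12 volumes at 0.75 × 0.75 × 3.0 mm. Recovery experiments
use n = 100 cohorts at effect size 2. The predicted-group prognosis
experiment trains on an n = 200 default-mix cohort and evaluates 20–40
independent n = 250 inference cohorts whose group mix follows the
independent-testing composition (19/16/17/23/6 over 81 classified
patients), where the G2 and G3 arms are each ~20% of the cohort; with
the clustering-cohort mix the G3 arm (6.5%) leaves the pairwise
log-rank test under-powered at these sizes regardless of model
quality.

## Known limitations

* `normalize_array` (single-pass LOWESS against a median reference) is
  exactly idempotent only when sample deviations are smooth in mean
  intensity — the regime it is designed for; with non-smooth
  deviations the reference moves and a second pass shifts values.
  Iterating to a fixed point was rejected: it collapses all samples
  onto the reference.
* Median-split binarization forces a 50% high rate per subset even
  when the planted rate differs, so a few boundary samples are
  inherently mislabelled; this bounds the achievable agreement between
  enrichment levels and planted states.
* The rarest group may not separate as its own Ward cluster in small
  cohorts; labels remain well-defined through the rule table.
* Probe-to-gene mapping, batch correction, registration and
  skull-stripping are out of scope; images must be pre-aligned.
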