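# Methods

`leukoflow` re-creates, end to end, a label-free white-blood-cell (WBC)
classification workflow for imaging flow cytometry: per-cell brightfield
(BF) and darkfield (DF, side scatter) images are quality-gated, packed into
montages, reduced to a fixed 213-feature-per-channel morphological battery,
and classified in two stages (four WBC main types, then B vs T within
lymphocytes) under a subject-wise evaluation protocol. Because the original
instrument data cannot be bundled, the package ships a synthetic cohort
generator whose statistical structure matches what the pipeline assumes;
every stage is exercised and tested against it.

## Synthetic image formation

A cell is a logistic-edged disk (radius drawn per cell from a class
Normal(μ_r, σ_r), donor-scaled) on a dim background. The brightfield
channel adds a concentric darker nucleus covering a class-specific fraction
of the cell area and multiplicative spatially-smoothed texture noise. The
darkfield channel is a flat background at the class's base scatter level
plus bright Gaussian granules placed uniformly inside the cell by a Poisson
process with a class-specific density (granules per 100 px²). Defaults: 64 × 64
px tiles, BF background 0.02, nucleus contrast 0.45; all parameters are
config-exposed through `CellPhenotypeSpec`.

Class presets encode the qualitative contrasts the classifier exploits:
eosinophils and neutrophils carry dense DF granularity (eosinophils with
larger, brighter granules), monocytes are the largest cells with sparse
granules, lymphocytes are small with a high nucleus fraction. The B/T
contrast is deliberately subtle — small shifts in nucleus fraction
(0.78 vs 0.83), edge sharpness (4.25 vs 4.5) and granule density (0.30 vs
0.22/100 px²) — and per-cell jitter with SDs comparable to those gaps
(e.g. nucleus fraction SD 0.05) gives the two subtypes genuinely
overlapping distributions. This makes the second classification stage
measurably harder than the first, the ordering the two-stage protocol is
meant to expose, without targeting any particular score.

Donor-level batch effects are sampled per donor: log-normal illumination
gain per channel (default log-SD 0.10; `STRONG_BATCH_EFFECTS` uses 0.50),
uniform residual defocus (default max 0.35 px; strong 0.6), and a
log-normal size scale (default log-SD 0.04; strong 0.18, clipped to
[2/3, 4/3] so the largest phenotype still fits the tile). Class
proportions are drawn uniformly inside the clinical reference intervals —
lymphocytes 20–40 %, eosinophils 1–6 %, monocytes 2–10 %, neutrophils
40–80 % — renormalized to sum to one, with lymphocytes split 25 % B / 75 % T.

Reproducibility: one master seed; each donor's stream is seeded by
CRC32(`seed|donor_id`) (kept below 2³¹), so a donor's cells are bit-identical
regardless of cohort composition or generation order.

What the generator does **not** emulate: real cytology (lobed nuclei,
cytoplasmic texture families, optical point-spread functions), fluorescence
channels (ground truth is assigned directly, standing in for antibody
gating), basophils (the workflow's label space is the four stained classes
plus the B/T split), and instrument containers (ingestion starts at
montages/tiles). Passing tests therefore demonstrate that the *pipeline
machinery* — gating, measurement, protocol, accounting — behaves correctly
on data with the right feature-level contrasts; they say nothing about
classification accuracy on real instruments.

## Gating

Focus is scored as `100 · RMS(∇(I / mean(I)))` with central-difference
gradients. Normalizing by the mean intensity (rather than to the [0, 1]
range) keeps the score invariant under global illumination changes while
placing sharp synthetic cells at ≈ 60–110 units and σ ≥ 3 blur below 40, so
the conventional threshold of 55 "arbitrary units" separates them with
margin; any instrument/generator change requires re-calibrating this
threshold, which is why it is a config field. Segmentation is Otsu on the
smoothed BF image, holes filled, largest connected component. Gates apply
in order: focus → debris (area < `area_min`, default 30 px² ≈ 0.2 × the
smallest expected cell) → doublet (area > `area_max`, default 1250 px²
≈ 2.5 × the largest, or second-moment aspect ratio < 0.6). Counts always
partition the input.

## Feature battery

Per channel: 50 shape (20 scalar descriptors + 30 Zernike magnitudes,
degrees 0–9, m ≥ 0, n − m even, on the mask scaled to its enclosing unit
disk and normalized by pixel count), 15 intensity (within-mask moments,
quartiles, MAD; 1-px edge statistics; mass displacement), 104 texture
(13 co-occurrence statistics × scales {3, 8} px × angles {0°, 45°, 90°,
135°}; 8 gray levels by equal-width binning of the within-mask range;
co-occurrence restricted to pixel pairs fully inside the mask,
symmetrized; log₂ entropies), 32 granularity (16-element spectra at
structuring-element radii {1, 2}) and 12 radial distribution (FracAtD,
MeanFrac, RadialCV over 4 rings of equal normalized-distance width with
8 angular wedges) — 213 features per channel, 426 per cell, asserted
against the manifest at build time. One mask, segmented from BF, serves
both channels; shape features are mask-only and thus repeat across the
two channel blocks, which keeps each 213-column block self-contained.

Granularity uses an erosion–reconstruction sieve: after background
subtraction (mask-exterior median) the image is repeatedly eroded with a
disk and reconstructed under the original; element k is the percentage of
initial within-mask intensity removed at step k. Erosion sequences are
monotone and reconstruction order-preserving, so spectra are non-negative
and sum to at most 100 by construction.

Degenerate conventions: co-occurrence matrices with a single cell (or no
valid pair at the offset) report energy 1, contrast 0, entropies 0 and
correlation-type measures 0; rings with zero mean wedge intensity report
RadialCV 0; zero-signal cells report an all-zero granularity spectrum. Any
non-finite feature value raises — it is a measurement bug, never a
sentinel.

## Evaluation protocol

Subject-wise cross-validation: one fold per donor, the model refit per
fold, and *all* preprocessing — class balancing and feature
standardization — fit on the training donors only. Random undersampling
draws every class down to the minority count without replacement, inside
each fold's training portion. Classifier selection repeats the whole CV
for 10 undersampling seeds across five classifiers (AdaBoost,
gradient-boosted trees, k-nearest neighbors, random forest, RBF SVM; KNN
and SVM wrapped in per-fold standardization) and majority-votes the
per-run winners; ties break by mean F1 across runs, then lexicographically.
The score is macro F1 (per-class F1 averaged over the classes present in
the truth, zero-division → 0), averaged over folds; a `weighted` switch is
available. Folds whose training set lacks a class are flagged and excluded
from the mean with a warning.

Gradient boosting is backed by XGBoost with default settings. At this
protocol's scale (hundreds of balanced training rows × 426 features,
650 cross-validation fits) it trains the same model family one to two
orders of magnitude faster than the scikit-learn gradient-boosting
estimators while exposing the per-feature importances the
importance-union report requires; no hyperparameters are tuned anywhere
(library defaults throughout).

Two-stage classification trains a four-class model on all cells and a
binary B/T model on ground-truth lymphocytes only. At prediction time the
B/T model is applied under two conventions, both reported: to cells the
stage-1 model calls lymphocytes (deployment) and to cells whose ground
truth says lymphocyte (evaluation, matching the restriction of training
and evaluation to labeled lymphocytes).

Shuffle-and-split — a row-level split ignoring donor identity — is
implemented solely as the negative control: with donor batch effects
present it overstates performance because cells of each donor appear on
both sides of the split.

Feature importances: per undersampling run, a gradient-boosting model is
fit on a balanced copy of the full table; the top-10 features per run are
pooled, and the union is sorted by the number of runs in which a feature
appears (ties by mean rank).

## Differential counts

Per donor, class percentages over classified cells (always summing to
100); the cohort average is the unweighted mean over donors, compared per
class against closed reference intervals. Donors with no classified cells
are excluded with a warning. Basophils are absent from the label space, so
reported percentages are of the four modelled classes.

## Problem sizes and numerical choices

The reference protocol run used by the tests and the acceptance script is
13 donors × 500 cells (the cohort geometry the evaluation protocol is
designed around); the shuffle-vs-subject comparison uses smaller replicate
cohorts (5 donors × 150 cells in tests, 4 × 120 in the acceptance script)
because the effect is a mean over replicates, not a per-cohort quantity.
Montage tests use 2000 synthetic tiles. Zernike tolerances in tests allow
for rasterization error (≤ 0.05 on high-degree moments of a radius-10
disk); RadialCV of a uniform disk is only approximately zero because the
innermost ring holds few pixels.

## Known limitations

* The image model is a caricature; absolute feature values carry no
  biological meaning, only the engineered orderings do.
* The 213-feature decomposition (50 + 15 + 104 + 32 + 12) is this
  package's fixed choice consistent with the printed category structure
  and every feature name the workflow's importance tables use; other
  decompositions of the same total are possible.
* The gradient-RMS "arbitrary units" are a package convention; thresholds
  do not transfer between instruments or generators without recalibration.
* Stage-2 deployment accuracy depends on stage-1's lymphocyte gate; only
  the truth-gated convention isolates the B/T model itself.
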