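# Methods

This note documents the models, conventions and parameter choices behind
`prostacad`: what the synthetic phantoms emulate, how each pipeline stage is
defined, where the design was genuinely open and what was decided, and what
passing the test suite does and does not demonstrate about clinical data.

## Conventions

All volumes are indexed `[x, y, z]` with 0-based voxel indices; spacing is
millimetres per voxel. Boxes (regions, windows) are half-open integer
intervals `[lo, hi)` per axis. The malignant class is always the positive
class; lesion labels follow the clinical convention that only lesions above
Gleason 3+3=6 are "significant" (label 1), so a case is malignant iff it
carries at least one malignant lesion.

## Synthetic phantom cohorts

No clinical cohort ships with the package, so a generator produces study
cases that preserve the *structure* of the problem:

- **Geometry.** The prostate gland is an axis-aligned ellipsoid (default
  semi-axes `(1.0, 0.9, 0.65) × gland_radius_mm`, default radius 20 mm,
  centre jittered ±2 mm per case). The peripheral zone (PZ) is the
  posterior shell of the gland — the outer `pz_shell_fraction` (default
  0.35) of the normalized ellipsoid radius on the posterior (+y) side,
  which appears as a crescent in transverse slices. Lesions are spheres
  (default radius 4–8 mm) rejection-sampled to lie fully inside the gland;
  70% of placement attempts target the PZ, matching the clinical prior that
  roughly 70% of prostate lesions arise there.
- **Texture.** Tissue intensity is a stationary Gaussian random field:
  white noise smoothed with a Gaussian kernel of class-specific correlation
  length, rescaled to a class-specific mean and SD, plus i.i.d. acquisition
  noise (SD 0.05). Defaults (arbitrary normalized units): gland background
  mean 1.0 / SD 0.10 / correlation length 1.5 mm; benign lesions mean
  0.90–1.10 depending on sequence, SD 0.10, 2 mm; malignant lesions SD
  0.18, 4 mm, with means 0.60 (T2W), 0.50 (ADC, hypointense) and 1.60
  (DWI, hyperintense). Malignant-vs-background mean contrast on ADC is 10
  acquisition-noise SDs: the default cohort is *strongly* separable by
  design, because the generator's job is to verify signal recovery, not to
  imitate clinical difficulty. Both first-order (mean) and second-order
  (variance, correlation length) statistics differ between classes so that
  co-occurrence, LBP and gradient features all carry real signal.
- **Composition.** Cohorts default to a benign:malignant ratio of 718:448;
  the malignant count is `round(n · 448/1166)`, so a 1166-case cohort
  contains exactly 718 benign and 448 malignant cases. Malignant cases
  carry at least one malignant lesion (plus possibly benign ones); benign
  cases carry 0–2 benign lesions under the default `lesion_count_range`.
- **Determinism.** Each case is generated from an integer seed; cohort
  case seeds are spawned from the cohort seed via `numpy` `SeedSequence`.
  Identical (spec, label, seed) yields bit-identical volumes.

What the phantom does **not** model: MR physics (no bias fields, no Rician
noise, no sequence-dependent geometry), inter-sequence misregistration,
anatomical variability beyond ellipsoid jitter, and — most importantly —
realistic class overlap. A classifier reaching AUC ≈ 1 on phantoms shows
the pipeline recovers planted signal without leakage; it predicts nothing
about clinical AUC.

## Preprocessing

Each sequence is normalized, resampled to 0.75 × 0.75 × 3 mm and centre
cropped / symmetrically zero-padded to 149 × 149 × 32 voxels, in that
order. Two z-score variants exist: the global z-score (`zscore`, exactly
idempotent; the default for the standalone operator) and the
foreground-only z-score (`zscore_fg`, statistics over nonzero voxels with
background left at zero). The study chain defaults to `zscore_fg` so that
the zero padding added by crop/pad does not shift the statistics when the
chain is re-applied — the full chain is a fixed point either way on
phantom input, which has no exact zeros before padding. A constant volume
normalizes to all zeros with a logged warning.

Resampling is corner-aligned: output voxel `i` samples input coordinate
`i · target_spacing / source_spacing` (voxel units), linear interpolation
for images, nearest-neighbour for masks, edge-clamped. Masks stay binary
through the whole chain, and crop/pad offsets are a deterministic function
of the grid shape, so images and masks remain aligned. Centring is on the
grid centre, not the gland centroid, because no segmentation is available
at this position in the upstream-filter setting.

## Texture features (297 per sequence, 891 per study)

The per-sequence feature count decomposes as 169 + 64 + 64:

- **Haralick / GLCM (169).** Intensities are quantized into 32 equal-width
  gray levels over the (sub)volume's range. For each of the 13 unique 3D
  offset directions at distance 1 (one per antipodal pair of the
  26-neighbourhood) a co-occurrence matrix is accumulated, symmetrized and
  normalized to sum 1. The 13 classic statistics — energy, contrast,
  correlation, variance, homogeneity, sum average, sum variance, sum
  entropy, entropy, difference variance, difference entropy, IMC1, IMC2 —
  are computed per offset (no offset averaging), logs base 2, gray levels
  indexed 0..31. Degenerate cases are defined: zero marginal SD gives
  correlation (and IMC1) 0; `0·log 0 = 0` throughout.
- **3D LBP (64).** Six face-adjacent neighbours per interior voxel, bit
  set iff neighbour ≥ centre (ties encode as 1), yielding 2⁶ = 64 codes;
  the normalized code histogram is the descriptor. A constant volume puts
  all mass in code 63.
- **3D HOG (64).** Central-difference gradients (spacing-aware, so the
  anisotropic z-axis is weighted physically), binned by orientation into 16
  solid-angle bins and weighted by gradient magnitude. The 16 bins are the
  antipodally merged icosahedron directions: 6 vertex directions plus 10
  face-centre directions; a gradient falls into the bin whose direction
  maximizes `|g·d|`. The volume is divided into a 2 × 2 × 1 cell grid
  (respecting the thin z extent), each cell histogram L2-normalized with an
  epsilon guard; a constant volume yields the zero descriptor.

Feature names are stable and modality-prefixed (`t2w_…`, `adc_…`,
`dwi_…`); a study vector concatenates T2W, ADC, DWI in that canonical
order regardless of supply order. The peripheral-zone setting uses ADC
only and therefore yields a 297-vector.

This decomposition of 297 is a design choice: the canonical 13 statistics ×
13 offsets plus round LBP/HOG bin counts is the simplest configuration
meeting the per-sequence contract, and it is config-encoded
(`FeatureConfig` rejects any configuration that does not total 297).
Offsets and LBP neighbourhoods live in voxel space; because all inputs are
resampled to a common spacing first, voxel space is consistent across
cases. Spacing enters only HOG gradient scaling.

## Feature selection

PCA (scikit-learn, full SVD) with a default of 95 retained components —
the packaged best whole-image SVM preset — or greedy mRMR. mRMR uses the
mutual-information difference (MID) criterion: the first feature maximizes
I(f; y); each next feature maximizes I(f; y) − mean over selected g of
I(f; g). Continuous features are discretized into three levels at
mean ± SD before MI; ties break to the lowest feature index, making
selection deterministic and permutation-equivariant. The quotient (MIQ)
criterion is available by config. Selection models carry a fitted flag and
refuse to transform before fitting, which enforces per-fold fitting at the
API level. When a training fold is smaller than the requested PCA k, the
evaluation harness caps k at `n_train − 1` (the preset value applies
whenever feasible; the structural 95-component contract is asserted at
cohort sizes that support it).

## Classifiers

Three families behind one contract (confidences in [0, 1]; label =
confidence ≥ threshold; feature-name contract enforced on prediction):

- **SVM** — scikit-learn SVC; best preset: RBF kernel, C = 60 (the
  "error tolerance" of the preset configuration), balanced class weights.
  Confidences are the decision margin through a logistic squashing rather
  than Platt scaling, keeping the family fully deterministic: changing only
  the seed never changes SVM output.
- **GBT** — XGBoost with learning rate, max depth, max leaf count exposed;
  class imbalance handled by `scale_pos_weight = n_neg/n_pos`.
- **MLP** — scikit-learn MLPClassifier (layer layout and L2 penalty
  exposed). It has no class-weight mechanism, so imbalance is unhandled
  for this family; seeds control its stochastic fitting.

Hyperparameter optimisation is a seeded random search over the family's
dimensions, scored by mean 3-fold inner-CV AUC-ROC, with the full trial log
returned. A heavier model-based optimiser was deliberately not used: the
search interface is what matters here, and random search keeps it
dependency-free and reproducible.

## Regions and sliding windows

Regional inputs crop a bounding box around the relevant mask (margin 2
voxels in-plane, 0 across slices — peritumoral texture without crossing
slices) and resample it to a fixed per-kind shape (whole 149×149×32, gland
96×96×18, pz 96×56×18, lesion 28×28×8), so features have consistent
support across cases; the shapes were sized once from the default phantom
geometry and are config-overridable. Boxes are raw (background not
zeroed). Benign cases without lesions yield an empty lesion-input list,
which is valid.

The sliding window is 70 × 65 × 3 voxels at 50% overlap: stride
`floor(dim/2)` = (35, 32, 1), plus one clamped final window per axis so
every voxel is covered. A window takes a lesion's label when
`|window ∩ lesion| / |lesion| > 0.5` (strict; malignant wins when several
lesions qualify), else it is background. The lesion-relative denominator is
deliberate: a window-relative ratio would make any lesion smaller than half
the 13,650-voxel window unlabelable. Window classifiers are trained
malignant-vs-rest (background and benign merged into the negative class);
the three-way labels are retained in the window tables. Heatmaps average
the confidences of all windows covering a voxel (order-independent; max
accumulation available). The image-level rule labels a study malignant iff
any voxel exceeds the ROC cutoff, with optional restrictions (minimum
connected-component size; gland-mask gating) that suppress supra-threshold
blobs outside the prostate. The cutoff maximizes Youden's J over validation
scores, with candidates at midpoints between adjacent distinct scores —
for perfectly separated classes this lands mid-gap; a best J ≤ 0 is
flagged as degenerate in the returned diagnostics.

## Evaluation protocol

A stratified 85/15 train/test split, then stratified 5-fold CV inside the
85%. Feature selection and classifiers are fitted per fold on fold-train
rows only; lesion- and window-level instances inherit their case's
assignment, so a case never straddles a fold. Final test metrics come from
a refit on the full 85% (a protocol choice, logged in every report).
Metrics: AUC-ROC (the Mann–Whitney pairwise probability), sensitivity and
specificity at the declared cutoff, malignant positive; an undefined rate
(no positives or no negatives present) is reported as NaN, never as 0.

**Pipeline emulation.** The external segmentation pipeline is emulated,
not reimplemented: `EmulatedSegmenter` returns ground-truth lesion masks,
dropping each with probability `fn_rate` and adding Poisson(`fp_rate`)
spherical false proposals inside the gland (benign-textured tissue, which
is what makes downstream texture classification of proposals meaningful).
Proposals are deterministic per (seed, case index), so an always-pass
filter reproduces the segmenter-only baseline exactly. The default is an
over-proposing regime, recreating the low-specificity setting a
false-positive filter exists for. Mode 1 gives filtered-out cases the
final label 0 and skips segmentation (skip counts are reported); mode 2
classifies every proposal and calls the case malignant iff any proposal is
called malignant. Both are scored at case level against case truth.

## Problem sizes

Defaults are sized for a laptop-class single CPU: unit and property tests
run on reduced phantom grids (48³·12 to 64²·16 voxels) with cohorts of
8–60 cases; the structural acceptance computation uses 120 cases at the
full 149 × 149 × 32 geometry. Sliding-window training scales with window
count × feature cost and is exercised on reduced grids; the window
*geometry* contracts are verified at full scale, where they are cheap.

## Known limitations

- Phantom realism: see above; no claim of clinical transfer is made or
  testable here.
- The 297-feature composition is one contract-satisfying choice; the
  decomposition (and GLCM level count, LBP neighbourhood, HOG geometry) is
  config-encoded rather than canonical.
- mRMR's MI discretization (3 levels at mean ± SD) is coarse by design;
  heavily skewed features lose information under it.
- MLP lacks class weighting; on strongly imbalanced cohorts prefer SVM/GBT
  or rebalance upstream.
- The emulated segmenter corrupts ground truth geometrically (drop/add),
  not morphologically (no boundary errors, no partial masks).
- PCA/mRMR are alternatives, never chained.
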