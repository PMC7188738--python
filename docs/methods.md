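# Methods

This note records the mathematical definitions, parameter conventions and
numerical choices implemented in `gliorad`, including every place where a
convention had to be chosen.

## Feature extraction

All texture analysis is **2D in-plane per axial slice**, pooled over
slices, on gray levels quantized to `n_levels = 64` equal-width bins
between the ROI minimum and maximum (`level = floor((v - lo)/(hi - lo) *
Ng) + 1`, clipped to `Ng`; a constant ROI maps to level 1). Quantization
is invariant under positive affine rescaling of the intensities (and only
under affine maps — a general monotone transform changes bin boundaries).

### First-order (raw intensities)

- `Quantile0.025`: 2.5th percentile, linear interpolation.
- `RMS`: sqrt(mean(x²)).
- `stdDeviation`: population SD (ddof = 0).
- `RelativeDeviation`: mean(|x − mean|)/|mean|; defined as 0 for a
  constant ROI and NaN (with a warning) when the mean is zero.

### GLCM

Pairs of in-mask voxels displaced by `offset` steps along angle
θ ∈ {0°, 45°, 90°, 135°} (row/col steps (0,1), (−1,1), (−1,0), (−1,−1))
are counted within each slice, symmetrized, and normalized to sum 1.
Features: GLCMEnergy, Inertia, Correlation, HaralickCorrelation,
ClusterShade, ClusterProminence, InverseDifferenceMoment, in their
standard-reference forms with levels indexed 1..Ng. When the marginal
variance is zero (single-level ROI), Correlation is defined as 1 and
HaralickCorrelation as 0. A direction/offset combination with no valid
pair raises `EmptyGlcmError` and surfaces as NaN in the catalogue.

### GLRLM

Runs are maximal sequences of equal level along lines in the angle
direction. The **offset is a sampling stride**: the line is sampled every
`offset` voxels (all `offset` phases pooled), so `offset = 1` is the
classical run-length matrix and larger offsets measure run structure at a
coarser scale. This is this package's own convention — the source
equations list run-length features at offsets 4 and 7 without defining
"offset" for runs. Unmasked sampled voxels, slice boundaries and line
boundaries all terminate runs. Features: ShortRunEmphasis,
LongRunHighGreyLevelEmphasis, ShortRunLowGreyLevelEmphasis,
ShortRunHighGreyLevelEmphasis, normalized by the number of runs.

### Direction aggregation

`AllDirection` is the mean over the four angles, `_SD` the population SD.
Angles whose value is undefined are dropped from both aggregates; the SD
is NaN when fewer than two angles remain. The catalogue (3 offsets × 11
texture features × (4 angles + 2 aggregates) + 4 first-order + sphericity
= 203 per modality, + TBRmean/TBRmax per PET tracer = 613 total) depends
only on the configuration, never on the data; unattainable combinations
are NaN and a patient with more than 20 % missing raises.

### Shape and uptake

Sphericity = π^(1/3)(6V)^(2/3)/A. Two surface-area estimators:

- `mesh` (default): marching-cubes triangulation of the 0.5 isosurface of
  the mask indicator after 0.8-voxel Gaussian smoothing. Smoothing removes
  the ~1.5× staircase-artifact overestimate of a raw binary isosurface
  (a radius-10 ball scores 1.000; without smoothing it scores ≈ 0.92);
  angular shapes can slightly exceed their analytic value.
- `faces`: exposed voxel-face counting, under which a cube scores exactly
  (π/6)^(1/3); used by the oracle tests.

TBRmax/TBRmean = max/mean lesion uptake over mean background uptake.

## Selection and model fitting

- **ICC(2,1)** (two-way random effects, absolute agreement, single
  measure) per feature between the two raters' tables, via the closed-form
  ANOVA decomposition, vectorized across features; retain ICC > 0.8.
  Zero-variance features have undefined ICC and are not retained.
  (Verified against `pingouin`'s ICC(A,1) to 1e-9.)
- **Spearman pruning**: greedy scan in a seeded random order; a scanned
  feature correlating with |ρ| ≥ 0.9 against an already-kept feature is
  dropped. Idempotent; constant columns are dropped first.
- **Standardization** to zero mean / unit population SD on the primary
  cohort; the stored (mean, SD) pairs are applied unchanged to validation
  data and are embedded in exported models.
- **L1-penalized logistic regression** minimizing
  `L = (1/m) Σ [ln(1 + e^η) − y·η] + (λ/2)‖β‖₁` with an unpenalized
  intercept. Solver: IRLS outer loop with coordinate soft-thresholding on
  the weighted least-squares subproblem, warm-started along a descending
  grid of 100 log-spaced λ from the data-driven λ_max (smallest λ with an
  all-zero solution, `2·max|Xᵀ(ȳ − y)|/m`) down to λ_max·1e−4, with
  sequential strong-rule screening and full KKT verification (violators
  are pulled into the working set). Convergence is certified by the exact
  KKT subgradient residual ≤ `tol` (default 1e−8; the acceptance bound is
  1e−6). The inner sweep tolerance is clamped to [1e−7, 1e−6] — loose
  enough to avoid thousands of sweeps, tight enough that the outer test
  can pass.
- **λ choice**: stratified shuffled k-fold CV (10-fold default, 5-fold
  variant) minimizing mean held-out negative log-likelihood; ties resolve
  toward the larger (sparser) λ. Fold-path fits use a relaxed tolerance
  (`max(tol, 1e−5)`) because they only feed the loss curve; the reported
  full-data path keeps the exact tolerance. This changes no chosen λ in
  our checks but cuts CV cost ≈ 3×.

## Evaluation

- AUC as the Mann-Whitney statistic (ties count ½).
- 95 % CI by stratified (within-class) bootstrap percentiles, 2000
  resamples, seeded.
- Operating point by the Youden index over observed score thresholds,
  ties toward the lowest threshold; positives are score ≥ threshold.
- Decision curves: NB(p_t) = TP/n − (FP/n)·p_t/(1 − p_t) on the grid
  0.01…0.99 (step 0.01), against treat-all and treat-none.

## Synthetic cohort generator

Scope: the generator produces phantoms for pipeline validation, not
physically realistic brains. Per patient it builds a 32×32×16 grid at
2×2×4 mm with an ellipsoidal lesion in the left hemisphere, a mirrored
contralateral ellipsoid as PET background reference, and Gaussian-
correlated intra-lesion texture whose amplitude and correlation length are
drawn per patient from class-dependent truncated normals (recurrence:
finer, stronger heterogeneity). Mean uptake per tracer follows the study's
class-conditional TBR distributions (FDG 2.83 ± 1.38 vs 1.54 ± 1.21; MET
2.81 ± 2.12 vs 1.23 ± 0.62; MR enhancement analogue 1.80 ± 0.50 vs
1.40 ± 0.40). A second rater is simulated by seeded stochastic boundary
flips (probability 0.3 per round) with the eroded lesion core always
retained. Randomness fans out through `numpy.random.SeedSequence.spawn`,
one child per patient, so cohorts are bit-reproducible per seed and
patients are independent.

Defaults are the study conditions: 118/42 class sizes, 0.7 split giving
112 primary (83 recurrence = 74.1 %) and 48 validation (35 recurrence =
72.9 %).

## Pipeline determinism

One global seed is fanned out per stage through SHA-256 of
`"{seed}:{stage}"` (mod 2³¹). Every artifact is hashed (SHA-256) into
`manifest.json`; feature CSVs are parsed back with round-trip float
precision so a resumed run (`skip_extract`) reproduces downstream
artifacts bit for bit.

The permuted-label null study (`permutation_null_auc`) is a facility of
this package; its problem sizes are package choices: 100 permutations,
30-λ grid truncated at λ_max·1e−2 (permuted labels always select a large
λ, so the overfitting tail of the path is never chosen), 5-fold CV,
solver tolerance 1e−5. Permutations yielding a constant score vector
count as AUC 0.5.

## Limitations

- Texture is strictly 2D in-plane; no 3D co-occurrence or wavelet/filtered
  features, no gray-level size-zone or dependence matrices.
- The phantom generator is a statistical caricature: no anatomy, no
  partial-volume or scanner noise model, and its effect sizes are inputs,
  not discoveries — pipeline validation shows the machinery recovers
  injected signal (validation AUC > 0.85) and finds none in permuted
  labels, not that the published AUCs generalize.
- The published models' standardization constants are not recoverable
  from the source equations, so packaged published models apply to
  already-standardized inputs (`standardization: null`).
- ICC supports exactly two raters; the bootstrap CI is percentile (no
  BCa); DCA carries no confidence bands.
- The mesh sphericity estimator is biased slightly high for angular
  shapes (cube ≈ 1.07) as a consequence of the smoothing that removes the
  much larger staircase bias for rounded shapes.
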