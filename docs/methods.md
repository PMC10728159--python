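# Methods

`pfntopo` implements an end-to-end analysis linking personalized functional
brain-network topography to cognition. Because the cohort data such an
analysis is designed for (surface-sampled BOLD time series from a large
multi-site developmental study) are restricted-access, the package ships a
synthetic-cohort generator with known ground truth; every stage is
validated against that ground truth or against independent closed-form /
brute-force oracles.

## Model

### Personalized functional networks (PFNs)

Each subject's preprocessed, rescaled time-series matrix `X` (T frames ×
N cortical vertices, entries in [0, 1]) is factorized by non-negative
matrix factorization,

    X ≈ U V,    U ∈ ℝ₊^{T×K},  V ∈ ℝ₊^{K×N},

where each row of `V` is one network's spatial loading map and `U` holds
the network time courses. Two penalties shape `V`:

    F(U, V) = ‖X − U V‖²_F  +  α ‖V − V^g‖²_F  +  β tr(V L Vᵀ)

* **Group consensus** (weight α, default 1): `V^g` is a shared group
  atlas; the penalty keeps network k meaning the same thing in every
  subject while allowing individual deviation. The default α = 1 is a
  package choice — the weight is exposed in `DecompositionConfig` because
  no canonical value exists for desk-scale data.
* **Data locality** (weight β, default 300): `L = D − W` is the Laplacian
  of the mesh-adjacency graph weighted by the positive part of the Pearson
  correlation between adjacent vertices' time courses. It smooths loadings
  along the cortical sheet in proportion to local temporal coherence,
  making the decomposition robust to noise. Negative correlations are
  clipped to zero so `L` stays positive semidefinite and the objective
  stays bounded below.

Minimization uses multiplicative updates

    U ← U ∘ (X Vᵀ) ⊘ (U V Vᵀ + ε)
    V ← V ∘ (Uᵀ X + α V^g + β V W) ⊘ (Uᵀ U V + α V + β V D + ε)

with ε = 1e−10 guarding denominators. Starting from nonnegative factors
every iterate stays nonnegative and the objective is non-increasing (the
update for `V` is the standard graph-regularized NMF majorize–minimize
rule with the consensus term folded in; the suite asserts monotonicity at
relative slack 1e−12). `V` is initialized at the atlas and `U` by
per-frame nonnegative least squares of `X` onto the atlas, which makes the
fit deterministic. Iteration stops when the relative objective decrease
falls below 1e−6 or after 1000 iterations; the full objective trajectory
is returned so convergence can be audited. No re-normalization is applied
between sweeps: the consensus term anchors the scale of `V` to the atlas.

### Group atlas derivation

The consensus atlas is built by running unregularized NMF (α = β = 0,
random uniform initialization) `n_runs` times, each on a random half of
the participants with data row-stacked in time; pooling all `n_runs × K`
components; clustering them into K groups by normalized-cuts spectral
clustering on their pairwise spatial correlation; and keeping, per
cluster, the component with the highest mean within-cluster similarity.
An empty cluster raises an error (the networks are not separable at that
K). With `n_runs = 1` the single run's components are returned unchanged.

### Preprocessing and QC

Frames are censored when framewise displacement exceeds 0.2 mm or when
the z-scored per-frame global mean signal exceeds ±3 SD (the outlier
statistic is not fully pinned down by upstream conventions; the global
mean is the simplest defensible choice and is isolated in one function).
Participants with fewer than 600 surviving frames are excluded — the
synthetic pipeline uses a proportionally reduced floor since desk-scale
cohorts have shorter runs. Runs are concatenated in time. Rescaling is
per vertex: subtract the minimum, divide by the maximum of the shifted
course; constant vertices map to zeros. Frames are dropped, never
interpolated.

### Topography metrics

* **Total cortical representation (TCR)**: per-network sum of loadings
  over all vertices (soft parcellation) — the network's spatial extent.
* **Hard parcellation**: each vertex labeled by its highest-loading
  network, ties toward the lowest index, all-zero columns unassigned.
* **Mean S-A rank**: average sensorimotor-association-axis rank over each
  hard parcel, excluding unassigned and medial-wall vertices; empty
  parcels yield NaN rather than an error (they can occur at low mesh
  resolution under strong consensus deviation).
* **Split-half reliability**: ICC(2,1) — two-way random effects, absolute
  agreement, single measures — across vertices (targets) with the two
  data halves as raters. The variant is recorded in the output; it is the
  standard agreement ICC when both halves are exchangeable measurements.

### Harmonization and univariate association

ComBat removes per-site location and scale effects from the subject ×
feature table while protecting age, sex and family structure: the
standardization design contains site indicators plus the protected
covariates, site effects are estimated on the standardized residuals and
(optionally) shrunk by the standard parametric empirical-Bayes scheme,
then removed. Site variances use the maximum-likelihood (1/n) convention,
which makes the single-site transform an exact identity. Family is a
grouping factor with mostly singleton levels, so it is protected through
indicator columns for multi-member families only — encoding every family
would make the design rank deficient.

The association between one network's TCR and cognition is a
random-intercept linear mixed model (intercept per family, so siblings
share it) with fixed effects for cognition, age, sex and mean FD, fit by
REML with Wald z tests (a normal reference; at the sample sizes involved
the difference from a t reference is negligible). Bonferroni adjustment
multiplies by the number of networks within a cognitive domain (17 in the
full-scale design, the cohort's K here).

### Multivariate prediction

Ridge regression predicts cognition from concatenated vertex-wise
loadings. The λ grid is the 16 ascending powers of two 2⁻¹⁰ … 2⁵.
Features are standardized with training statistics; the intercept is
unpenalized; all grid solutions reuse one economy SVD of the training
matrix. Covariates (age, sex, one-hot site, mean FD) are removed by
residualizing the *outcome* on the training fold only, and the same
training coefficients adjust the test fold — residualization rather than
unpenalized covariate columns keeps the penalty off the covariates and
makes the no-leakage contract easy to state and test.

λ selection is an inner two-fold cross-validation: for each λ, mean
held-out Pearson r and mean MAE over the two inner directions; the mean-r
vector and the mean-1/MAE vector are min–max normalized across the grid
(a constant vector maps to zeros, so a flat r profile leaves the choice
to MAE) and summed into the inner prediction accuracy; the argmax wins
with ties toward smaller λ; undefined r (constant predictions) takes the
grid's minimum defined r before normalization. Outer two-fold
cross-validation between two disjoint samples reports held-out r and MAE
per direction; repeated random half-splits (default 100) give an accuracy
distribution; permutation tests shuffle the outcome and rerun the entire
nested procedure, with the one-sided add-one p-value
(1 + #{null ≥ observed}) / (1 + n_perm). Per-network models use one
network's vertex loadings at a time; weight summaries report signed and
absolute sums within each network's feature block.

### Spin test

The correlation between per-network prediction accuracy and per-network
mean S-A rank is tested against a spatial-rotation null: Haar-uniform
proper rotations of the spherical mesh (QR of a Gaussian matrix with sign
correction; the contralateral hemisphere uses the mirror-conjugated
rotation F R F), each vertex taking the value of the nearest original
vertex to its rotated position. Rotated-in medial-wall values become
missing and are excluded from parcel means; parcel means are recomputed
under *fixed* labels with the rotated map; a spin retaining fewer than 3
networks with defined means is dropped from the null (the denominator
uses valid spins). The p-value is one-sided toward larger ρ by the
add-one rank rule, matching a directional reading of rank ordering;
Spearman ρ is the Pearson correlation of average-tied ranks.

## Synthetic cohorts

The generator emulates exactly the structure the pipeline consumes:

* **Mesh**: icosphere per hemisphere (default subdivision 3, 642 vertices
  per hemisphere — a desk-scale stand-in for the ~59k-vertex cortical
  sheet; every algorithm here is resolution-agnostic), right hemisphere
  mirrored across the sagittal plane, a polar cap of 5% of vertices
  flagged as medial wall to exercise missing-data paths.
* **Atlas**: K geodesic bumps `exp(c (cos θ − 1))` seeded by
  farthest-point sampling; concentration c = 5 so loadings overlap and
  cover the cortex, as real soft parcellations do.
* **Subjects**: each network's seed is displaced along a random geodesic
  (half-normal angle, scale `topography_jitter` = 0.15 rad) and its
  extent scaled by a lognormal width multiplier
  (`network_width_sd` = 0.3) — the width variation is the main driver of
  between-subject TCR differences, mirroring how network spatial extent
  varies across people. Time courses are nonnegative AR(1) processes
  (coefficient 0.4, half-normal innovations), matching NMF's
  nonnegativity directly; observed data are `U V` plus Gaussian noise
  (sd 0.1). FD traces are lognormal (median 0.08 mm, log-sd 0.6) with 5%
  spike frames ×4, producing both censored frames and excludable
  subjects at the 0.2 mm threshold.
* **Outcome**: cognition couples linearly to *true* TCR (default: weight
  0.2 on one network, giving a cognition–TCR correlation near 0.6 —
  chosen for testability since no empirical effect size is available for
  simulation), plus age/sex/mean-FD effects, a per-site intercept and a
  small per-site multiplicative gain on the loadings (so harmonization
  has a real feature-level effect to remove), a per-family random
  intercept shared by sibling pairs, and Gaussian noise. The executive
  function and learning/memory scores share the coupling attenuated by
  0.7 and 0.5 with independent noise.
* **S-A axis**: a random degree-1–3 spherical-harmonic mixture ranked
  1..M over non-medial vertices — smooth and isotropic, which is what the
  spin-test calibration checks require.

What the generator does *not* emulate: hemodynamics, task structure,
scanner artifacts, spatially heterogeneous noise, genuine anatomical
medial-wall geometry, or any empirically calibrated effect size. Passing
tests therefore demonstrate the *machinery* is correct and calibrated on
data satisfying the model's assumptions, not that real cortical data
satisfy them.

## Problem sizes and numerical choices

Test and acceptance runs use reduced sizes chosen to keep the whole suite
desk-scale: end-to-end loading recovery uses n = 200 subjects on a
642-vertex single-hemisphere mesh at T = 150; prediction validity uses
n = 400 subjects with ground-truth loadings as features (running the NMF
inside every Monte-Carlo replicate would test nothing additional about
the predictor); permutation and spin calibrations use 200 null cohorts
with 99 permutations / 200 spins each; mixed-model recovery uses
n = 1000 with 200 families. Convergence tolerances, tie-breaking rules
and degenerate-input behavior (constant vertices, empty parcels,
zero-variance features, all-NaN r vectors) are stated next to the
functions that implement them and covered by tests.

`scripts/acceptance.py` re-runs all of these computations from scratch
with a caller-supplied seed and writes the measured quantities to JSON.

## Known limitations

* The NMF objective's consensus weight α has no empirically validated
  default; results at other scales should sweep it.
* Multiplicative updates converge slowly near the optimum; the 1e−6
  relative tolerance trades accuracy for runtime, and the returned trace
  lets users tighten it.
* ComBat here implements the parametric empirical-Bayes variant only.
* The mixed model supports a single random intercept (family); nested or
  crossed structures are out of scope.
* The spin test assumes maps live on a sphere; it is exact for the
  synthetic icosphere but only approximate for real, areally distorted
  spherical registrations.
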