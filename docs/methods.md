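# Methods

This note describes the models and procedures implemented in
`voxelhisto`, the choices made where the design was genuinely open, and
what the synthetic validation does and does not demonstrate.

## Problem setting

The package addresses voxel-based statistical analysis of segmented
high-resolution marker images — binary masks of an immunostained marker
(the motivating case is amyloid-beta plaques in mouse brain histology at
a 5 µm pixel size), pre-registered to a common template. Direct
voxel-to-voxel comparison at microscopic resolution is hopeless: the
binary signal and the inter-individual variability of microstructure
swamp any group effect. The pipeline therefore (1) converts each binary
image into a lower-resolution continuous *marker-load* map (the local
tissue fraction occupied by the marker), (2) compares maps voxel-wise
between groups, and (3) controls family-wise error over voxels with
permutation cluster-mass inference.

## Boolean-Poisson simulator

Synthetic cohorts are realizations of a Boolean model: disk centers
follow an inhomogeneous Poisson point process with piecewise-constant
intensity λ(x), and disk radii are Gaussian, N(7, 2²) pixels by default
(a typical plaque radius at 5 µm/px). The intensity is a constant
background plus four square clusters whose rates are the background
times 20, 10, 5 and 2.5 — the "exacerbated" condition; the control
condition has no clusters. The basal expected disk count per image, Λ ∈
{40, 80, 160} over a 2560×2560 px image, spans sparse to dense marker
regimes; cohorts have 10 images per group, a realistic animal-study
sample size.

Choices behind the simulator:

* **Cluster geometry.** Side 512 px (one fifth of the image, 4% area
  each), centered in the four image quadrants, multipliers assigned
  top-left 20, top-right 10, bottom-left 5, bottom-right 2.5. The
  quadrant layout keeps clusters far apart relative to plausible
  smoothing kernels.
* **Λ semantics.** Λ is the expected number of *background-rate* seeds
  over the whole image; cluster multipliers scale the per-pixel rate, so
  the expected total in the exacerbated condition is
  Λ·(1 + Σᵢ fᵢ(mᵢ − 1)) with fᵢ the cluster area fractions (e.g. 93.6
  disks at Λ = 40).
* **Radius truncation.** Gaussian radii can be non-positive; the default
  rule resamples them (a 3.5 sd event, negligible but it keeps E[R²]
  well-defined); clipping to zero is available.
* **Rasterization.** A pixel belongs to a disk iff its center (at
  integer coordinates) is within the sampled radius of the seed; disks
  are clipped at image borders; overlaps are a Boolean union.
* **Determinism.** Each image draws from its own RNG substream spawned
  from the config seed, so cohorts are bit-reproducible and independent
  of generation order.

The true marker load µₓ — the probability that pixel x is covered — has
the closed form µₓ = 1 − exp(−∫ λ(y) P(R ≥ ‖x−y‖) dy). It is evaluated
by convolving the intensity grid with the radius survival function
sampled on the pixel lattice (the lattice sum matches the continuous
integral to ≪0.1% for the default radius model); for a homogeneous field
this reduces to 1 − exp(−λ π E[R²]). Estimator accuracy is scored as the
mean squared error between the cohort-mean map and this truth aggregated
to map resolution.

What the simulator does *not* emulate: anatomy (no brain mask or
spatially varying tissue), registration error, segmentation noise,
non-circular or spatially correlated objects, and group differences in
object *size* or *shape* (only seeding density differs). Passing the
benchmark therefore shows the estimators and inference behave correctly
under a known stochastic-geometry model, not that they are robust to
those real-data effects.

## Parametric map estimators

All estimators end with window-mean binning (default 18×18, i.e. 90 µm
maps from 5 µm pixels — about the smallest biologically interesting
cluster size; a 2560-px image yields 143×143 maps whose last row/column
average 4-px partial windows rather than discarding tissue).

* **Binning alone** — unbiased but high-variance at realistic densities.
* **Voronoi + binning** — connected objects are reduced to centroids
  (rounded to the nearest pixel), the image is partitioned into
  nearest-centroid cells by exact Euclidean feature transform, and every
  pixel of a cell carries load = object area / cell area. Parameter-free.
* **Gaussian smoothing + binning** — convolution with a unit-sum sampled
  Gaussian kernel (truncated at 4 sd, zero padding; with a brain mask the
  result is renormalized by the smoothed mask so border voxels stay
  unbiased). The kernel sd σ is the one free parameter.

For cohort-scale sweeps the smoothing is evaluated by zero-padded FFT
with per-sweep padding large enough to make circular convolution equal
linear convolution; it is the same sampled kernel as the spatial path
and agrees with it to float32 precision (tested).

## Bootstrap bandwidth selection

σ is chosen to minimize an out-of-bag bootstrap estimate of the squared
error of the smoothed-map sample mean: draw B bootstrap samples of the T
individuals with replacement; for each individual j, average the
voxel-mean squared difference between the mean smoothed map of every
sample not containing j and j's raw binary image; average over j
(individuals that appear in every sample are skipped, and it is an error
for all of them to be). The error is computed per experimental group
with one shared set of bootstrap samples across the σ grid (common
random numbers), and the selected σ minimizes the across-group mean
curve, ties toward the smaller σ. The implementation regroups the voxel
sums into Gram matrices of the smoothed images — algebraically identical
to materializing every bootstrap mean, and tested against the direct
enumeration.

Defaults: B = 1000; candidate grid of 10 geometric values from 2 to
64 px. The benchmark and validation runs use B = 100, which changes the
selected σ only within Monte-Carlo noise at these cohort sizes. A
subsampling stride over voxels exists for very large volumes but is off
by default.

Note a property of the default simulated geometry: with 512-px clusters
the true-error curve keeps decreasing up to σ = 64, so both the true and
the bootstrap-selected optimum sit at the top of the default grid rather
than at an interior minimum; the selection criterion is that the
bootstrap argmin tracks the true-error argmin, which it does. Smaller
clusters (or a wider grid) move the optimum into the interior.

## Voxel-wise inference

Group maps are compared with a two-tailed two-sample Student t test per
voxel (pooled variance, df = nₐ+n_b−2; Welch available). Voxels where
both groups are constant and equal get t = 0, p = 1. The p map is
thresholded at the cluster-forming level (0.05), suprathreshold voxels
are grouped into connected components separately for t > 0 and t < 0
(default connectivity: 8 in 2D, 26 in 3D), and each cluster's mass is
the sum of |t| over members.

For family-wise error control, group labels are permuted preserving
group sizes (all distinct assignments are enumerated when there are
fewer than the requested permutations), the maximum cluster mass is
recorded per permutation (0 when none forms), and a cluster's corrected
p is (1 + #{null ≥ mass}) / (1 + n_perm) — the +1 convention avoids zero
p values at n_perm = 100. The observed labeling is not included in the
null set. In the simulation benchmark, detection is scored on the
*uncorrected* p < 0.05 map restricted to the planted direction
(exacerbated > control; opposite-sign detections count as false
positives), with the ground-truth mask at map resolution defined by
majority coverage (>50% of a bin's source pixels inside a true cluster).
The permutation correction is exercised separately by a type-I
calibration study.

## Within-cluster object statistics

Significant clusters are mapped back to image resolution
(nearest-neighbor replication of map voxels) and marker objects are
re-examined there: connected components are labeled per coronal slice by
default (objects are defined in the sectioning plane; volumetric 3D
labeling is available), an object belongs to a cluster iff its centroid
voxel lies in the cluster mask (any-overlap and majority-overlap rules
available), per-individual counts are compared with the pooled t test
(with percent change of means), and per-object sizes are exported as a
tidy CSV for mixed-model analysis in any statistics package — the size
model itself is deliberately out of scope.

## Validation problem sizes

The packaged validation suite runs: the full three-condition benchmark
(2560² images, 10 vs 10, five replicate cohorts per condition, B = 100);
the bandwidth-selection property on proportionally scaled cohorts (1280²
images, Λ = 10, 256² clusters, ten replicates); the coverage oracle on
200 homogeneous 2560² realizations; and the type-I calibration on 200
reduced-size cohorts (512² images with 40 expected disks per image —
keeping the per-image count rather than the per-area density, so maps
are informative enough for clusters to form and the false-positive rate
is actually exercised). These sizes were chosen as the smallest at which
each property is a sharp test; all quantities are recomputed at run
time.

## Numerical notes

* Window sums of binary images are accumulated in float32 (exact below
  2²⁴) and divided by actual window counts; float inputs keep their
  precision.
* Cohort-scale Gram/cross products use float32 BLAS with float64
  reduction of the small matrices; the bootstrap error of a cohort is
  reproducible across seeds within O(1/√B).
* Degenerate inputs: empty images yield all-zero Voronoi maps; a single
  object yields one whole-image cell; zero-intensity fields yield no
  seeds and zero true load.

## Known limitations

* The Voronoi estimator's cell boundaries depend on centroids rounded to
  the pixel grid; ties at exact half-pixel distances follow the feature
  transform's scan order.
* 3D smoothing uses an anisotropic kernel specified per axis; the
  FFT fast path is 2D-only (3D volumes go through the spatial filter).
* Permutation inference with 100 permutations cannot produce corrected
  p below 1/101; studies needing finer p values should raise n_perm.
* The simulator is 2D; 3D Boolean models with non-spherical grains are
  out of scope.
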