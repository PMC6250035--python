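# voxelhisto

Voxel-based statistical analysis of segmented high-resolution marker
images — e.g. amyloid-plaque masks from immunostained rodent brain
sections, pre-registered to a common template.

Comparing such images voxel-by-voxel at microscopic resolution is not
meaningful: the signal is binary and inter-individual microstructure
variability dwarfs group effects. `voxelhisto` instead

1. **builds parametric maps** — low-resolution continuous maps of the
   local *marker load* (tissue fraction occupied by the marker) — from
   each binary image, by window binning, Voronoi tessellation of object
   centroids, or Gaussian kernel smoothing (each followed by binning);
2. **selects the smoothing bandwidth** σ by minimizing an out-of-bag
   bootstrap estimate of the squared error of the smoothed-map sample
   mean,

   Err^boot = (1/T) Σⱼ (1/|C₋ⱼ|) Σ_{b∈C₋ⱼ} (1/n) Σᵢ ( μ̂^b(xᵢ) − Mⱼ(xᵢ) )²,

   where C₋ⱼ are the bootstrap samples not containing individual j,
   μ̂^b is the mean smoothed map of sample b and Mⱼ the raw binary
   image;
3. **detects between-group clusters**: a pooled two-sample t statistic
   per map voxel, thresholding at p < 0.05, sign-separated connected
   components scored by cluster mass Σ|t|, and family-wise error control
   by a permutation null of the maximum cluster mass (corrected
   p = (1 + #{null ≥ mass}) / (1 + n_perm));
4. **characterizes detected clusters** at full resolution: per-individual
   marker-object counts (compared with a t test) and a tidy object-size
   table for mixed-model analysis;
5. ships a **Boolean–Poisson simulator** (Poisson-seeded disks with
   Gaussian radii, piecewise-constant seeding intensity with rectangular
   high-rate clusters) whose exact coverage probability
   µₓ = 1 − exp(−∫ λ(y) P(R ≥ ‖x−y‖) dy) provides ground truth for
   benchmarking every stage.

See `docs/methods.md` for the models, defaults and design choices.

## Worked example

Simulate a two-group experiment (10 vs 10 images of 2560² px, basal
expected disk count 40, four clusters at rate multipliers 20/10/5/2.5),
select the kernel, build maps and detect clusters — all in Python:

```python
import numpy as np
from voxelhisto import (SimulationConfig, simulate_cohort, select_kernel,
                        estimate_map, tstat_map, f1_detection,
                        true_cluster_mask)

cfg = SimulationConfig(basal_expected_count=40.0, n_per_group=10, seed=1)
ctrl = simulate_cohort(cfg, "control")
exac = simulate_cohort(cfg, "exacerbated")

curve = select_kernel([ctrl, exac], n_bootstrap=100,
                      rng=np.random.default_rng(1))
print(f"selected sigma: {curve.selected_sigma:g} px")

maps = {g: [estimate_map(im, "gaussian_binning", (18, 18),
                         sigma=curve.selected_sigma).grid for im in imgs]
        for g, imgs in (("control", ctrl), ("exacerbated", exac))}
sm = tstat_map(maps["exacerbated"], maps["control"])
detected = (sm.p_values < 0.05) & (sm.t_values > 0)
truth = true_cluster_mask(cfg.image_shape, cfg.clusters, (18, 18))
print(f"detection F1: {f1_detection(detected, truth):.2f}")
```

Typical output (stochastic, seed 1):

```
selected sigma: 64 px
detection F1: 0.66
```

i.e. the bootstrap picks the largest candidate sd on this geometry (the
bias penalty of smoothing 512-px clusters is still small at σ = 64) and
about two thirds harmonic-mean precision/recall of the planted cluster
voxels is recovered from one 10-vs-10 cohort at the sparsest density;
averaged over replicates the benchmark yields F1 ≈ 0.67–0.74 across the
three density conditions (`scripts/acceptance.py` below).

The same pipeline is available from the shell, stage by stage:

```sh
voxelhisto simulate -c sim.yaml -o cohort/
voxelhisto select-kernel --group 'cohort/control_*.png' \
    --group 'cohort/exacerbated_*.png' -o sel/
voxelhisto maps 'cohort/exacerbated_*.png' -o maps_e/ \
    --estimator gaussian_binning --sigma 64
voxelhisto infer --group-a 'maps_e/*.tif' --group-b 'maps_c/*.tif' \
    -o clusters/ --n-perm 100
voxelhisto objects --manifest cohort/manifest.csv \
    --cluster-mask clusters/significant_mask.tif -o objects/
voxelhisto benchmark -o bench/
```

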