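# Methods

This note records the mathematical conventions, parameter choices and known
limitations of `fcmseg`. Notation: voxel index `j`, class index `k ∈ {1..K}`
(default `K = 3`: CSF, GM, WM, in ascending T1 intensity), intensity `y_j`,
centroid `v_k`, membership `u_jk` with `Σ_k u_jk = 1`, fuzzifier `q`.

## Intensity normalization

Unless disabled, intensities inside the brain mask are clipped to their
1st–99th percentile range and linearly rescaled to [0, 1]. This makes the
regularization weights below (β, γ) and the convergence threshold meaningful
across scanners and units; all defaults assume this scale. Normalization with
a degenerate (zero-width) percentile range is rejected with an error rather
than silently producing NaNs.

## The clustering energy

All three methods minimize

```
J(u, v) = Σ_j Σ_k u_jk^q ( (y_j − v_k)² + r_jk )
```

by alternating updates. The membership update is the closed-form stationary
point `u_jk ∝ a_jk^(−1/(q−1))` with `a_jk = (y_j − v_k)² + r_jk`; the centroid
update is `v_k = Σ_j u_jk^q y_j / Σ_j u_jk^q`. If any `a_jk < 1e-15` the voxel
gets a one-hot membership on the (first such) zero-cost class; ties between
identical costs therefore resolve to the lower class index. After
convergence, classes are relabeled in ascending centroid order, so class 1 is
always the darkest T1 tissue (CSF) and class 3 the brightest (WM). Label maps
use 0 for background (outside the mask).

Convergence is declared when the maximum absolute centroid change falls below
`thr`; the iteration budget is `n`.

### FCM

`r_jk = 0`. Defaults: `q = 2`, `n = 500`, `thr = 0.001`.

### RFCM (spatially regularized)

`r_jk = β Σ_{l ∈ N_j} Σ_{m ≠ k} u_lm^q` with `N_j` the 6-connected
neighborhood. Because each discordant pair is counted from both ends, the
objective carries the penalty with weight β/2. Defaults: `q = 2`, `β = 1`,
`n = 500`, `thr = 0.001`.

The membership update is a Jacobi sweep (all voxels updated simultaneously
from the previous iterate's neighborhoods). That surrogate step is not
guaranteed to decrease the true coupled objective, so each membership step is
wrapped in a backtracking line search: the step is halved (as a convex
combination with the previous memberships, which preserves row-stochasticity)
until the objective does not increase. An accepted full step is used verbatim
so that the β → 0 reduction is bit-identical to FCM. The reported objective
trace is therefore monotonically non-increasing by construction.

### AR-FCM (atlas regularized)

`r_jk = γ (1 − π_jk)^w`, where `π_jk` is a probabilistic atlas renormalized to
sum to one inside the mask (voxels whose atlas mass is ~0 fall back to the
uniform prior 1/3). Defaults: `q = 2`, `γ = 0.025`, `w = 1`, `n = 200`,
`thr = 0.001`. The penalty depends only on the atlas, not on `u`, so no
backtracking is needed.

Initialization: FCM and RFCM initialize centroids at the intensity quantiles
`(2i+1)/(2K)` of the masked voxels; AR-FCM initializes at the atlas-weighted
mean intensity per class. Every fitter also accepts explicit
`initial_centroids`, which is what makes the three methods exactly comparable
from a shared start (with β = γ = 0 they then realize the identical update map
and produce identical iterates).

A post-processing step (`redistribute_boundaries`) re-assigns boundary voxels
— voxels with at least one 6-neighbor carrying a different non-background
label — to `argmax_k u_jk · m_jk`, where `m` is a morphological atlas
(by default the same probabilistic atlas).

## Lesion screening and statistical filling

White-matter lesions are T1-hypointense and FLAIR-hyperintense; plain
clustering mislabels them as GM. The pipeline (LFA-FCM):

1. **Coarse segmentation**: plain FCM on the T1.
2. **FLAIR screening**: candidate lesion voxels are FLAIR intensities above
   `μ_GM + α·σ_GM`, where μ/σ are the mean and *population* standard deviation
   of FLAIR over the coarse GM class (default `α = 2`). Candidates are
   intersected with the coarse GM∪WM estimate, and 26-connected components
   smaller than `min_size = 10` voxels are discarded.
3. **Statistical lesion filling (SLF)**: per axial slice (array axis 2 by
   convention; the CLI `--axial-axis` option permutes other layouts), lesion
   voxels are replaced by draws from `Normal(μ_NAWM, σ_NAWM / 2)`, where NAWM
   is the coarse WM class on that slice minus the lesion mask and σ is the
   population standard deviation. Slices with lesion voxels but no NAWM fall
   back to the global NAWM statistics; a volume with no NAWM anywhere is an
   error. All draws come from a single seeded generator, consumed in
   ascending slice order and row-major order within a slice, so a fill is
   fully determined by `(volume, masks, seed)`. Draws are not clipped;
   non-lesion voxels are bit-identical to the input.
4. **AR-FCM** on the filled volume, then boundary redistribution.

Each stage tags its exceptions with the stage name (`StageError`), so a
failure mid-pipeline is attributable.

The choice of half the NAWM standard deviation (rather than the full σ) keeps
filled lesions from re-creating intensity outliers inside WM while preserving
the slice mean.

## Evaluation metrics

Per class, treating segmentation and ground truth as binary masks:

- **DSC** = `200·|A∩B| / (|A|+|B|)` (reported ×100). If both masks are empty
  the structure was correctly found absent and DSC is 100.
- **VS** = `100·(1 − ||B|−|A|| / (|A|+|B|))`. Undefined (error) when both are
  empty.
- **HD95**: surfaces are the masks minus their 6-connected erosion (with the
  volume border counted as outside, so voxels touching the array edge are
  surface). Distances are Euclidean, computed by a distance transform with
  anisotropic physical spacing. HD95 is the 95th percentile — linear
  interpolation convention — of the *pooled* symmetric surface-to-surface
  distances.

`evaluate` returns a per-tissue table; a class absent from the ground truth
yields a NaN row, and a ground-truth class missed entirely by the
segmentation yields DSC = 0, VS = 0 and NaN HD95.

## Synthetic phantom

The phantom is an analytic 3-D head: nested ellipsoids (semi-axes 0.46× the
volume dimensions) partitioned by normalized radius into ventricular CSF
(≤ 0.17), WM (≤ 0.60), GM (≤ 0.83) and a peripheral CSF shell (≤ 1.0).
Channel means default to T1 = (0.15, 0.50, 0.80) and
FLAIR = (0.10, 0.60, 0.45) for (CSF, GM, WM). Spherical lesions are placed
inside the WM compartment (away from boundaries, mutually non-overlapping)
with the characteristic signature: T1 drops to the GM mean (0.50), FLAIR
rises to 0.90 — so an intensity-only method provably mislabels them as GM. A
smooth multiplicative bias field (separable cosines, amplitude `bias_amp`)
and i.i.d. Gaussian noise (σ = `noise_sigma`) corrupt both channels. The
probabilistic atlas is the Gaussian-smoothed (σ = 2 voxels) one-hot ground
truth, renormalized — deliberately aligned but soft, mimicking a registered
population atlas. Everything is driven by one seed; identical specs produce
bit-identical bundles.

What the phantom does *not* emulate: Rician noise statistics (noise is
Gaussian), partial-volume mixing at tissue interfaces (boundaries are hard
digitized ellipsoid surfaces), anatomical cortical folding, and registration
error between atlas and subject. Conclusions about fine boundary behavior
should be read with the digitization in mind.

The canonical validation suite is three bundles: a noise-free 48³ volume, a
noisy 48³ volume (σ = 0.08), and a lesioned 64³ volume (σ = 0.05, five
lesions of radius 2–4 voxels).

## Known limitations

- **RFCM smooths high-curvature boundaries.** On the [0, 1] intensity scale
  the maximum squared intensity distance between tissue classes is ≈ 0.42,
  while the default spatial weight is β = 1. Near digitized surfaces, a voxel
  whose 6-neighborhood majority belongs to another class can lower the total
  energy by flipping, regardless of its own intensity. This is a property of
  the energy, not the optimizer: on the noise-free phantom the fitted RFCM
  labeling has energy ≈ 3569 versus ≈ 9816 for the ground-truth labeling, so
  exact recovery is not the energy minimum. Consequences: RFCM does not
  perfectly recover even a noise-free phantom (per-tissue DSC ≈ 99.2–99.6),
  and on moderately noisy data it trades a small CSF Dice loss (thin,
  high-curvature structures) for GM/WM gains — its mean DSC exceeds FCM's,
  but not uniformly per tissue. Users segmenting thin structures should lower
  β.
- **One-hot tie-breaking** at (near-)zero cost deterministically prefers the
  lower class index; with `K` identical centroids this is arbitrary but
  reproducible.
- **SLF assumes slice-wise NAWM homogeneity**; strong within-slice bias
  fields violate this, and the global fallback for NAWM-free slices uses
  volume-wide statistics that may not match local intensity.
- **Lesion screening is intensity-thresholded**; FLAIR-hyperintense artifacts
  inside the GM∪WM region larger than `min_size` will be treated as lesion
  and filled.
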