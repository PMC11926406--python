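# Methods

This note records the models implemented by `golgiatlas`, the parameter
choices that matter, and the limitations a user should know before
trusting numbers on real data.

## Colocalization model

The degree of colocalization between two labeled proteins is the Pearson
correlation of their voxel intensities over a region of interest, computed
only on *signal* voxels. Signal is defined by the Costes automatic
threshold:

1. Fit the orthogonal regression (principal axis of the 2×2 intensity
   covariance) of channel B on channel A: `B ≈ slope·A + intercept`.
   Orthogonal rather than ordinary least squares because both channels
   carry noise. A non-positive covariance (anti-correlated channels) makes
   the construction meaningless and is reported as an explicit
   `negative-slope` error.
2. Scan a candidate threshold `t_a` over the occupied intensity levels of
   channel A, from the maximum downward, with `t_b = slope·t_a +
   intercept`. At each step, compute Pearson r of the below-threshold set
   `{A ≤ t_a and B ≤ t_b}`.
3. Accept the largest `t_a` whose below-set r is ≤ 0 with at least two
   distinct values in each channel. Everything above threshold is signal;
   the retained background is, by construction, statistically
   uncorrelated. If no crossing exists the thresholds fall to the
   channel-A minimum and the result is flagged `converged=False` (the
   whole ROI is then treated as signal).

Implementation detail: because both thresholds decrease together, the
below set shrinks monotonically along the scan. Each voxel is assigned the
threshold at which it enters the below set, voxels are sorted once by that
value, and the correlation at every candidate is computed from prefix
cumulative sums — an O(n log n) scan rather than O(levels × n). The
accepted candidate is re-verified with an exact two-pass correlation
before being returned.

Two voxel policies are exposed for the signal set of the final Pearson r:
the default union (`A > t_a` OR `B > t_b`), which keeps mutually
exclusive staining in the computation and therefore penalizes
non-colocalized pairs, and the intersection (`and`), reported in
provenance whenever used. The below-set of the Costes scan likewise
supports `and` (default) and `or`.

### nMDP and Icorr

For the colormap statistics the images are first segmented per channel by
Otsu or maximum-entropy (Kapur) thresholding; the foreground is the union
of the two channels' foregrounds (voxels strictly above threshold). With
means and maxima taken over that foreground,

    nMDP(x) = (A(x) − ā)(B(x) − b̄) / ((A_max − ā)(B_max − b̄))

`Icorr` is the fraction of foreground voxels with nMDP > 0, and
`Inega-corr = 1 − Icorr` holds exactly by construction. Means and maxima
are computed over the foreground only, so background does not dilute
them. The raw nMDP field is kept unclamped: values below −1 (and, for
pathological intensity distributions, above +1) are mathematically
possible; clamping to [−1, 1] is applied only when rendering a colormap.
On the right-skewed intensity distributions typical of fluorescence data
the raw field stays ≤ 1.

### Threshold selection

Otsu maximizes the between-class variance `ω0·ω1·(μ0−μ1)²`; maximum
entropy maximizes the sum of Shannon entropies of the renormalized
background and foreground histograms (with 0·log 0 ≡ 0). Integer images
get one histogram bin per integer level; float images default to 256
equal-width bins. Ties between equally optimal thresholds always break to
the lowest threshold. For integer histograms the Otsu criterion is
evaluated in exact integer arithmetic (the criterion is a ratio of
integers, compared by cross-multiplication), so the chosen level is never
an artifact of floating-point rounding.

## The atlas

Per-pair mean correlations r̄ become dissimilarities `d = 1 − r̄`
(averaging both orderings of a pair when both were measured). `d` lies in
[0, 2] but is *not* a metric — the triangle inequality can fail — which
metric MDS tolerates. An optional `self-control` normalization divides
r̄(X,Y) by √(r̄(X,X)·r̄(Y,Y)) (capped at 1) before forming distances, so
a pair cannot appear less colocalized than the dual-label noise ceiling
allows; it is off by default and recorded in output metadata either way,
since either convention is defensible.

The matrix is embedded in three dimensions by SMACOF stress majorization:
raw stress `Σ_{i<j} (d_ij − δ_ij)²`, Guttman-transform updates (stress is
non-increasing by construction and asserted per iteration), convergence
when the per-iteration stress decrease falls below 1e-12 or after 3000
iterations, 8 restarts from seeded random starts keeping the lowest
stress. The tight convergence tolerance costs little at these problem
sizes (tens of points) and makes degenerate configurations — e.g. two
enzymes at zero distance — collapse to numerically coincident points.
The 3D configuration is centered and projected onto its top two principal
components (eigen-decomposition of the 3×3 covariance, each component's
largest-magnitude loading forced positive for a deterministic sign).
Orientation of the atlas is arbitrary up to rigid motion; all tests
compare geometry modulo that invariance.

## Group statistics

Per-pair summaries are mean, sample SD (n−1 denominator) and SEM =
SD/√n over cells (SEM flagged undefined at n = 1). Many-to-one
comparisons against a control pair use classic equal-variance Dunnett:
pooled within-group variance across all groups, two-sided family-wise
adjusted p from the joint multivariate t distribution of the contrasts
(numerically integrated; accuracy ~±0.002, so the k = 1 case reproduces
the pooled two-sample t-test). The Welch-type variant is out of scope.
Two-group comparisons use the two-sided pooled-variance unpaired t-test.
Significance stars follow */**/***/**** at 0.05/0.01/0.001/0.0001.

## Synthetic scenes

The simulator emulates the statistical structure of dual-color 3D
confocal acquisitions of a Golgi ribbon, not their optics:

- **Geometry.** The ribbon is a chain of `n_ministacks` (default 10)
  ministacks placed at equal arc length along a gently S-curved polyline
  spanning ~55% of the lateral field, with per-stack center jitter
  (σ = 0.15 µm) and a local cis→trans axis tilted from the optical z-axis
  by up to 12° at random azimuth. Both channels of a cell share every
  geometry draw.
- **Enzyme density.** Per ministack, an enzyme contributes a Gaussian
  blob: lateral σ = `stack_radius` (default 0.5 µm) perpendicular to the
  local axis, axial σ = `axial_sigma` (default 0.15 µm) along it, centered
  `axial_mu` µm from the stack center along the axis. `axial_mu` is the
  ground truth the pipeline is asked to recover.
- **Optics and noise.** The density is convolved with an anisotropic
  Gaussian PSF, default (σz, σxy) = (0.3, 0.1) µm — plausible for a
  high-NA spinning-disk system — scaled by `brightness` (default 150
  counts), offset by a background of 4 counts, then subjected to Poisson
  shot noise and additive Gaussian read noise (σ = 2 counts), clamped at
  zero: the standard EM-CCD forward model. Noise draws are independent
  between channels.
- **Sampling.** Default grid 64×256×256 voxels at (0.2, 0.1, 0.1) µm —
  0.2-µm optical sectioning over a ~13-µm axial range, matching the
  acquisition geometry the pipeline targets. A scene whose noiseless
  density leaks more than 1% of its mass into a 3·PSF border margin is
  rejected as under-sized.
- **Seeding.** `SceneConfig.seed` fixes every draw via three spawned
  SeedSequence streams (geometry, channel-0 noise, channel-1 noise).
  Panels derive per-scene seeds from `SeedSequence([base_seed,
  pair_index, cell_index])`, so any single cell is reproducible in
  isolation. Panels include self-pairs — the same enzyme profile imaged
  in both channels with independent noise — as dual-label controls.

What the simulator does **not** model: deconvolution, pinhole crosstalk,
photobleaching, drift, cytosolic background structure, or enzyme-specific
expression variability. No signal-to-noise statistics were available to
fit the noise defaults; they are asserted as plausible, not estimated.
Passing tests on these scenes demonstrate that the measurement machinery
recovers known ground truth under a realistic noise model — not that any
particular biological dataset meets the model's assumptions.

## Problem sizes used in the automated checks

Panel-scale tests and the acceptance script run on a reduced 32×64×64
grid (same voxel size, 6 ministacks): large enough to contain the ribbon
plus the PSF margin, small enough that the full six-enzyme, 21-pair,
8-cells-per-pair atlas-recovery experiment (repeated over 20 base seeds)
completes in minutes on a single CPU. The offset-decay and control-ceiling
checks reuse matched per-cell seeds across offsets, so offset is the only
systematic difference between conditions. The Dunnett null calibration
uses 5 groups of n = 10 over 2000 replicates (500 in the acceptance
script).

## Known limitations

- The Costes scan steps over the occupied intensity levels of channel A;
  for float images every distinct value is a level. This is deterministic
  and resolution-independent but can be slow on extremely large float
  volumes.
- `d = 1 − r` is not Euclidean; MDS stress is generally nonzero and the
  atlas is a least-stress compromise, not an exact map.
- Dunnett assumes equal group variances; strongly heteroscedastic r
  distributions across pairs would call for a Welch-type procedure that
  this package does not provide.
- Line profiles use trilinear interpolation on the voxel grid; they do
  not resample below the optical resolution.
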