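# Methods

This note documents the models, conventions and numerical choices behind
`choroquant`, and what the synthetic validation does and does not show.

## Coordinate and slab conventions

Volumes are indexed `(y, x, z)` with `z = 0` on the vitreous side,
0-based indices, and physical position = index × spacing.  Surfaces are
real-valued depth grids (fractional voxels allowed).  The choroidal slab
of an A-scan is the **half-open** voxel range `[round(bm), round(csi))`
with round-half-up, so voxel counts are integers, adjacent slabs never
share a voxel, and the CVI is an exact pixel-count ratio.  An exact
identity follows and is asserted in the tests: the pooled vessel
fraction equals the slab-count-weighted mean of the per-A-scan CVI map.

Surface depths use an *edge-centre* convention: an intensity step
between voxels `k−1` and `k` is reported as `k − 0.5`, which rounds to
the first voxel of the lower layer.  Because both BM and CSI carry the
same −0.5-voxel offset relative to the rounded class boundaries, the
offsets cancel in thickness; measured regional thickness is unbiased to
about 1 µm at the default 3.9 µm axial spacing.

## Attenuation compensation

`corrected(z) = I(z)^n / (2 Σ_{z'≥z} I(z')^n + ε)`, per A-scan, with
contrast exponent `n = 2` and `ε = 1e−8 · max(I)^n` (scale-invariant
stabilizer; all-zero tails map to 0).  Two properties matter here:

- a *multiplicative* shadow acting on the whole tail of an A-scan
  cancels out of the ratio — this is what suppresses shadowing from
  overlying exudation or pigment epithelial detachments;
- tails are nonincreasing in depth, so of two voxels with equal raw
  intensity the deeper one is never dimmer after compensation — this is
  what enhances the choroidal–scleral contrast.

The exponent is exposed as a parameter (`attenuation.exponent_n`)
rather than fixed; the variant used by any particular device pipeline
differs in normalization details.

## Surface segmentation

Each surface is a per-B-scan minimum-cost path (Viterbi dynamic
program) through a cost image: the signed axial derivative of the
smoothed intensity (`bright_to_dark` selects falling edges).  Column-
to-column moves are limited to `max_step = 2` voxels; ties break toward
smaller depth; a parabolic fit around the integer optimum gives
sub-voxel precision; a 3-point median filter across B-scans enforces
3-D coherence.  The DP is exact: on small grids it matches exhaustive
path enumeration in the tests.

Smoothing before differentiation uses an anisotropic Gaussian: σ = 1.5
voxels axially *and laterally*.  The lateral smoothing is load-bearing:
individual vessels are only one or two A-scans wide at the 187.5 µm
desk-scale spacing, so their (strong) edges average away while the
laterally coherent layer boundary survives.  Without it the CSI path
locks onto vessel walls.

BM is searched in a ±10-voxel band around the brightest axial
reflection (the RPE, located by argmax of a heavily smoothed volume);
CSI is searched on the compensated volume in a band from BM + 20 µm to
BM + 600 µm.  The 20 µm minimum reflects the thinnest plausible
choroid; a consequence is that a truly zero-thickness choroid is
reported at ~the band minimum rather than zero (a `SurfaceSet` with
`bm ≡ csi` is still valid input everywhere downstream and yields a zero
thickness map).  `csi ≥ bm` is enforced by clamping; if more than 5% of
A-scans need clamping the segmentation errors out rather than
returning silently bad surfaces.

## Vessel binarization

Otsu's threshold is computed over a 256-bin histogram with exact
integer arithmetic on bin indices (the between-class-variance ranking
is affine-invariant, and float round-off otherwise flips near-ties),
ties toward the lower threshold.  The histogram is built from *slab
voxels only* — the choroid of that eye-visit — not the whole volume.

The pipeline thresholds the **logarithmic (dB-like) scale** of the
compensated intensity, optionally despeckled with an axial Gaussian
(σ = 2 voxels, `despeckle_sigma_z`).  Rationale: OCT speckle is
multiplicative, so it is additive and symmetric on the log scale; and
the compensated intensity carries a residual common depth factor that
is also multiplicative, so on the log scale the vessel and stroma
classes stay parallel with comparable spreads — the regime where a
variance-based threshold lands in the gap.  On the linear scale the
right-skewed stroma distribution pulls the Otsu threshold into the
stroma and the CVI is overestimated by ~0.2.

## Registration

Rigid model (translation + rotation about the image centre); the
day-of-exudation visit is the reference frame, since every eye has it.
For each candidate rotation on a grid (±5°, step 0.25°) the de-rotated
moving image is aligned by subpixel phase correlation (upsampling 20),
and the candidate with the best normalized cross-correlation of the
re-aligned overlap wins.  Inputs are en face retinal projections
(mean intensity above BM), whose vessel shadows are stable landmarks
across visits.  No scaling degree of freedom is fitted by default
(axial-length magnification differences are out of scope); maps warp
with bilinear interpolation, masks with nearest-neighbour, and
out-of-bounds pixels become missing/False.  Accuracy on phantoms:
median errors ≈ 0.05 px and 0.08° over seeded trials.

## Regions, exclusions, eligibility

"5-mm" and "11-mm" circles are *diameters* (an 11-mm radius cannot fit
a 12-mm scan, and the 6-mm-wide rim matches the diameter difference).
Pixel-centre inclusion, Euclidean distance in physical units, no
partial-pixel weighting — consistent with the integer pixel-ratio
arithmetic elsewhere; the area-weighted identity
`mean₁₁ = (n₅·mean₅ + n_rim·mean_rim)/(n₅+n_rim)` then holds exactly.
Exclusion masks drawn at any visit are warped to the reference frame
and their union removed from **all** visits, so the same area is
compared longitudinally.  An eye is CVI-ineligible only when *more
than* 10% of the 5-mm circle is excluded (exactly 10% stays eligible).
The regional CVI reported is the unweighted mean of the per-A-scan CVI
map; the pooled voxel ratio is also computable (`global_cvi`).

## Longitudinal statistics

Visit comparisons are run as change-score regressions on per-eye
paired differences (matching the increase/decrease/change structure of
the study tables), not as visit-by-visit mixed models.  Inference uses
the cluster-robust sandwich clustered on patient with the CR1
small-sample factor `G/(G−1)·(N−1)/(N−k)` and a t reference with
`G − 1` degrees of freedom; CR0 is available, and with singleton
clusters CR0 reduces exactly to HC0.  The mean-change test is an
intercept-only fit; the MNV-type contrast (types 1/2, which arise from
the choroid, versus type 3, which arises from the retina) is the
indicator coefficient in an intercept + indicator fit.  The
"decrease" tables report the positive decrease `from − to`.  Coverage
of the 95% CI under the simulated cohort (37 patient clusters,
fellow-eye correlation) is 0.94–0.95 over 2000 replicates, inside the
[0.92, 0.98] Monte-Carlo band.

## The synthetic phantom

The phantom emulates a 12 × 12-mm posterior-pole scan: smooth
band-limited random BM-depth and thickness fields; retina and a bright
RPE band above BM; a choroidal slab filled with hyporeflective vessel
tubes (intensity 60 vs stroma 180 on an 8-bit-like scale) that follow
the slab curvature at random in-plane orientations, placed until the
global vessel fraction is within ±0.01 of target (the loop aims at the
band centre); dark retinal-vessel lines in the inner retina that cast
shadows and serve as registration landmarks; per-tissue Beer–Lambert
extinction along each A-scan; optional focal shadow discs; and
multiplicative gamma speckle (shape 4, mean 1) applied after ground
truth is recorded.

Default desk-scale grid: 64 × 64 × 256 voxels covering the full 12-mm
field of view (lateral spacing 187.5 µm) with 3.9 µm axial spacing —
chosen so the whole validation suite runs in minutes on one CPU.  The
full device geometry (500 × 500 A-scans at 24 µm, 1536 axial samples at
1.95 µm) is available via `PhantomParams.full_scale()` and the CLI
`--full-scale` flag.

Extinction coefficients default to the weak-extinction regime
(~0.001/µm in the slab).  This is a deliberate modelling choice: under
strong extinction the compensation denominator is dominated by the few
voxels immediately below each voxel, so a stroma voxel sitting on top
of a large vessel is boosted ninefold relative to one above stroma and
the class histogram smears; under weak extinction the tail is a smooth
per-depth factor shared by both classes.  Real devices sit between the
regimes; the coefficients are parameters.

Longitudinal series share one baseline anatomy: per visit, the
thickness field gets an additive offset and the vessel-fraction target
an additive change, the continuous fields are warped by the programmed
rigid transform (recorded exactly in the truth), and speckle is redrawn
from a per-visit substream while the vessel-placement substream is
reused so the vascular pattern persists across visits.

### What the phantom does *not* show

It is not an optically rigorous OCT simulation (no interferometry, PSF,
rolloff, or motion artifacts), has no MNV lesion morphology, models
vessels as tubes rather than a branching plexus, and uses piecewise-
constant tissue reflectivities.  Passing the phantom tests demonstrates
the internal consistency and accuracy of the measurement chain under
controlled conditions, not performance on clinical scans.

### Known accuracy limits

- Regional (5-mm circle) thickness is recovered to ≤ 1.3 µm and
  regional CVI to ≤ 0.02 of truth under full speckle.
- Per-A-scan CVI has an irreducible error floor under shape-4 speckle:
  ~9% of slab voxels lie within the despeckle blur of a vessel
  boundary, so only ~45% of A-scans are within ±0.05 of truth (97%
  noiseless).  Regional and global CVI are unaffected because boundary
  errors largely cancel in aggregation.

## The simulated cohort

`generate_cohort` simulates the measurement table directly: per-eye
values = baseline + patient effect + eye effect + cumulative visit
shift + visit residual, all Gaussian.  Defaults emulate the study
population: 37 patients, fellow-eye probability 4/37 (≈ 41 eyes), MNV
type probabilities 24:4:13, 5-mm baseline thickness 200.7 µm with SD
split 62/25/16.1 µm (patient/eye/residual — giving a cross-sectional SD
≈ 69 µm and a paired-change SD ≈ 23 µm), programmed +12.7 µm at
exudation and −19.5 µm after therapy; CVI analogues 0.617 baseline,
0.032/0.012/0.0163 SDs, +0.014/−0.017 shifts.  The cohort generator
shares no code path with the estimators it is used to test.

## Problem sizes used in validation

Phantom tests use the 64 × 64 × 256 grid; the coverage experiment uses
2000 cohorts of ~41 eyes; registration recovery uses 20 seeded trials;
the Otsu and sandwich oracles use 100 histograms and 50 random designs.
These sizes were chosen as the smallest at which the Monte-Carlo bands
quoted above are meaningful.
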