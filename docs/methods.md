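# Methods

## The measurement problem

An in-shell walnut imaged by X-ray CT shows three compartments with
distinct attenuation: the dense shell, the kernel, and the air-filled
empty space between them. A batch scan adds two more populations — the
air around the sample and the low-attenuation foam holder. The package's
job is to go from such a greyscale volume `I(z, y, x)` on an isotropic
grid (voxel edge in mm) to fourteen per-nut descriptors, excluding any
nut whose shell is damaged, and then to the usual dataset-level
statistics.

Two facts shape the design:

* **Cavity air and exterior air are the same grey.** "Empty space" can
  therefore never be identified by intensity; it is defined geometrically
  as the region enclosed by the shell. This is also why a breached shell
  must disqualify a nut: without enclosure, shell and cavity are not
  measurable.
* **Derived shape indices are brutally sensitive to surface-area bias.**
  Sphericity Ψ = π^(1/3)(6Vn)^(2/3)/A, rugosity Ω = 1/Ψ and the shape
  factor S1 = Ω³ all hinge on A. Counting exposed voxel faces
  overestimates a sphere's area by roughly 50% (the staircase never
  converges), which would push Ψ far below any plausible walnut value;
  a mesh-based estimator is mandatory.

## Pipeline stages and their numerical choices

**Preprocessing.** Gaussian denoising with `gaussian_sigma_mm = 0.05`
(default): sub-voxel at the native 0.1 mm resolution, enough to tame
pixel noise without displacing the threshold crossing at material
boundaries — a heavier blur visibly inflates the foreground mask at
shell/air interfaces. The foreground threshold τ is the midpoint between
the foam and kernel intensity populations found by histogram clustering;
the mask keeps strictly-above-τ voxels, is opened and closed with a
1-voxel ball, and loses connected components below `min_spot_mm3 =
100 mm³` — two orders of magnitude below any real nut (collection
minimum ≈ 10,000 mm³), so only debris can be removed.

**Histogram clustering.** One-dimensional k-means (Lloyd) on the voxel
intensities, initialised from the multi-Otsu thresholds of the histogram.
The initialisation matters: air outnumbers nut material by orders of
magnitude, and quantile-based starts collapse all centers into the air
mode. Multi-Otsu initialisation plus Lloyd refinement recovers the
generating levels exactly on noise-free data and within 2% under 5%
noise, deterministically (no random restarts). Cluster ranges are the
midpoints between adjacent centers; the whole segmentation is therefore
invariant under affine intensity rescaling.

**Part segmentation.** Shell = top intensity cluster, sealed with a
6-connected closing and reduced to its largest connected component. An
opening is deliberately *not* applied to the shell: at coarse working
resolutions the wall is only 2–3 voxels thick and an opening erodes
through it, fabricating the very breach the QC step is meant to detect
(isolated bright specks are removed by the largest-component rule
instead). Interior = hole-filling of the shell; kernel vs internal air
inside the interior is decided by a marker-based watershed on the
Gaussian gradient magnitude (σ = 1 voxel), seeded from the central half
of the kernel and air cluster ranges. Shell ∪ kernel ∪ empty is the nut
foreground by construction, so Vn = Vs + Vk + Ve holds exactly.

**Shell QC.** A nut fails if the shell is fragmented, encloses nothing,
or if kernel/empty voxels lie outside the enclosed interior (equivalent
to interior air reaching the volume border through non-shell voxels).
Failed nuts produce no trait values and are listed with a reason in the
run report.

**Individualization.** Connected components (default 26-connectivity,
configurable) numbered in raster order of each component's first voxel —
deterministic across runs and platforms. The optional `split_touching`
watershed acts only on components whose distance transform has at least
two maxima above half the global maximum separated by more than
`min_seed_distance_mm` (default 10 mm); it is opt-in because a foam
holder normally separates nuts and an aggressive splitter would shatter
hollow, bumpy singletons. Crops mask everything outside the owner
label's mask, dilated by 3 voxels — the dilation restores true boundary
voxels shaved off by the morphological cleaning, which would otherwise
punch pinholes into the shell and wrongly fail QC.

**Traits.**
* L, F, P: extents along the second-moment principal axes (max − min
  projection of voxel centres + 1 voxel). The suture plane cannot be
  recovered from geometry alone, so assigning "face" vs "profile" to the
  2nd vs 3rd axis is a convention, exposed via `swap_face_profile`.
* A: marching cubes on the indicator smoothed with σ = 1 voxel,
  contoured at 0.5 — ≈ 0.2% error on digitised spheres at working
  resolutions (raw marching cubes on the hard indicator carries a few
  percent of staircase bias, face counting ~50%).
* Feret S2: caliper widths of the convex-hull vertices over 2000
  Fibonacci-lattice directions on the half sphere, with three rounds of
  local cap refinement around the minimum; D is the maximum width over
  720 in-plane directions orthogonal to d's direction. The brute-force
  oracle uses 20,000 directions with no refinement; doubling the
  direction count moves S2 by < 0.5%.
* T: mean local thickness by the inscribed-sphere rule. For closed
  shells the inscribed-sphere diameter through a wall voxel equals the
  wall-normal span, computed as the sum of two distance transforms
  (to the exterior and to the enclosed cavity) minus half a voxel — the
  half-voxel term removes the centre-to-centre overshoot of the EDT at
  digitised surfaces, calibrated on analytic annuli (≤ 0.6% error for
  1 mm walls at 0.1 mm voxels, ~15% worst case at the 0.73 mm thin end).
* Ψ, Ω, S1 are all evaluated from the same (Vn, A) pair, so Ψ·Ω = 1 and
  S1 = Ω³ hold to machine precision on every measured nut and are
  asserted on every run.

## The phantom generator

The generator emulates the study conditions of a walnut batch scan:
several nut-like objects embedded in foam, four greyscale populations
(air 10 < foam 40 < kernel 110 < shell 200 by default), additive
Gaussian noise (σ = 5, i.e. ~2.5% of the shell–air contrast), 5–16 nuts
per scan with 12 as the typical batch.

Geometry is analytic. The outer surface is a base ellipsoid whose radius
is modulated by a seeded band-limited angular field (a spherical-harmonic
mixture of degrees 2–4, tabulated once on a 256×512 (θ, φ) grid and
bilinearly interpolated, so the same nut digitises identically at any
resolution). The shell is an inward radial offset; the kernel is two
ellipsoidal lobes, deliberately oversized and clipped to the cavity so
the kernel touches the shell wall — a real kernel does, and a floating
kernel would make a nut two connected components and break labelling.
The lobe scale is solved by bisection so the filling ratio hits its
target within ±1 percentage point (reachable for targets ≳15%; the
realistic range is 21–37%). Cavity air is rendered at exterior-air grey
on purpose: it forces enclosure-based, not intensity-based, empty-space
detection.

Defaults use outer semi-axes 8.5 × 7.2 × 7.4 mm — real-walnut aspect
ratios at a reduced size, so that a nut at the scanner's native 0.1 mm
voxels fits a ≈ 200³ working grid. Absolute sizes only rescale the
volumetric traits; the dimensionless indices (Ψ, Ω, S1, S2, R) are
scale-invariant (verified within 1% discretisation tolerance), so
recovery conclusions carry to full-size nuts. Shell thickness (1.0 mm)
and filling target (0.30) match the middle of the published collection
ranges (0.73–1.49 mm; 21–37%).

Ground truth: spheres carry closed-form trait values; general nuts are
re-digitised at ≥ 2× finer resolution and measured by the brute-force
oracle (voxel counting, fine-grid meshing, 20,000-direction Feret
search, inscribed-sphere thickness). `damage_shell` drills an
air-intensity channel from the cavity through the shell; a voxel joins
the channel only if its whole footprint is inside the cylinder, so a
sub-voxel hole changes nothing — matching the physical fact that damage
below the scanner's resolution is undetectable.

What the phantoms do *not* emulate: partial-volume blur at interfaces,
beam hardening, ring artefacts, kernel internal anatomy (halves,
pellicle), or shrivelled kernels detached from the wall. Passing the
recovery suite therefore demonstrates correctness of the geometry and
measurement chain under realistic noise and class imbalance, not
robustness to reconstruction artefacts; on real scans the histogram
clustering and QC stages are the components most exposed to those
effects.

## Statistics

Descriptive statistics, Pearson correlations and PCA operate on per-nut
rows (not accession means); rankings aggregate to accession level.
Sample (n−1) standard deviations throughout. Correlation p-values are
two-sided from the t-distribution with n−2 degrees of freedom, reported
raw (a Bonferroni option exists but is off by default, matching common
practice for exploratory trait matrices). PCA standardises traits to
unit variance, fixes each component's sign so its largest-magnitude
loading is positive, and reports explained-variance percentages (summing
to 100) plus per-individual squared cosines as representation quality.

## Known limitations

* Face vs profile assignment is a convention; without a suture detector
  the two transverse diameters can be swapped relative to manual
  measurements.
* Shell thickness at the thin end (≈ 0.7 mm) sits near the resolution
  floor at 0.1 mm voxels; errors up to ~15% are expected there and
  halve with each resolution doubling.
* The Feret shape S2 is ill-conditioned for near-round nuts: when the
  caliper-width landscape is flat to ~0.1%, voxel-level perturbations
  flip which direction attains the minimum, and the orthogonal maximum D
  can move by several percent even though d barely changes. Within the
  elongation range of real walnuts (S2 ≈ 1.12–1.48) the minimum is
  well-separated and S2 is stable to ~1–2%.
* The touching-nut splitter assumes fused *solid-ish* bodies with
  separated distance-transform maxima; heavily interlocked hollow shells
  are out of scope.
* Anisotropic voxel spacing is rejected, not resampled.
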