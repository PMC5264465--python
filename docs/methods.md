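# Methods

This note records the models, parameter choices and numerical decisions
behind `phasevasc`, and what the synthetic experiments do and do not show
about real specimens.

## Specimen model

A specimen is a voxel grid (isotropic, 9 µm default; axes z = rotation axis,
y, x) with five material labels: background air, liver, tumor, vessel lumen
and suture. Optical constants at the 15 keV reference energy are a built-in
table of order-of-magnitude realistic values — water-like soft tissue
(δ ≈ 1.05·10⁻⁶, β ≈ 1.15·10⁻⁹ for liver; the tumor slightly denser), ethanol
for the vessel lumen (δ ≈ 0.80·10⁻⁶, β ≈ 0.66·10⁻⁹; fixed, dehydrated
specimens carry ethanol in the vasculature, which is the only source of
vessel contrast without a contrast agent), and a dense polymer suture whose
absorption is boosted by a configurable multiplier (default 30×) so it casts
the characteristic opaque shadow. Across energies δ scales with E⁻²
(electron-density scattering) and β with E⁻⁴ (photoelectric regime, valid
for soft tissue below ~30 keV; the table is not meant for the hard end of
the beamline range). All values are configurable.

### Vessel trees

Vasculature grows by stochastic recursive bifurcation: each segment extends
from its parent node with a jittered direction and a length proportional to
its radius, then splits into two children carrying `radius_ratio` times the
parent radius (deterministically, so *g* generations taper the root caliber
by `ratio**g`). Normal liver uses regular dichotomous branching (root 90 µm,
ratio 0.8, mild tortuosity); tumor neovasculature uses wider branch angles,
strong per-segment sinusoidal tortuosity, glomeruloid *cluster motifs*
(bursts of short curled twigs from one node), and slender feeders — the
feeder radius adapts to the tumor size but never falls below 18 µm, the
caliber of co-opted host vessels. Segment centerlines are deterministic in
(tree seed, segment index), so identical spec + seed gives bit-identical
phantoms.

### Hitting density targets exactly

The rasterizer paints segments thick-to-thin and stops when the vessel voxel
count inside the region reaches the target (density × region voxels),
truncating the last segment chord-by-chord. Ground truth is therefore exact
bookkeeping: density = 100 × vessel ∩ tumor / tumor voxels. Each phantom
reports a discretization bound (the |analytic − voxelized|/analytic volume
mismatch of the painted segments plus the one-segment granularity), and the
achieved density matches the target within that bound.

### The staged series

`stage_series` produces weeks 1–4 with tumor volumes in the printed growth
ratios (1 : 7.4 : 34.2 : 108.2), vascular density rising to its week-2 peak
(3.51, 4.29, 2.62, 1.52%) and the avascular (necrotic) fraction growing late
(0, 0.03, 0.15, 0.30). Absolute tumor volumes up to ~400 mm³ cannot be
voxelized at 9 µm in a desk-scale grid, so the week-4 tumor is scaled to 14%
of the domain volume and the other weeks follow the ratios; densities are
dimensionless and are used unscaled. The 14% ceiling is a fidelity choice,
not merely a budget one: it keeps even the largest tumor's boundary more
than ~15 voxels away from the specimen/air interface, as in the real
specimens where tumors were embedded in liver with a visible parenchyma
margin. The suture defaults to an implantation-site pose — a 40 µm-radius
rod lying tangentially at the tumor margin.

## Imaging model

Parallel-beam illumination (the source sits ~34 m upstream, the detector at
most a few meters downstream, so magnification ≈ 1 and source blur is
neglected). Line integrals of δ and β are computed by a bilinear-interpolation
projector; the exit wave exp(iφ − A/2) is propagated with the paraxial
Fresnel transfer function applied to the full 2D wave of each projection
(edge enhancement acts along both detector axes). At zero distance the model
returns exp(−A) exactly. Poisson noise is applied per pixel with mean
photons × intensity; the photon proxy defaults to 10⁴ (the flux was never
published; this level puts ~1% noise on each projection pixel). Detector
gain errors are modeled as per-column multipliers recorded in the sinogram's
gain profile; a constant-column error back-projects into a ring at the
column's distance from the rotation center.

Reconstruction is standard FBP: band-limited ramp filter (exact real-space
kernel, so no DC bias; Shepp-Logan and Hann windows available) and linear
interpolation in the back projection, rotation center at the detector
midpoint with a configurable offset. Both projector and back projector are
numba kernels whose inner loop runs over slices, which keeps a full
128³ / 400-view scan-plus-reconstruction under ~10 s on one core; they are
cross-checked in the tests against `skimage.transform.radon`/`iradon` and
against analytic disk oracles. The edge-enhanced intensity is reconstructed
directly (no phase retrieval), as the beamline software did; the fringes
therefore survive into the gray values, which is both the signal exploited
by the contrast analyses and a known artifact source for thresholding.

## Contrast statistics

"Either side of the vessel wall" is operationalized as the extrema of the
profile within a configurable half-width (default 10 px) around its
steepest-gradient point; an optional 256-level quantization mode replicates
analysis on 8-bit exports. The local-contrast map is exactly the windowed
coefficient of variation (default window 15 px — the window size was never
published), computed with reflective boundaries via uniform filters and
verified against a brute-force double loop to 10⁻¹⁰; excluded (suture)
pixels are left out of the window moments.

## Vessel extraction and calibers

Vessels are *dark* in these reconstructions (ethanol lumen, lower µ than
tissue), so masks are `gray < threshold`. Three threshold modes exist:

- **otsu** — the classic two-class choice. On edge-enhanced reconstructions
  with a 2–4% vessel fraction it fails structurally: the histogram is a
  unimodal tissue mode with a small dark tail, and Otsu splits the mode
  (measured: ~50% recovered density against ~4% truth). It is retained
  because it is correct on genuinely bimodal data and is the method used in
  the detection-limit experiment, where it performs well.
- **robust** (pipeline default) — median − k·MAD (k = 3.5) of the domain
  grays, a noise-calibrated dark-tail cut that is insensitive to the vessel
  fraction. It is applied to a vessel-enhanced volume: Gaussian smoothing
  (σ = 1 voxel) damps the oscillatory fringes, leaving the net absorption
  deficit of the lumen, and subtracting a broad background (σ = 6) removes
  the low-frequency bands printed by the specimen-edge fringe. The deep
  k = 3.5 cut also counteracts the partial-volume fattening of thin tubes.
- **fixed** — reproducibility mode.

Components under 8 voxels (26-connectivity) are discarded as specks. For
large tumors (equivalent radius ≥ 15 voxels) the counting domain is the
tumor outline eroded by 2 voxels — emulating the conservative manual outline
an analyst draws to keep clear of boundary fringes and peritumoral liver
vessels — while the density denominator remains the full tumor volume.

Caliber is medial-axis local thickness: the Euclidean distance transform
gives the inscribed-sphere radius at every voxel, each sphere stamps its
diameter onto the voxels it covers, and a voxel's thickness is the largest
stamp (the maximal-inscribed-sphere definition; the volume border counts as
background). Per-component calibers are medians over skeleton voxels with a
−1 voxel digitization offset, so a one-voxel line reads 9 µm and a radius-2
digital rod ~4 voxels. Diameters at or below two voxels are flagged as
sub-resolution. Histogram bins are one voxel (9 µm) wide so the 27–54 µm
band maps to bins 3–6. Both the per-segment (primary) and per-voxel minimum
are reported.

## Week-series statistics

Summaries are mean ± SD per week over replicates. Trends are ordinary least
squares of each metric on week, fitted on per-replicate values (the original
analysis does not state whether replicates or means were used); r is the
Pearson correlation with a two-sided slope test. The published regression
coefficients for the real specimens are not reproducible from printed means
alone and are not targeted.

## What the synthetic experiments show — and what they do not

The phantoms validate the *chain*: with known truth, the simulation
demonstrates quantitative density recovery (within 15% relative per week at
128³, 400 views, 10⁴ photons, three seeds, preserving the rise-to-week-2
trajectory), a detection limit at the voxel scale for the cylinder battery,
the near-field contrast orderings over energy and distance, and the
ring-artifact threshold confound. They do not model real tissue
heterogeneity (parenchyma texture, necrosis contrast, partial fixation),
polychromaticity, partial coherence, detector PSF beyond pixel integration,
or phase retrieval; real-specimen thresholds will not transfer numerically.
Two desk-scale simplifications matter: the suture is excluded from the
density-recovery experiment (at 128³ it subtends a far larger fraction of
the tumor than a real suture does of a mm-scale tumor, and its fringe/streak
systematics would measure the scale compression rather than the method — its
effects are demonstrated separately in the projection-correction and
ring-confound analyses), and an interesting property of direct edge-enhanced
reconstruction surfaces in the battery: large lumina (≥ 6 voxels) are
recovered only partially because their interiors return to tissue gray,
while 1–3 voxel vessels are fully dark — small-caliber sensitivity is a
genuine strength of the technique, interior fill of large vessels is not.

## Problem sizes

Default experiment sizes were chosen so the full validation runs on a single
core in minutes: 128³ voxel phantoms with 400 projections for the recovery
and detection-limit experiments, 64³ with 120 projections for smoke tests
and examples, 1200 views only where view-count convergence itself is under
test. The acquisition default of 1200 projections over 180° (0.15° steps)
matches the emulated beamline protocol and is used when no experiment
overrides it.
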