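# Methods

This note records the models behind each pipeline, the parameters that
matter, what the phantoms do and do not emulate, and the numerical choices
made where the design was genuinely open.

## OCT corneal geometry

**Model.** A volume is indexed (frame, axial px, lateral px) with axial
position 0 at the top of the image, increasing downward. Depths are
optical-path pixels: the axial scale in air (default 2.66 μm/px) applies
above the anterior surface; inside tissue the effective scale is divided by
the refractive index (default n = 1.4). Thickness is measured along the
axial direction at the apex — no surface-normal correction is applied,
matching how a pixel count between boundaries is read off a B-scan. The
anterior radius of curvature uses the sagitta construction with h = 300 μm
(R = w²/8h + h/2), which is exact for a circle at any h ∈ (0, 2R].

**Procedure and defaults.**
- ~10 central frames are averaged (speckle is uncorrelated between frames).
- Per column, the anterior boundary is the first intensity peak from the
  top with prominence ≥ 20% of the column maximum; the posterior boundary
  is the next such peak. Both are refined by a 3-point parabolic fit.
  Whether the posterior peak is the endothelial band or the posterior
  stromal edge is not decidable from intensity alone; the choice
  ("strongest peak below anterior") is recorded in the QC output.
- The apex is the minimum of the anterior trace after an 11-column moving
  average, ties broken toward the image center. Chord endpoints at depth h
  are linearly interpolated between bracketing columns.
- Thickness is the median anterior→posterior span over 11 columns centered
  on the apex — the median suppresses residual speckle-driven outliers
  without biasing the estimate.

**A-scan reconstruction.** The minimal spectral-domain chain is included:
resample the spectrum from its wavelength grid to uniform wavenumber,
subtract the mean, apply a Hann window, FFT. A reflector at optical depth z
produces a fringe cos(2kz), so depth bin m maps to z = mπ/(NΔk). The
source model is a Gaussian envelope at 1040 nm with 70 nm bandwidth.

## SAXS interfibrillar spacing

**Geometry.** The exact mapping q = (4π/λ)·sin(½·arctan(r·pitch/L)) is used
rather than the small-angle form; at λ = 0.1 nm and L = 6 m they agree to
<1e-4 relative over the corneal q-range, but the exact form costs nothing
and stays correct for other cameras.

**Beam centering.** The center minimizes the azimuthal variance of the
first calibrant ring's radius (36 sectors, intensity-weighted radius per
sector), by coordinate descent with steps shrinking from 2 px to 0.05 px.
The ring is identified as the most prominent *local* maximum of the radial
profile — the diffuse background is monotone in r and can exceed the ring
near the beamstop, so a global maximum would find the wrong feature.

**Calibration.** Orders m = 1..3 of the tendon D-period (67 nm) are located
to sub-pixel precision and the q-per-pixel scale k fitted through the
origin by least squares. Calibration replaces the geometric mapping
entirely, which is why a 5% error in the recorded detector distance leaves
the recovered spacing unchanged (the distance only positions the search
windows). Silver behenate (d(001) = 5.838 nm, the community value) is
supported for centering/calibration at wider angles.

**Background and peak.** The background model is A·q^(−b), fitted by
ordinary least squares in log–log space. Peak location runs in two passes:
a provisional fit on the flanks of the search window gives a first peak
estimate (steep backgrounds can bury the reflection in the raw profile),
then the background is refitted on the sidebands [0.5, 0.8]·q_peak and
[1.3, 2.0]·q_peak and the highest local maximum relocated with parabolic
refinement; exact ties break toward lower q. Annulus statistics are means,
not sums, so profiles are independent of annulus area; bins with no pixels
are absent rather than zero. The spacing is reported as the Bragg spacing
d = 2π/q with no liquid-like packing correction. Transect analysis labels
the center as the minimum-IFS position within the middle third of the scan
(corneal IFS is U-shaped, lowest centrally) and the periphery as the mean
of the two outermost positions per side.

## Elastic-fiber volumetrics

**Segmentation.** Automatic thresholding uses Otsu's inter-class-variance
criterion; dark fibers keep voxels at or below the threshold (Otsu assigns
the threshold bin to the lower class — with strict `<` a clean two-level
stack would segment empty). 26-connected components under 50 voxels are
removed as speckle; the threshold value and any manual edits of a
semi-automated workflow are inherently operator-dependent, so only the
automatic criterion and fixed thresholds are offered.

**Reference plane and binning.** The Descemet's-membrane plane is fitted by
total least squares (SVD); depth is the signed distance along the unit
normal, positive into the stroma. Voxels are binned in contiguous
12.5 μm depth bins (= 250 sections × 50 nm) starting at depth 0; voxels
below the plane fall outside all bins. A slice-group mode (bin whole
slices in runs of bin_depth/slice_spacing) is retained and agrees exactly
with the plane mode when the plane is the z = 0 stack face.

**Diameters.** Per component, the Euclidean distance transform (anisotropic
voxel sampling) is evaluated on the EDT ridge — voxels whose EDT is not
exceeded in their 26-neighborhood. The ridge is used as the medial axis
because iterative 3D thinning can collapse tubes of even voxel width to
nothing. Diameter = 2 × median ridge radius − one voxel: EDT distances run
center-to-center, so a one-voxel-thick structure has a medial radius of a
full voxel. On oblique cylinders threading between voxel centers the
estimate is conservative by up to ~1.5 voxels; stacks should sample fibers
at ≳4 voxels per diameter where diameters matter.

## Synthetic phantoms

The generators are pure functions of (truth record, shape): identical seeds
give bit-identical phantoms, and the truth record suffices to score every
downstream stage.

- **OCT:** spherical-cap anterior surface, posterior surface displaced by
  the optical-path thickness, both rendered as Gaussian bands (σ = 2 px, a
  free parameter standing in for the unknown axial point-spread), plus a
  faint uniform stromal level. Speckle is multiplicative unit-mean gamma
  noise with contrast 0.3 by default; real OCT speckle is spatially
  correlated and signal-dependent, which the phantom does not model, so
  recovery results bound discretization and estimator error rather than
  full instrument noise.
- **SAXS:** isotropic Gaussian ring in q over an A·q^(−b) background with
  per-pixel Poisson counting noise; calibrant mode renders full rings at
  q_m = 2πm/d_cal. Real tendon patterns are azimuthally structured arcs
  and real corneal reflections ride on form-factor modulation; neither is
  emulated. Default camera: λ = 0.1 nm, L = 6 m, 0.172 mm pixels, 384²
  detector.
- **SBF-SEM:** dark cylinders (radii 50–135 nm, i.e. diameters 100–270 nm)
  with axes parallel to the reference plane, random in-plane azimuth,
  placed uniformly within their depth bin; dark-on-bright rendering with
  Gaussian noise (σ = 8 gray levels at 60/180 contrast). The reference
  plane is tilted about the y axis and cuts through the stack, leaving a
  below-plane wedge as in an obliquely trimmed block. Default voxels are
  50 × 50 × 250 nm over a 9.6 × 9.6 μm field and nine 12.5 μm bins — a
  deliberately scaled-down stand-in for 2000² × ~2300-slice acquisitions,
  chosen so a full phantom builds in seconds; the binning arithmetic is
  scale-free.

**Fiber placement quota.** A Poisson-distributed fiber count would leave
~n^(−1/2) ≈ 15–20% relative fluctuation in each bin's realized fraction,
which would swamp per-bin recovery checks. Placement is therefore spatially
uniform but count-controlled: proposals are accepted while the realized
voxel count stays at or below the bin target (plus a small tolerance), and
chords grazing the field edge close the remaining gap, pinning the
realized fraction to the target within tens of voxels out of ~2 million.
Two guards keep the truth mask consistent with what a segmentation
pipeline can see: fragments smaller than 64 voxels are never added (at
250 nm slice spacing a tilted thin cylinder rasterizes as dashes, and
sub-threshold dashes would be erased by the speckle filter), and fiber
surfaces are inset from bin boundaries by half a voxel diagonal so
sub-voxel plane-registration error cannot reassign their voxels between
bins. Overlap is allowed (union mask), which is unbiased at the ≪5%
fractions modeled here; a 5% cap rejects requests where union placement
would bias.

- **Plane markers** are continuous points on the reference plane with
  0.02 μm z-jitter, emulating operator clicks on the membrane rather than
  voxelized annotations.

## Statistics

The workflow mirrors a standard small-study comparison: Shapiro–Wilk
normality per group, Levene's variance check on absolute deviations from
the group *median* (Brown–Forsythe variant — robust to the mild
non-normality it is meant to tolerate), then an independent two-sample
t-test with pooled variance (df = n₁+n₂−2); Welch is available behind a
flag. p-values come from the t-distribution CDF (regularized incomplete
beta). Null calibration uses 2000 seeded replicates of two N(0, 1) groups
of 30 — a realistic small-study size at which all three tests sit near
their nominal 5% level; the Brown–Forsythe test is known to run
conservative at much smaller n. For the fiber-density comparison the
printed depth-averaged means are compared directly (one specimen per
group in the source design); where a test is run on depth bins as
replicates, reports must say so — bins are serially correlated and the
nominal df is optimistic.

## Problem sizes and limitations

Default analysis sizes — OCT 12 × 320 × 768 voxels per phantom, SAXS 384²
detectors, SBF-SEM 450 × 192 × 192 stacks — were chosen so the full
validation battery (20 OCT phantoms, 10 SAXS phantoms plus calibration
invariance, two full fiber stacks, 2000 statistical replicates) completes
in well under a minute; all estimators are resolution-independent.
Known limitations: no refraction dewarping below the anterior surface (the
posterior surface is rendered and traced in optical-path coordinates); no
azimuthally resolved fibril orientation; diameter estimates are
voxelization-limited as described; phantom noise models are simpler than
instrument reality, so passing recovery tests demonstrates estimator
correctness, not robustness to every artifact of real acquisitions.
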