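"""Synthetic phantoms with known ground truth for every pipeline stage.

Each generator is a pure function of (truth record, output shape): the same
seed always produces a bit-identical phantom, and the truth record carries
everything needed to score the downstream measurement without looking at
generator internals.

* OCT: a spherical-cap anterior surface plus a posterior surface displaced
  by the *optical-path* thickness (physical thickness × refractive index),
  rendered as bright Gaussian bands with multiplicative unit-mean gamma
  speckle.
* Spectral A-scans: cosinusoidal interference fringes, one per reflector,
  sampled non-uniformly in wavelength as a spectrometer would.
* SAXS: an isotropic Gaussian ring at q = 2π/d over a power-law background
  A·q^(−b) with per-pixel Poisson counting noise; calibrant mode renders
  rings at q_m = 2πm/d_cal (tendon D = 67 nm, silver behenate 5.838 nm).
* SBF-SEM: dark thin cylinders with axes parallel to a (possibly tilted)
  reference plane, placed uniformly in space with a per-depth-bin quota so
  the realized volume fraction tracks the requested profile to within half
  a fiber volume.
* Group samples: seeded normal draws for the statistics workflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .fibers import DepthProfile, FiberStack, ReferencePlane
from .oct import OCTVolume
from .saxs import (
    SILVER_BEHENATE_D_NM,
    TENDON_D_NM,
    DetectorGeometry,
    ScatterPattern,
)

__all__ = [
    "OCTPhantomTruth",
    "SAXSPhantomTruth",
    "FiberPhantomTruth",
    "FiberPhantom",
    "gen_oct_volume",
    "gen_spectral_ascan",
    "gen_saxs_pattern",
    "gen_fiber_stack",
    "gen_group_samples",
]


# ---------------------------------------------------------------------------
# OCT


@dataclass(frozen=True)
class OCTPhantomTruth:
    """Ground truth for a spherical-cap OCT phantom.

    Default scan scales match a 1040 nm SD-OCT microscope: 2.66 μm/px axial
    in air, 3.09 μm/px lateral; mouse cornea refractive index 1.4.
    """

    radius_mm: float
    thickness_um: float
    refractive_index: float = 1.4
    axial_scale_air: float = 2.66
    lateral_scale: float = 3.09
    apex_position_px: float = 40.0
    surface_sigma_px: float = 2.0  # axial point-spread of the surface bands
    speckle_contrast: float = 0.3  # 0 disables; 1/sqrt(gamma shape)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.radius_mm <= 0 or self.thickness_um <= 0:
            raise ValueError("radius and thickness must be positive")
        if self.refractive_index < 1:
            raise ValueError("refractive index must be >= 1")
        if min(self.axial_scale_air, self.lateral_scale) <= 0:
            raise ValueError("pixel scales must be positive")
        if self.speckle_contrast < 0:
            raise ValueError("speckle contrast must be non-negative")

    def chord_width_um(self, sagitta_um: float = 300.0) -> float:
        """Analytic chord width w = 2√(2Rh − h²) at sagitta h."""
        r = self.radius_mm * 1000.0
        if sagitta_um > r:
            raise ValueError("sagitta exceeds the radius")
        return 2.0 * np.sqrt(2.0 * r * sagitta_um - sagitta_um**2)


def gen_oct_volume(
    truth: OCTPhantomTruth, shape: tuple[int, int, int] = (12, 320, 768)
) -> OCTVolume:
    """Render an OCT volume of a spherical corneal cap.

    ``shape`` is (frames, axial px, lateral px); frames are adjacent B-scans
    spaced by the lateral scale.  The anterior surface is a sphere of the
    true radius with its apex at ``apex_position_px``; the posterior surface
    lies ``thickness·n/axial_scale_air`` pixels below it (optical-path
    convention).  Speckle is multiplicative unit-mean gamma noise.
    """
    frames, n_ax, n_lat = shape
    r_um = truth.radius_mm * 1000.0
    x = (np.arange(n_lat) - (n_lat - 1) / 2.0) * truth.lateral_scale
    y = (np.arange(frames) - (frames - 1) / 2.0) * truth.lateral_scale
    rho2 = y[:, None] ** 2 + x[None, :] ** 2
    if rho2.max() >= r_um**2:
        raise ValueError(
            "spherical cap of radius "
            f"{truth.radius_mm} mm does not cover the lateral field of view"
        )
    sag_px = (r_um - np.sqrt(r_um**2 - rho2)) / truth.axial_scale_air
    z_ant = truth.apex_position_px + sag_px  # (frames, lat)
    dz = truth.thickness_um * truth.refractive_index / truth.axial_scale_air
    z_post = z_ant + dz
    if z_post.max() + 4 * truth.surface_sigma_px >= n_ax:
        raise ValueError("posterior surface falls outside the axial extent")

    zz = np.arange(n_ax, dtype=float)[None, :, None]
    s2 = 2.0 * truth.surface_sigma_px**2
    ant = np.exp(-((zz - z_ant[:, None, :]) ** 2) / s2)
    post = 0.7 * np.exp(-((zz - z_post[:, None, :]) ** 2) / s2)
    stroma = 0.08 * ((zz > z_ant[:, None, :] + 2 * truth.surface_sigma_px)
                     & (zz < z_post[:, None, :] - 2 * truth.surface_sigma_px))
    intensity = 0.01 + ant + post + stroma
    if truth.speckle_contrast > 0:
        rng = np.random.default_rng(truth.seed)
        shape_k = 1.0 / truth.speckle_contrast**2
        intensity = intensity * rng.gamma(shape_k, 1.0 / shape_k, size=intensity.shape)
    return OCTVolume(
        intensity=intensity.astype(np.float32),
        axial_scale_air=truth.axial_scale_air,
        lateral_scale=truth.lateral_scale,
        refractive_index=truth.refractive_index,
    )


def gen_spectral_ascan(
    reflector_depths_um,
    amplitudes=None,
    *,
    n_samples: int = 1024,
    center_wavelength_um: float = 1.040,
    bandwidth_um: float = 0.070,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Spectrometer output for point reflectors at the given optical depths.

    The wavelength grid is uniform in λ (hence non-uniform in wavenumber),
    the source envelope Gaussian, and each reflector at optical depth z
    contributes a fringe cos(2kz).  Depths at or beyond the Nyquist depth of
    the sampled spectrum are rejected.  Returns ``(wavelengths_um, spectrum)``.
    """
    depths = np.atleast_1d(np.asarray(reflector_depths_um, dtype=float))
    if amplitudes is None:
        amplitudes = np.full(depths.shape, 0.4)
    amplitudes = np.atleast_1d(np.asarray(amplitudes, dtype=float))
    if amplitudes.shape != depths.shape:
        raise ValueError("amplitudes must match reflector depths")
    lam = np.linspace(
        center_wavelength_um - bandwidth_um / 2.0,
        center_wavelength_um + bandwidth_um / 2.0,
        n_samples,
    )
    k = 2.0 * np.pi / lam
    dk = (k.max() - k.min()) / (n_samples - 1)
    z_nyquist = np.pi / (2.0 * dk)
    if np.any(depths >= z_nyquist):
        raise ValueError(
            f"reflector depth beyond the Nyquist depth {z_nyquist:.1f} um"
        )
    envelope = np.exp(-(((lam - center_wavelength_um) / (bandwidth_um / 3.0)) ** 2))
    fringes = np.zeros_like(lam)
    for z, a in zip(depths, amplitudes):
        fringes += a * np.cos(2.0 * k * z)
    spectrum = envelope * (1.0 + fringes)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        spectrum = spectrum + rng.normal(0.0, noise_sd, size=spectrum.shape)
    return lam, spectrum


# ---------------------------------------------------------------------------
# SAXS


@dataclass(frozen=True)
class SAXSPhantomTruth:
    """Ground truth for a 2D SAXS detector image.

    Default geometry matches a synchrotron small-angle camera: λ = 0.1 nm,
    sample–detector distance 6 m, 0.172 mm pixels.  ``calibrant='none'``
    renders the sample ring at q = 2π/d; calibrant modes render powder rings
    at q_m = 2πm/d_cal instead.
    """

    d_nm: float = 65.0
    peak_sigma_inv_nm: float = 0.004
    peak_amplitude: float = 400.0
    bg_amplitude: float = 0.05
    bg_exponent: float = 3.0
    calibrant: str = "none"  # none | tendon_67nm | silver_behenate
    n_orders: int = 3
    geometry: DetectorGeometry = field(
        default_factory=lambda: DetectorGeometry(
            wavelength_nm=0.1,
            distance_mm=6000.0,
            pixel_pitch_mm=0.172,
            beam_center=(191.5, 191.5),
        )
    )
    center_offset_px: tuple[float, float] = (0.0, 0.0)
    noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d_nm <= 0 or self.peak_sigma_inv_nm <= 0:
            raise ValueError("spacing and peak width must be positive")
        if self.bg_exponent <= 0:
            raise ValueError("background exponent must be positive")
        if self.calibrant not in ("none", "tendon_67nm", "silver_behenate"):
            raise ValueError(f"unknown calibrant {self.calibrant!r}")

    @property
    def beam_center_true(self) -> tuple[float, float]:
        r, c = self.geometry.beam_center
        return (r + self.center_offset_px[0], c + self.center_offset_px[1])

    def ring_q(self) -> np.ndarray:
        """q positions (nm⁻¹) of every rendered ring."""
        if self.calibrant == "none":
            return np.array([2.0 * np.pi / self.d_nm])
        d_cal = TENDON_D_NM if self.calibrant == "tendon_67nm" else SILVER_BEHENATE_D_NM
        return 2.0 * np.pi * np.arange(1, self.n_orders + 1) / d_cal


def gen_saxs_pattern(
    truth: SAXSPhantomTruth, shape: tuple[int, int] = (384, 384)
) -> ScatterPattern:
    """Render a detector image for the given truth record.

    The returned pattern's geometry carries the *nominal* beam center; the
    true center (nominal + offset) lives in the truth record, so beam-center
    refinement can be scored against it.
    """
    geo = truth.geometry
    cr, cc = truth.beam_center_true
    rows = np.arange(shape[0], dtype=float)[:, None] - cr
    cols = np.arange(shape[1], dtype=float)[None, :] - cc
    r = np.hypot(rows, cols)
    # every ring must fit inside the detector from the true center
    edge = min(cr, cc, shape[0] - 1 - cr, shape[1] - 1 - cc)
    for q0 in truth.ring_q():
        if geo.radius_from_q(q0) >= edge:
            raise ValueError(
                f"ring at q = {q0:.4f} 1/nm falls outside the detector"
            )
    q = geo.q_from_radius(np.maximum(r, 0.5))  # clip r to avoid q=0 blowup
    model = truth.bg_amplitude * np.power(q, -truth.bg_exponent)
    s2 = 2.0 * truth.peak_sigma_inv_nm**2
    for m, q0 in enumerate(truth.ring_q(), start=1):
        amp = truth.peak_amplitude / m
        model = model + amp * np.exp(-((q - q0) ** 2) / s2)
    if truth.noise:
        rng = np.random.default_rng(truth.seed)
        counts = rng.poisson(model).astype(float)
    else:
        counts = model
    return ScatterPattern(counts=counts, geometry=geo)


# ---------------------------------------------------------------------------
# SBF-SEM fiber stacks


@dataclass(frozen=True)
class FiberPhantomTruth:
    """Ground truth for a fiber-filled SBF-SEM stack.

    ``depth_fractions_pct`` gives the target fiber volume fraction (%) per
    contiguous depth bin of ``bin_depth_um`` above the reference plane.
    Fiber diameters span 100–270 nm (radii 50–135 nm); the default voxel is
    50 × 50 nm laterally with 250 nm slice spacing, a 5× coarser axial
    sampling than the 50 nm sectioning it stands in for (stacks at the full
    sectioning rate bin identically, just with more slices per bin).
    """

    depth_fractions_pct: tuple[float, ...]
    bin_depth_um: float = 12.5
    fiber_radius_range_nm: tuple[float, float] = (50.0, 135.0)
    voxel_size_nm: tuple[float, float, float] = (50.0, 50.0, 250.0)
    plane_tilt_deg: float = 0.0
    background_level: float = 180.0
    fiber_level: float = 60.0
    noise_sd: float = 8.0
    marker_jitter_um: float = 0.02  # z-error of clicked plane marker points
    min_fiber_voxels: int = 64  # shortest fragment a grazing chord may leave
    max_fraction_pct: float = 5.0  # overlap-cap: beyond this, union placement biases
    seed: int = 0

    def __post_init__(self) -> None:
        for f in self.depth_fractions_pct:
            if not 0.0 <= f <= 100.0:
                raise ValueError("volume fractions must lie in [0, 100]%")
            if f > self.max_fraction_pct:
                raise ValueError(
                    f"fraction {f}% exceeds the {self.max_fraction_pct}% overlap cap"
                )
        if min(self.voxel_size_nm) <= 0:
            raise ValueError("voxel sizes must be positive")
        lo, hi = self.fiber_radius_range_nm
        if not 0 < lo <= hi:
            raise ValueError("invalid fiber radius range")
        if lo < min(self.voxel_size_nm[:2]):
            raise ValueError("fiber radius must be at least one lateral voxel")


@dataclass(frozen=True)
class FiberPhantom:
    """A rendered fiber stack with everything needed to score the pipeline."""

    intensity: FiberStack
    truth_mask: np.ndarray  # voxel-exact fiber mask
    plane: ReferencePlane
    marker_points_um: np.ndarray  # sampled points on the reference plane
    realized: DepthProfile  # realized per-bin fractions of the truth mask


def _plane_for_truth(
    truth: FiberPhantomTruth, shape: tuple[int, int, int]
) -> ReferencePlane:
    """Reference plane tilted about the y axis, cutting through the stack.

    With no tilt the plane is the z = 0 stack face (so plane-distance and
    slice-group binning agree exactly); with tilt it is raised so the whole
    membrane trace z(x) stays inside the volume, leaving a thin wedge of
    below-plane tissue as in an obliquely trimmed block.
    """
    t = np.radians(truth.plane_tilt_deg)
    normal = (float(np.sin(t)), 0.0, float(np.cos(t)))
    vx, vy, vz = (v / 1000.0 for v in truth.voxel_size_nm)
    nz, ny, nx = shape
    if truth.plane_tilt_deg == 0:
        return ReferencePlane(normal=normal, offset_um=0.0)
    margin = 2.0 * vz  # keep the membrane clear of the stack face
    offset = normal[0] * (nx - 0.5) * vx + normal[2] * margin
    z_high = (offset - normal[0] * 0.5 * vx) / normal[2]
    if z_high >= nz * vz:
        raise ValueError("plane tilt too steep for the stack extent")
    return ReferencePlane(normal=normal, offset_um=float(offset))


def gen_fiber_stack(
    truth: FiberPhantomTruth, shape: tuple[int, int, int] = (450, 192, 192)
) -> FiberPhantom:
    """Render a fiber-filled stack realizing the requested depth profile.

    Fibers are straight cylinders with axes parallel to the reference plane
    (random in-plane azimuth), placed uniformly in space within their depth
    bin.  Per bin, proposals leaving fewer than ``min_fiber_voxels`` new
    voxels are discarded (fragments that short would be indistinguishable
    from speckle) and the rest accepted only while they move the realized
    voxel count toward the target, so the realized fraction lands within
    half the smallest allowed fragment of the target.  Overlapping fibers
    merge into a union mask.  The rendered image is dark fibers on a bright
    background with Gaussian noise.
    """
    rng = np.random.default_rng(truth.seed)
    nz, ny, nx = shape
    vx, vy, vz = (v / 1000.0 for v in truth.voxel_size_nm)
    plane = _plane_for_truth(truth, shape)
    n_vec = np.asarray(plane.normal)

    x, y, z = (np.arange(nx) + 0.5) * vx, (np.arange(ny) + 0.5) * vy, (np.arange(nz) + 0.5) * vz
    # separable depth field: depth(z,y,x) = z nz + y ny + x nx − offset
    depth_zx = z[:, None] * n_vec[2] + x[None, :] * n_vec[0] - plane.offset_um
    mask = np.zeros(shape, dtype=bool)

    # in-plane frame: e1 in the xz tilt plane, e2 along y
    tilt = np.radians(truth.plane_tilt_deg)
    e1 = np.array([np.cos(tilt), 0.0, -np.sin(tilt)])
    e2 = np.array([0.0, 1.0, 0.0])
    field_center = np.array([nx * vx / 2.0, ny * vy / 2.0, nz * vz / 2.0])
    span = float(np.hypot(nx * vx, ny * vy))  # generous in-plane reach
    r_lo, r_hi = (r / 1000.0 for r in truth.fiber_radius_range_nm)

    coords_x = x[None, None, :]
    coords_y = y[None, :, None]
    # keep fiber surfaces clear of bin boundaries by half a voxel diagonal,
    # so sub-voxel plane-registration error cannot reassign their voxels
    edge_pad = 0.5 * float(np.linalg.norm([vx, vy, vz]))

    def depth_of(p):  # signed distance of a point to the plane
        return float(p @ n_vec - plane.offset_um)

    bin_lo = np.arange(len(truth.depth_fractions_pct)) * truth.bin_depth_um
    row_min = depth_zx.min(axis=1)  # per-slice depth range (y-independent)
    row_max = depth_zx.max(axis=1)

    depth_all = (
        z[:, None, None] * n_vec[2]
        + y[None, :, None] * n_vec[1]
        + x[None, None, :] * n_vec[0]
        - plane.offset_um
    ).astype(np.float32)
    bin_idx = np.floor(depth_all / truth.bin_depth_um).astype(np.int64)
    n_bins = len(truth.depth_fractions_pct)
    total_per_bin = np.bincount(
        bin_idx[(bin_idx >= 0) & (bin_idx < n_bins)], minlength=n_bins
    )

    for b, frac in enumerate(truth.depth_fractions_pct):
        target = int(round(frac / 100.0 * total_per_bin[b]))
        current = 0
        lo_d, hi_d = bin_lo[b], bin_lo[b] + truth.bin_depth_um
        if target > 0 and hi_d - lo_d <= 2.0 * r_hi:
            raise ValueError("depth bin thinner than a fiber diameter")
        tol = max(20, truth.min_fiber_voxels // 2, int(0.002 * target))
        attempts = 0
        stalled = 0
        while target - current > tol and attempts < 20000 and stalled < 2000:
            attempts += 1
            radius = rng.uniform(r_lo, r_hi)
            c_d = rng.uniform(lo_d + radius + edge_pad, hi_d - radius - edge_pad)
            phi = rng.uniform(0.0, 2.0 * np.pi)
            u = np.cos(phi) * e1 + np.sin(phi) * e2
            w = np.cross(n_vec, u)
            s = rng.uniform(-span / 2.0, span / 2.0)
            p0 = field_center + (c_d - depth_of(field_center)) * n_vec + s * w

            # z-slab where voxel centers can lie within `radius` of the axis
            zx_lo, zx_hi = c_d - radius, c_d + radius
            slab = np.flatnonzero((row_max >= zx_lo) & (row_min <= zx_hi))
            if slab.size == 0:
                continue
            z0, z1 = slab[0], slab[-1] + 1
            zc = z[z0:z1][:, None, None]
            dxv = coords_x - p0[0]
            dyv = coords_y - p0[1]
            dzv = zc - p0[2]
            proj = dxv * u[0] + dyv * u[1] + dzv * u[2]
            dist2 = (dxv**2 + dyv**2 + dzv**2) - proj**2
            cand = dist2 <= radius * radius
            new = cand & ~mask[z0:z1]
            if new.any():
                # at coarse slice spacing, tilted thin cylinders rasterize
                # as dashes; drop fragments below the placement floor so the
                # truth mask holds nothing a speckle filter would erase
                lab, _ = ndimage.label(new, structure=np.ones((3, 3, 3)))
                counts = np.bincount(lab.ravel())
                counts[0] = 0
                new = (counts >= truth.min_fiber_voxels)[lab]
            n_new = int(new.sum())
            if n_new < truth.min_fiber_voxels:
                stalled += 1
                continue
            # approach the quota from below, never overshooting beyond tol;
            # short chords near the field edge close the remaining gap
            if current + n_new <= target + tol:
                mask[z0:z1] |= new
                current += n_new
                stalled = 0
            else:
                stalled += 1
        if target > 0 and current < 0.9 * target:
            raise ValueError(
                f"could not realize {frac}% in bin {b}: fraction unreachable"
            )

    fiber_counts = np.bincount(bin_idx[mask & (bin_idx >= 0) & (bin_idx < n_bins)],
                               minlength=n_bins)
    realized = DepthProfile(
        bin_edges_um=np.arange(n_bins + 1) * truth.bin_depth_um,
        fiber_voxels=fiber_counts,
        total_voxels=total_per_bin,
        bin_depth_um=truth.bin_depth_um,
    )

    image = np.full(shape, truth.background_level, dtype=float)
    image[mask] = truth.fiber_level
    if truth.noise_sd > 0:
        image = image + rng.normal(0.0, truth.noise_sd, size=shape)
    image = np.clip(image, 0, 255).astype(np.uint8)

    # continuous plane-marker points, as a user would click on the membrane
    n_marker = 200
    mx = rng.uniform(0.5 * vx, (nx - 0.5) * vx, n_marker)
    my = rng.uniform(0.5 * vy, (ny - 0.5) * vy, n_marker)
    mz = (plane.offset_um - n_vec[0] * mx - n_vec[1] * my) / n_vec[2]
    if truth.marker_jitter_um > 0:
        mz = mz + rng.normal(0.0, truth.marker_jitter_um, mz.shape)
    markers = np.column_stack([mx, my, mz])
    markers = markers[(mz >= 0) & (mz <= nz * vz)]

    return FiberPhantom(
        intensity=FiberStack(data=image, voxel_size_nm=truth.voxel_size_nm),
        truth_mask=mask,
        plane=plane,
        marker_points_um=markers,
        realized=realized,
    )


# ---------------------------------------------------------------------------
# group samples


def gen_group_samples(mean: float, sd: float, n: int, seed: int = 0) -> np.ndarray:
    """n seeded normal draws N(mean, sd²) for the statistics workflow."""
    if n < 2:
        raise ValueError("need at least 2 samples per group")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    rng = np.random.default_rng(seed)
    return rng.normal(mean, sd, size=n)
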