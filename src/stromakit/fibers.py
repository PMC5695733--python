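"""Elastic-fiber volumetrics from serial block-face SEM stacks.

Elastic (fibrillin-rich microfibril) fibers appear as thin, dark, in-plane
cylinders in SBF-SEM stacks of corneal stroma.  This module segments them,
fits the Descemet's-membrane reference plane (blocks are rarely cut exactly
parallel to the tissue surface, so the plane is generally oblique), bins
voxels by signed distance above that plane in 12.5 μm depth bins, and
reports the percentage of tissue volume occupied by fibers per bin, plus
per-fiber diameters from a skeleton/distance-transform measurement.

Axis convention: stacks are indexed (slice z, row y, col x); voxel sizes are
given as (x, y, z) in nm; physical coordinates are (x, y, z) in μm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

__all__ = [
    "FiberStack",
    "ReferencePlane",
    "DepthProfile",
    "segment_fibers",
    "fit_reference_plane",
    "depth_volume_fractions",
    "depth_volume_fractions_by_slices",
    "fiber_diameters",
]


@dataclass(frozen=True)
class FiberStack:
    """3D stack (grayscale intensity or boolean fiber labels) + voxel sizes."""

    data: np.ndarray  # (slice, row, col)
    voxel_size_nm: tuple[float, float, float]  # (x, y, z); z = slice spacing

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("stack must be 3D (slice, row, col)")
        if min(self.voxel_size_nm) <= 0:
            raise ValueError("voxel sizes must be positive")

    @property
    def slice_spacing_nm(self) -> float:
        return self.voxel_size_nm[2]

    def voxel_centers_um(self):
        """Physical (x, y, z) coordinate vectors of voxel centers, in μm."""
        vx, vy, vz = (v / 1000.0 for v in self.voxel_size_nm)
        nz, ny, nx = self.data.shape
        x = (np.arange(nx) + 0.5) * vx
        y = (np.arange(ny) + 0.5) * vy
        z = (np.arange(nz) + 0.5) * vz
        return x, y, z


@dataclass(frozen=True)
class ReferencePlane:
    """Plane n·x = offset (coordinates in μm); ‖n‖ = 1.

    Depth of a point is its signed distance n·x − offset, positive on the
    side the normal points to (into the stroma).
    """

    normal: tuple[float, float, float]  # (x, y, z) components
    offset_um: float
    residual_rms_um: float = 0.0

    def __post_init__(self) -> None:
        if not np.isclose(np.linalg.norm(self.normal), 1.0):
            raise ValueError("plane normal must be a unit vector")
        if self.residual_rms_um < 0:
            raise ValueError("residual must be non-negative")

    def signed_distance(self, points_um: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points_um, dtype=float))
        return pts @ np.asarray(self.normal) - self.offset_um

    def tilt_deg(self) -> float:
        """Angle between the plane normal and the stack z axis."""
        return float(np.degrees(np.arccos(np.clip(abs(self.normal[2]), -1, 1))))


@dataclass(frozen=True)
class DepthProfile:
    """Fiber volume fraction per depth bin above the reference plane."""

    bin_edges_um: np.ndarray  # length n_bins + 1, contiguous
    fiber_voxels: np.ndarray
    total_voxels: np.ndarray
    bin_depth_um: float

    def __post_init__(self) -> None:
        if np.any(self.fiber_voxels > self.total_voxels):
            raise ValueError("fiber voxels cannot exceed total voxels")
        if np.any(np.diff(self.bin_edges_um) <= 0):
            raise ValueError("bins must be contiguous and increasing")

    @property
    def fraction_pct(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(
                self.total_voxels > 0,
                100.0 * self.fiber_voxels / self.total_voxels,
                np.nan,
            )

    @property
    def mean_fraction_pct(self) -> float:
        """All-depth mean: total fiber voxels over total voxels, in %."""
        return 100.0 * float(self.fiber_voxels.sum()) / float(self.total_voxels.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "depth_start_um": self.bin_edges_um[:-1],
                "depth_end_um": self.bin_edges_um[1:],
                "fiber_voxels": self.fiber_voxels,
                "total_voxels": self.total_voxels,
                "fraction_pct": self.fraction_pct,
            }
        )


def segment_fibers(
    stack: FiberStack,
    threshold: float | str = "otsu",
    *,
    dark_fibers: bool = True,
    min_component_voxels: int = 50,
) -> np.ndarray:
    """Threshold a grayscale stack into a boolean fiber mask.

    ``threshold='otsu'`` picks the inter-class-variance-maximizing level;
    a float fixes it.  Dark fibers (the default) keep voxels at or below
    the threshold — Otsu assigns the threshold bin itself to the lower
    class — while ``dark_fibers=False`` keeps voxels strictly above it.
    Components smaller than ``min_component_voxels`` under 26-connectivity
    are removed as speckle.
    """
    data = np.asarray(stack.data)
    if isinstance(threshold, str):
        if threshold != "otsu":
            raise ValueError(f"unknown automatic threshold {threshold!r}")
        if data.min() == data.max():
            raise ValueError("constant stack: automatic threshold undefined")
        thr = threshold_otsu(data)
    else:
        thr = float(threshold)
    mask = data <= thr if dark_fibers else data > thr
    if min_component_voxels > 0 and mask.any():
        comp = cc_label(mask, connectivity=3)
        sizes = np.bincount(comp.ravel())
        small = sizes < min_component_voxels
        small[0] = False
        mask = mask & ~small[comp]
    return mask


def fit_reference_plane(points_um: np.ndarray) -> ReferencePlane:
    """Total-least-squares plane through marker points (N×3, μm).

    The normal is the direction of least variance (smallest right singular
    vector of the centered coordinates), oriented with non-negative z so
    depth increases into the stack.  Degenerate (collinear or coincident)
    marker sets are rejected.
    """
    pts = np.atleast_2d(np.asarray(points_um, dtype=float))
    if pts.shape[0] < 3 or pts.shape[1] != 3:
        raise ValueError("need at least 3 points of dimension 3")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    # collinear points: second singular value vanishes relative to the first
    scale = s[0] if s[0] > 0 else 1.0
    if s[1] / scale < 1e-10:
        raise ValueError("marker points are collinear or coincident")
    normal = vt[2]
    if normal[2] < 0:
        normal = -normal
    residual_rms = s[2] / np.sqrt(pts.shape[0])
    return ReferencePlane(
        normal=tuple(float(c) for c in normal),
        offset_um=float(normal @ centroid),
        residual_rms_um=float(residual_rms),
    )


def _voxel_depths_um(stack: FiberStack, plane: ReferencePlane) -> np.ndarray:
    """Signed distance of every voxel center to the plane (float32, zyx grid)."""
    x, y, z = stack.voxel_centers_um()
    nx_, ny_, nz_ = plane.normal
    depth = (
        z[:, None, None] * nz_ + y[None, :, None] * ny_ + x[None, None, :] * nx_
        - plane.offset_um
    )
    return depth.astype(np.float32)


def depth_volume_fractions(
    labels: np.ndarray | FiberStack,
    voxel_size_nm: tuple[float, float, float] | None = None,
    *,
    plane: ReferencePlane | None = None,
    bin_depth_um: float = 12.5,
    excluded: np.ndarray | None = None,
) -> DepthProfile:
    """Fiber volume fraction per depth bin above the reference plane.

    Voxels are binned by signed distance to the plane, in contiguous bins of
    ``bin_depth_um`` starting at depth 0 (the default 12.5 μm matches 250
    serial sections at 50 nm).  Per bin, fraction % = 100 × fiber voxels /
    total voxels; ``excluded`` voxels (e.g. cell bodies) are dropped from
    both counts.  Voxels below the plane (negative depth) are outside all
    bins; empty bins are absent from the profile.
    """
    if isinstance(labels, FiberStack):
        stack = FiberStack(np.asarray(labels.data, dtype=bool), labels.voxel_size_nm)
    else:
        if voxel_size_nm is None:
            raise ValueError("voxel_size_nm required when labels is a bare array")
        stack = FiberStack(np.asarray(labels, dtype=bool), tuple(voxel_size_nm))
    if bin_depth_um <= 0:
        raise ValueError("bin depth must be positive")
    if plane is None:
        plane = ReferencePlane(normal=(0.0, 0.0, 1.0), offset_um=0.0)

    depth = _voxel_depths_um(stack, plane)
    idx = np.floor(depth / bin_depth_um).astype(np.int64)
    keep = idx >= 0
    if excluded is not None:
        keep &= ~np.asarray(excluded, dtype=bool)
    idx_k = idx[keep]
    fiber_k = stack.data[keep]
    n_bins = int(idx_k.max()) + 1 if idx_k.size else 0
    if n_bins == 0:
        raise ValueError("no voxels above the reference plane")
    total = np.bincount(idx_k, minlength=n_bins)
    fiber = np.bincount(idx_k[fiber_k], minlength=n_bins)
    present = total > 0
    first, last = np.flatnonzero(present)[[0, -1]]
    edges = np.arange(first, last + 2) * bin_depth_um
    return DepthProfile(
        bin_edges_um=edges,
        fiber_voxels=fiber[first : last + 1],
        total_voxels=total[first : last + 1],
        bin_depth_um=bin_depth_um,
    )


def depth_volume_fractions_by_slices(
    labels: np.ndarray | FiberStack,
    voxel_size_nm: tuple[float, float, float] | None = None,
    *,
    bin_depth_um: float = 12.5,
) -> DepthProfile:
    """Slice-group mode: bin whole slices in runs of bin_depth/slice_spacing.

    This reproduces direct grouping of serial images (e.g. 250 images ×
    50 nm ≈ 12.5 μm) and must agree exactly with the plane-distance mode
    when the reference plane is the z = 0 stack face.
    """
    if isinstance(labels, FiberStack):
        stack = FiberStack(np.asarray(labels.data, dtype=bool), labels.voxel_size_nm)
    else:
        if voxel_size_nm is None:
            raise ValueError("voxel_size_nm required when labels is a bare array")
        stack = FiberStack(np.asarray(labels, dtype=bool), tuple(voxel_size_nm))
    vz_um = stack.slice_spacing_nm / 1000.0
    group = max(1, int(round(bin_depth_um / vz_um)))
    nz = stack.data.shape[0]
    per_slice_fiber = stack.data.reshape(nz, -1).sum(axis=1)
    per_slice_total = np.full(nz, stack.data.shape[1] * stack.data.shape[2])
    gidx = np.arange(nz) // group
    n_bins = int(gidx[-1]) + 1
    fiber = np.bincount(gidx, weights=per_slice_fiber, minlength=n_bins).astype(np.int64)
    total = np.bincount(gidx, weights=per_slice_total, minlength=n_bins).astype(np.int64)
    edges = np.arange(n_bins + 1) * group * vz_um
    return DepthProfile(
        bin_edges_um=edges, fiber_voxels=fiber, total_voxels=total,
        bin_depth_um=group * vz_um,
    )


def fiber_diameters(
    labels: np.ndarray | FiberStack,
    voxel_size_nm: tuple[float, float, float] | None = None,
    *,
    connectivity: int = 3,
) -> dict:
    """Per-fiber diameters from the medial axis of each connected component.

    For each 26-connected component the Euclidean distance transform (with
    anisotropic voxel sampling) is evaluated on the component's medial axis
    — the ridge of EDT local maxima, which stays well defined for tubes of
    even voxel width where iterative thinning can collapse entirely.  The
    fiber diameter is twice the median of those medial radii, minus one
    voxel: EDT distances run between voxel *centers*, so a structure one
    voxel thick has medial radius of a full voxel, not half.  On oblique
    cylinders whose axis threads between voxel centers this is conservative
    by up to ~1.5 voxels; sample at fine voxels relative to the fiber
    radius.  Returns per-fiber diameters (nm) and summary statistics.
    """
    if isinstance(labels, FiberStack):
        mask = np.asarray(labels.data, dtype=bool)
        voxel_size_nm = labels.voxel_size_nm
    else:
        mask = np.asarray(labels, dtype=bool)
        if voxel_size_nm is None:
            raise ValueError("voxel_size_nm required when labels is a bare array")
    vx, vy, vz = voxel_size_nm
    comp = cc_label(mask, connectivity=connectivity)
    n_comp = comp.max()
    if n_comp == 0:
        raise ValueError("no fiber components in the mask")
    objects = ndimage.find_objects(comp)
    # sampling per array axis (z, y, x); correction uses the finest axis
    sampling = (vz, vy, vx)
    vox_min = float(min(voxel_size_nm))
    diameters = []
    for i, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        sub = comp[sl] == i
        padded = np.pad(sub, 1)
        edt = ndimage.distance_transform_edt(padded, sampling=sampling)
        ridge = (edt >= ndimage.maximum_filter(edt, size=3)) & padded
        radii = edt[ridge]
        d = 2.0 * float(np.median(radii)) - vox_min
        diameters.append(max(d, vox_min))
    diam = np.asarray(diameters)
    return {
        "n_fibers": int(diam.size),
        "mean_nm": float(diam.mean()),
        "min_nm": float(diam.min()),
        "max_nm": float(diam.max()),
        "diameters_nm": diam,
    }
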