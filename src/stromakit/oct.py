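"""Corneal geometry from spectral-domain OCT volumes.

Central corneal thickness and anterior radius of curvature are measured on
a B-scan averaged from the central frames of a 3D OCT volume.  Depths in the
raw data are *optical-path* pixels: below the anterior surface the axial
scale in air is reduced by the tissue refractive index (n = 1.4 for mouse
cornea), so a span of ``p`` pixels corresponds to a physical thickness of
``p * axial_scale_air / n`` micrometres.

The radius of curvature follows the sagitta construction: an arc of fixed
height (sagitta) ``h`` is taken at the corneal apex, its chord width ``w``
measured, and the circle radius recovered from Pythagoras as

    R = w^2 / (8 h) + h / 2.

A minimal spectral-domain A-scan reconstruction (resample to uniform
wavenumber, window, FFT) is included so spectra generated by the phantom
module can be processed end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

__all__ = [
    "OCTVolume",
    "SurfaceTraces",
    "CornealGeometry",
    "reconstruct_ascan",
    "average_central_frames",
    "trace_surfaces",
    "thickness_microns",
    "radius_of_curvature",
    "measure_cornea",
]


@dataclass(frozen=True)
class OCTVolume:
    """3D OCT intensity volume with its scan geometry.

    ``intensity`` is indexed (frame, axial px, lateral px); axial position 0
    is the top of the image and increases downward.  ``axial_scale_air`` is
    the depth per pixel in air (μm/px); inside tissue the effective scale is
    ``axial_scale_air / refractive_index``.
    """

    intensity: np.ndarray
    axial_scale_air: float
    lateral_scale: float
    refractive_index: float = 1.4

    def __post_init__(self) -> None:
        if self.intensity.ndim != 3:
            raise ValueError("intensity must be a 3D (frame, axial, lateral) array")
        if np.any(np.asarray(self.intensity) < 0):
            raise ValueError("intensities must be non-negative")
        if self.axial_scale_air <= 0 or self.lateral_scale <= 0:
            raise ValueError("pixel scales must be positive")
        if self.refractive_index < 1:
            raise ValueError("refractive index must be >= 1")

    @property
    def n_frames(self) -> int:
        return self.intensity.shape[0]


@dataclass(frozen=True)
class SurfaceTraces:
    """Per-column anterior/posterior boundary depths in (sub-pixel) axial px."""

    anterior: np.ndarray
    posterior: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        ok = self.valid
        if np.any(self.posterior[ok] < self.anterior[ok]):
            raise ValueError("posterior surface must lie below the anterior surface")

    @property
    def n_valid(self) -> int:
        return int(np.count_nonzero(self.valid))


@dataclass(frozen=True)
class CornealGeometry:
    """Measured central corneal geometry."""

    thickness_um: float
    radius_mm: float
    chord_width_um: float
    sagitta_um: float
    qc: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.thickness_um <= 0:
            raise ValueError("thickness must be positive")
        if self.chord_width_um <= 0:
            raise ValueError("chord width must be positive")
        # geometric feasibility: a circle of radius R supports sagitta h <= 2R
        if self.radius_mm * 1000.0 < self.sagitta_um / 2.0:
            raise ValueError("radius incompatible with sagitta (R < h/2)")


def reconstruct_ascan(
    spectrum: np.ndarray,
    wavelengths_um: np.ndarray,
    *,
    window: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Reconstruct a depth profile from a spectral-domain interferogram.

    The spectrum, sampled on an arbitrary strictly monotonic wavelength grid,
    is resampled to a uniform wavenumber (k = 2π/λ) grid, mean-subtracted,
    Hann-windowed and Fourier transformed.  A reflector at optical depth z
    contributes a fringe cos(2 k z), so the magnitude peak appears at depth
    bin  m = N δk z / π.

    Returns
    -------
    depths_um, magnitude : ndarray
        Optical-path depth axis (μm) and spectral magnitude per depth bin.
    """
    spectrum = np.asarray(spectrum, dtype=float)
    lam = np.asarray(wavelengths_um, dtype=float)
    if spectrum.ndim != 1 or spectrum.size < 16:
        raise ValueError("spectrum must be 1D with at least 16 samples")
    if lam.shape != spectrum.shape:
        raise ValueError("wavelength grid must match the spectrum length")
    dl = np.diff(lam)
    if not (np.all(dl > 0) or np.all(dl < 0)):
        raise ValueError("wavelength grid must be strictly monotonic")

    k = 2.0 * np.pi / lam
    order = np.argsort(k)
    k, s = k[order], spectrum[order]
    n = k.size
    ku = np.linspace(k[0], k[-1], n)
    su = np.interp(ku, k, s)
    su = su - su.mean()
    if window:
        su = su * np.hanning(n)
    mag = np.abs(np.fft.rfft(su))
    dk = ku[1] - ku[0]
    depths = np.arange(mag.size) * np.pi / (n * dk)
    return depths, mag


def average_central_frames(volume: OCTVolume, count: int = 10) -> np.ndarray:
    """Pixelwise mean of the central ``count`` frames of the volume."""
    nf = volume.n_frames
    if nf == 0:
        raise ValueError("volume has no frames")
    if not 1 <= count <= nf:
        raise ValueError(f"count must be in [1, {nf}], got {count}")
    start = (nf - count) // 2
    return volume.intensity[start : start + count].mean(axis=0)


def _parabolic_refine(y: np.ndarray, i: int) -> float:
    """Sub-pixel peak position by a 3-point parabola around index i."""
    if i <= 0 or i >= y.size - 1:
        return float(i)
    denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
    if denom >= 0:  # not locally concave
        return float(i)
    return float(i + 0.5 * (y[i - 1] - y[i + 1]) / denom)


def trace_surfaces(
    image: np.ndarray,
    *,
    smooth_sigma: float = 1.5,
    min_prominence: float = 0.2,
    min_separation_px: int = 5,
    flip: bool = False,
) -> SurfaceTraces:
    """Detect anterior and posterior corneal boundaries in every column.

    Per lateral column the anterior surface is the first sustained intensity
    peak from the top and the posterior surface the next sustained peak below
    it; both are refined to sub-pixel precision by a local parabolic fit.
    ``min_prominence`` is relative to the column's maximum, so bright and dim
    columns are treated alike.  Columns where detection fails are masked
    invalid; fewer than 50% valid columns is an error.

    Set ``flip`` when the image is stored upside down (axial axis reversed):
    the image is flipped internally and traces are reported in the upright
    frame, so ``trace_surfaces(img[::-1], flip=True)`` equals
    ``trace_surfaces(img)``.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2D B-scan image")
    if flip:
        img = img[::-1]
    sm = gaussian_filter1d(img, smooth_sigma, axis=0, mode="nearest")

    n_ax, n_lat = sm.shape
    anterior = np.full(n_lat, np.nan)
    posterior = np.full(n_lat, np.nan)
    valid = np.zeros(n_lat, dtype=bool)
    for j in range(n_lat):
        col = sm[:, j]
        top = col.max()
        if top <= 0:
            continue
        peaks, _ = find_peaks(
            col, prominence=min_prominence * top, distance=min_separation_px
        )
        if peaks.size < 2:
            continue
        a, p = peaks[0], peaks[1]
        anterior[j] = _parabolic_refine(col, a)
        posterior[j] = _parabolic_refine(col, p)
        valid[j] = True

    if np.count_nonzero(valid) < 0.5 * n_lat:
        raise ValueError(
            f"surface detection failed on {n_lat - np.count_nonzero(valid)} of "
            f"{n_lat} columns (>50% invalid)"
        )
    return SurfaceTraces(anterior=anterior, posterior=posterior, valid=valid)


def thickness_microns(pixel_count: float, axial_scale_air: float, n: float) -> float:
    """Convert an optical-path pixel span inside tissue to physical μm.

    thickness = pixel_count × axial_scale_air / n
    """
    if pixel_count < 0:
        raise ValueError("pixel count must be non-negative")
    if axial_scale_air <= 0:
        raise ValueError("axial scale must be positive")
    if n < 1:
        raise ValueError("refractive index must be >= 1")
    return pixel_count * axial_scale_air / n


def _moving_average_nan(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average ignoring NaNs (window forced odd)."""
    window = max(1, int(window) | 1)
    kernel = np.ones(window)
    finite = np.isfinite(x)
    num = np.convolve(np.where(finite, x, 0.0), kernel, mode="same")
    den = np.convolve(finite.astype(float), kernel, mode="same")
    with np.errstate(invalid="ignore"):
        return np.where(den > 0, num / den, np.nan)


def radius_of_curvature(
    anterior_px: np.ndarray,
    *,
    axial_scale_air: float,
    lateral_scale: float,
    sagitta_um: float = 300.0,
    valid: np.ndarray | None = None,
    smooth_window: int = 11,
) -> tuple[float, float]:
    """Anterior radius of curvature from a traced surface, via the sagitta.

    The apex is the minimum of the (moving-average smoothed) anterior trace,
    ties broken toward the image center.  The chord is taken at depth
    ``sagitta_um`` below the apex, its endpoints located by linear
    interpolation between the bracketing columns, and

        R = w²/(8h) + h/2.

    The anterior surface sits in air, so the trace converts to physical μm
    with the in-air axial scale.  Returns ``(radius_mm, chord_width_um)``.
    """
    if sagitta_um <= 0:
        raise ValueError("sagitta must be positive")
    z = np.asarray(anterior_px, dtype=float) * axial_scale_air
    if valid is not None:
        z = np.where(np.asarray(valid, dtype=bool), z, np.nan)
    zs = _moving_average_nan(z, smooth_window)
    if not np.any(np.isfinite(zs)):
        raise ValueError("anterior trace has no valid columns")

    center = (zs.size - 1) / 2.0
    zmin = np.nanmin(zs)
    candidates = np.flatnonzero(zs == zmin)
    apex = int(candidates[np.argmin(np.abs(candidates - center))])
    target = zmin + sagitta_um

    def _crossing(direction: int) -> float:
        j = apex
        while True:
            j_next = j + direction
            if j_next < 0 or j_next >= zs.size or not np.isfinite(zs[j_next]):
                raise ValueError(
                    "anterior trace does not reach the sagitta depth on "
                    + ("the right" if direction > 0 else "the left")
                )
            if zs[j_next] >= target:
                # linear interpolation between columns j and j_next
                frac = (target - zs[j]) / (zs[j_next] - zs[j])
                return j + direction * frac
            j = j_next

    left = _crossing(-1)
    right = _crossing(+1)
    w = (right - left) * lateral_scale
    h = sagitta_um
    radius_um = w * w / (8.0 * h) + h / 2.0
    return radius_um / 1000.0, w


def measure_cornea(
    volume: OCTVolume,
    *,
    frame_count: int = 10,
    sagitta_um: float = 300.0,
    thickness_window: int = 11,
    smooth_window: int = 11,
    trace_kwargs: dict | None = None,
) -> CornealGeometry:
    """Full measurement: average frames, trace surfaces, thickness + radius.

    Central thickness is the median anterior→posterior pixel span over a
    small window of columns centered on the apex (``thickness_window``,
    odd), converted to μm with the tissue refractive index.  The posterior
    boundary is the strongest peak below the anterior surface; which
    anatomical feature that is (endothelium vs posterior stromal edge) is
    recorded in the QC dict.
    """
    frame_count = min(frame_count, volume.n_frames)
    image = average_central_frames(volume, count=frame_count)
    traces = trace_surfaces(image, **(trace_kwargs or {}))
    radius_mm, w_um = radius_of_curvature(
        traces.anterior,
        axial_scale_air=volume.axial_scale_air,
        lateral_scale=volume.lateral_scale,
        sagitta_um=sagitta_um,
        valid=traces.valid,
        smooth_window=smooth_window,
    )

    zs = _moving_average_nan(
        np.where(traces.valid, traces.anterior, np.nan), smooth_window
    )
    apex = int(np.nanargmin(zs))
    half = max(0, int(thickness_window) // 2)
    lo, hi = max(0, apex - half), min(zs.size, apex + half + 1)
    span = traces.posterior[lo:hi] - traces.anterior[lo:hi]
    span = span[traces.valid[lo:hi]]
    if span.size == 0:
        raise ValueError("no valid columns around the apex for thickness")
    pixel_count = float(np.median(span))
    thickness = thickness_microns(
        pixel_count, volume.axial_scale_air, volume.refractive_index
    )
    qc = {
        "apex_column": apex,
        "valid_fraction": traces.n_valid / traces.valid.size,
        "thickness_pixel_count": pixel_count,
        "posterior_definition": "strongest peak below anterior",
    }
    return CornealGeometry(
        thickness_um=thickness,
        radius_mm=radius_mm,
        chord_width_um=w_um,
        sagitta_um=sagitta_um,
        qc=qc,
    )
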