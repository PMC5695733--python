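import numpy as np
import pytest

from stromakit import synth


@pytest.fixture(scope="session")
def oct_phantom_noiseless():
    """Noiseless spherical-cap volume with the default scan geometry."""
    truth = synth.OCTPhantomTruth(
        radius_mm=1.94, thickness_um=183.6, speckle_contrast=0.0, seed=0
    )
    return truth, synth.gen_oct_volume(truth)


@pytest.fixture(scope="session")
def tendon_calibrant_pattern():
    """Tendon powder rings with an off-center beam, Poisson noise on."""
    truth = synth.SAXSPhantomTruth(
        calibrant="tendon_67nm", center_offset_px=(2.3, -1.7), seed=5
    )
    return truth, synth.gen_saxs_pattern(truth)


@pytest.fixture(scope="session")
def fiber_phantom_small():
    """Two-bin fiber stack, untilted, used by segmentation/binning tests."""
    truth = synth.FiberPhantomTruth(
        depth_fractions_pct=(0.64, 0.3), plane_tilt_deg=0.0, seed=3
    )
    return truth, synth.gen_fiber_stack(truth, (100, 128, 128))


def brute_force_radial_mean(counts, center, n_bins, r_max):
    """Per-pixel reference for annular means: floor(r/dr) binning, mean."""
    dr = r_max / n_bins
    sums = np.zeros(n_bins)
    npix = np.zeros(n_bins, dtype=int)
    for i in range(counts.shape[0]):
        for j in range(counts.shape[1]):
            r = np.hypot(i - center[0], j - center[1])
            b = int(np.floor(r / dr))
            if b < n_bins:
                sums[b] += counts[i, j]
                npix[b] += 1
    with np.errstate(invalid="ignore"):
        return np.where(npix > 0, sums / np.maximum(npix, 1), np.nan), npix
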