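"""OCT geometry: A-scan reconstruction, surface tracing, thickness, radius."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stromakit import oct, synth


class TestReconstructAscan:
    def test_flat_spectrum_zero_profile(self):
        lam = np.linspace(1.005, 1.075, 256)
        depths, mag = oct.reconstruct_ascan(np.ones(256), lam, window=False)
        assert np.allclose(mag, 0.0, atol=1e-9)

    def test_single_reflector_peak_scales_with_depth(self):
        def peak_bin(z):
            lam, spec = synth.gen_spectral_ascan([z], amplitudes=[1.0])
            _, mag = oct.reconstruct_ascan(spec, lam)
            return int(np.argmax(mag[3:]) + 3)

        b1, b2 = peak_bin(250.0), peak_bin(500.0)
        assert abs(b2 - 2 * b1) <= 1

    def test_two_reflector_profile_is_union_of_singles(self):
        lam, s1 = synth.gen_spectral_ascan([200.0])
        _, s2 = synth.gen_spectral_ascan([500.0])
        _, s12 = synth.gen_spectral_ascan([200.0, 500.0])
        _, m1 = oct.reconstruct_ascan(s1, lam)
        _, m2 = oct.reconstruct_ascan(s2, lam)
        _, m12 = oct.reconstruct_ascan(s12, lam)
        p1, p2 = np.argmax(m1[3:]) + 3, np.argmax(m2[3:]) + 3
        peaks12 = sorted(np.argsort(m12[3:])[-2:] + 3)
        assert abs(peaks12[0] - min(p1, p2)) <= 1
        assert abs(peaks12[1] - max(p1, p2)) <= 1

    def test_non_monotonic_grid_rejected(self):
        lam = np.linspace(1.0, 1.1, 64)
        lam[10] = lam[12]
        with pytest.raises(ValueError, match="monotonic"):
            oct.reconstruct_ascan(np.ones(64), lam)


class TestAverageCentralFrames:
    def test_count_one_returns_central_frame(self):
        rng = np.random.default_rng(0)
        vol = oct.OCTVolume(rng.random((5, 8, 8)).astype(float), 2.66, 3.09)
        assert np.array_equal(oct.average_central_frames(vol, 1), vol.intensity[2])

    def test_matches_brute_force_mean(self):
        rng = np.random.default_rng(1)
        data = rng.random((4, 6, 7))
        vol = oct.OCTVolume(data, 2.66, 3.09)
        out = oct.average_central_frames(vol, 4)
        expected = sum(data[i] for i in range(4)) / 4.0
        assert np.allclose(out, expected)

    def test_count_exceeding_frames_rejected(self):
        vol = oct.OCTVolume(np.ones((3, 4, 4)), 2.66, 3.09)
        with pytest.raises(ValueError):
            oct.average_central_frames(vol, 5)


class TestTraceSurfaces:
    def test_noiseless_phantom_traces_within_half_pixel_rms(
        self, oct_phantom_noiseless
    ):
        truth, vol = oct_phantom_noiseless
        image = oct.average_central_frames(vol, 10)
        traces = oct.trace_surfaces(image)
        n_lat = image.shape[1]
        x = (np.arange(n_lat) - (n_lat - 1) / 2.0) * truth.lateral_scale
        r_um = truth.radius_mm * 1000.0
        z_true = truth.apex_position_px + (
            r_um - np.sqrt(r_um**2 - x**2)
        ) / truth.axial_scale_air
        err = traces.anterior[traces.valid] - z_true[traces.valid]
        assert np.sqrt(np.mean(err**2)) < 0.5

    def test_flipped_image_gives_symmetric_result(self, oct_phantom_noiseless):
        _, vol = oct_phantom_noiseless
        image = oct.average_central_frames(vol, 10)
        t = oct.trace_surfaces(image)
        tf = oct.trace_surfaces(image[::-1], flip=True)
        both = t.valid & tf.valid
        assert np.allclose(t.anterior[both], tf.anterior[both], atol=1e-6)
        assert np.allclose(t.posterior[both], tf.posterior[both], atol=1e-6)

    def test_blank_image_rejected(self):
        with pytest.raises(ValueError, match="columns"):
            oct.trace_surfaces(np.zeros((64, 64)))


class TestThicknessMicrons:
    def test_stated_formula_example(self):
        # 100 px at 2.66 um/px in air, n = 1.4  ->  190 um
        assert oct.thickness_microns(100, 2.66, 1.4) == pytest.approx(190.0)

    def test_zero_pixels_zero_thickness(self):
        assert oct.thickness_microns(0, 2.66, 1.4) == 0.0

    @given(
        px=st.floats(1.0, 500.0),
        scale=st.floats(0.5, 10.0),
        c=st.floats(0.1, 5.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_linear_homogeneous_in_pixel_count(self, px, scale, c):
        n = 1.4
        one = oct.thickness_microns(px, scale, n)
        scaled = oct.thickness_microns(c * px, scale, n)
        assert scaled == pytest.approx(c * one, rel=1e-9)

    def test_invalid_index_rejected(self):
        with pytest.raises(ValueError):
            oct.thickness_microns(10, 2.66, 0.9)


class TestRadiusOfCurvature:
    def _arc_trace(self, r_um, axial_scale, lateral_scale, n_cols=901):
        # odd n_cols so the grid hits the apex and (for integer radii) the
        # equator columns x = +/-R exactly
        x = (np.arange(n_cols) - (n_cols - 1) / 2.0) * lateral_scale
        keep = np.abs(x) <= r_um
        z = np.full(n_cols, np.nan)
        z[keep] = (r_um - np.sqrt(np.maximum(r_um**2 - x[keep] ** 2, 0.0))) / axial_scale
        return z, keep

    def test_semicircle_with_h_equal_r_returns_r(self):
        r_um = 900.0
        z, keep = self._arc_trace(r_um, 1.0, 1.0, n_cols=2201)
        radius_mm, w = oct.radius_of_curvature(
            np.where(keep, z, np.nan), axial_scale_air=1.0, lateral_scale=1.0,
            sagitta_um=r_um, valid=keep, smooth_window=1,
        )
        assert radius_mm * 1000.0 == pytest.approx(r_um, rel=5e-3)
        assert w == pytest.approx(2.0 * r_um, rel=5e-3)

    def test_noiseless_arc_recovers_paper_scale_radius(self):
        r_um = 1940.0
        z, keep = self._arc_trace(r_um, 2.66, 3.09)
        radius_mm, w = oct.radius_of_curvature(
            z, axial_scale_air=2.66, lateral_scale=3.09, sagitta_um=300.0,
            valid=keep, smooth_window=1,
        )
        w_true = 2.0 * np.sqrt(2.0 * r_um * 300.0 - 300.0**2)
        assert w == pytest.approx(w_true, rel=5e-3)
        assert radius_mm == pytest.approx(1.94, rel=5e-3)

    def test_exact_on_noiseless_circles_for_any_sagitta(self):
        r_um = 1500.0
        z, keep = self._arc_trace(r_um, 1.0, 1.0, n_cols=3201)
        for h in (100.0, 300.0, 750.0, 1500.0):
            radius_mm, _ = oct.radius_of_curvature(
                z, axial_scale_air=1.0, lateral_scale=1.0, sagitta_um=h,
                valid=keep, smooth_window=1,
            )
            assert radius_mm * 1000.0 == pytest.approx(r_um, rel=5e-3)

    def test_trace_not_reaching_sagitta_rejected(self):
        z = np.linspace(0.0, 50.0, 200)  # shallow ramp, never 300 um deep
        with pytest.raises(ValueError, match="sagitta"):
            oct.radius_of_curvature(
                z, axial_scale_air=1.0, lateral_scale=1.0, sagitta_um=300.0
            )


class TestMeasureCornea:
    @pytest.mark.parametrize("n_tissue", [1.0, 1.4])
    def test_recovery_unbiased_for_refractive_index(self, n_tissue):
        truth = synth.OCTPhantomTruth(
            radius_mm=1.94, thickness_um=154.8, refractive_index=n_tissue,
            speckle_contrast=0.0, seed=2,
        )
        geom = oct.measure_cornea(synth.gen_oct_volume(truth))
        assert abs(geom.thickness_um - 154.8) < truth.axial_scale_air / n_tissue
        assert abs(geom.radius_mm - 1.94) / 1.94 < 0.005
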