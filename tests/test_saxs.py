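"""SAXS reduction: integration oracle, centering, calibration, Bragg peaks."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from stromakit import saxs, synth
from tests.conftest import brute_force_radial_mean

GEO = saxs.DetectorGeometry(0.1, 6000.0, 0.172, (15.5, 15.5))


def _pattern(counts, center=(15.5, 15.5), mask=None):
    geo = dataclasses.replace(GEO, beam_center=center)
    return saxs.ScatterPattern(counts=np.asarray(counts, float), geometry=geo, mask=mask)


class TestQMapping:
    def test_small_angle_and_exact_mapping_agree_at_camera_geometry(self):
        # at lambda = 0.1 nm and L = 6 m the exact arctan/sin mapping and the
        # small-angle approximation differ by < 1e-4 relative over the
        # corneal q-range (r up to ~200 px)
        geo = saxs.DetectorGeometry(0.1, 6000.0, 0.172, (0.0, 0.0))
        r = np.linspace(1.0, 200.0, 50)
        exact = geo.q_from_radius(r)
        small = 2.0 * np.pi * r * geo.pixel_pitch_mm / (geo.wavelength_nm * geo.distance_mm)
        assert np.max(np.abs(exact - small) / small) < 1e-4

    def test_radius_from_q_round_trips(self):
        q = GEO.q_from_radius(np.array([5.0, 50.0, 150.0]))
        assert np.allclose(GEO.radius_from_q(q), [5.0, 50.0, 150.0], rtol=1e-12)


class TestRadialIntegrate:
    def test_uniform_image_flat_profile(self):
        prof = saxs.radial_integrate(_pattern(np.full((32, 32), 7.0)), n_bins=10)
        assert np.allclose(prof.intensity, 7.0)

    def test_seven_by_seven_matches_brute_force_exactly(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 100, (7, 7)).astype(float)
        center = (3.2, 2.9)
        prof = saxs.radial_integrate(_pattern(counts, center), n_bins=5, r_max=6.0)
        expected, npix = brute_force_radial_mean(counts, center, 5, 6.0)
        present = npix > 0
        assert np.array_equal(prof.pixel_count, npix[present])
        assert np.array_equal(prof.intensity, expected[present])

    @given(
        counts=hnp.arrays(np.float64, (11, 13), elements=st.floats(0, 1000)),
        row=st.floats(2.0, 9.0),
        col=st.floats(2.0, 11.0),
    )
    @settings(max_examples=25, deadline=None)
    def test_any_small_image_matches_brute_force(self, counts, row, col):
        prof = saxs.radial_integrate(_pattern(counts, (row, col)), n_bins=6, r_max=9.0)
        expected, npix = brute_force_radial_mean(counts, (row, col), 6, 9.0)
        present = npix > 0
        assert np.array_equal(prof.intensity, expected[present])

    def test_total_counts_conserved(self):
        rng = np.random.default_rng(1)
        counts = rng.random((24, 24))
        prof = saxs.radial_integrate(_pattern(counts, (11.5, 11.5)))
        assert np.sum(prof.intensity * prof.pixel_count) == pytest.approx(
            counts.sum(), rel=1e-12
        )

    def test_masked_pixels_excluded(self):
        counts = np.full((16, 16), 3.0)
        mask = np.zeros((16, 16), bool)
        mask[0:2] = True
        counts[0:2] = 1e6  # poisoned rows must not contribute
        prof = saxs.radial_integrate(_pattern(counts, (7.5, 7.5), mask=mask), n_bins=6)
        assert np.allclose(prof.intensity, 3.0)

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError, match="bins"):
            saxs.radial_integrate(_pattern(np.ones((8, 8))), n_bins=3)


class TestFindBeamCenter:
    def test_recovers_true_center_within_tolerance(self, tendon_calibrant_pattern):
        truth, pattern = tendon_calibrant_pattern
        center = saxs.find_beam_center(pattern)
        assert abs(center[0] - truth.beam_center_true[0]) < 0.2
        assert abs(center[1] - truth.beam_center_true[1]) < 0.2

    def test_translation_equivariance(self, tendon_calibrant_pattern):
        truth, pattern = tendon_calibrant_pattern
        c0 = saxs.find_beam_center(pattern)
        shifted = dataclasses.replace(
            pattern, counts=np.roll(pattern.counts, (3, -2), axis=(0, 1))
        )
        c1 = saxs.find_beam_center(shifted, initial=(c0[0] + 3, c0[1] - 2))
        assert c1[0] - c0[0] == pytest.approx(3.0, abs=1e-9)
        assert c1[1] - c0[1] == pytest.approx(-2.0, abs=1e-9)

    def test_noiseless_ring_variance_vanishes_at_center(self):
        truth = synth.SAXSPhantomTruth(
            calibrant="tendon_67nm", n_orders=1, noise=False, bg_amplitude=0.0
        )
        pattern = synth.gen_saxs_pattern(truth)
        center = saxs.find_beam_center(pattern)
        assert abs(center[0] - 191.5) < 0.06 and abs(center[1] - 191.5) < 0.06

    def test_featureless_image_rejected(self):
        with pytest.raises(ValueError, match="ring"):
            saxs.find_beam_center(_pattern(np.full((40, 40), 5.0), (19.5, 19.5)))


class TestCalibrateQ:
    def _tendon_profile(self, seed=5, offset=(0.0, 0.0)):
        truth = synth.SAXSPhantomTruth(
            calibrant="tendon_67nm", center_offset_px=offset, seed=seed
        )
        pattern = synth.gen_saxs_pattern(truth)
        return saxs.radial_integrate(pattern, center=truth.beam_center_true)

    def test_exact_geometry_matches_nominal_mapping(self):
        prof = self._tendon_profile()
        cal = saxs.calibrate_q(prof, 67.0, geometry=GEO)
        r1 = GEO.radius_from_q(2.0 * np.pi / 67.0)
        k_nominal = GEO.q_from_radius(r1) / r1
        assert cal.k == pytest.approx(k_nominal, rel=1e-3)

    def test_single_order_closed_form(self):
        prof = self._tendon_profile()
        cal = saxs.calibrate_q(prof, 67.0, orders=(1,), geometry=GEO)
        assert cal.k == pytest.approx(2.0 * np.pi / (67.0 * cal.radii_px[0]), rel=1e-12)

    def test_no_usable_orders_rejected(self):
        flat = saxs.RadialProfile(
            q=np.linspace(0.01, 0.3, 50), intensity=np.full(50, 2.0),
            pixel_radius=np.linspace(1, 150, 50), pixel_count=np.full(50, 10),
        )
        with pytest.raises(ValueError):
            saxs.calibrate_q(flat, 67.0, geometry=GEO)


class TestBackgroundSubtraction:
    def _power_profile(self, A=100.0, b=3.0, n=80):
        q = np.linspace(0.02, 0.4, n)
        return saxs.RadialProfile(
            q=q, intensity=A * q**-b, pixel_radius=q / 0.00186,
            pixel_count=np.full(n, 20),
        )

    def test_pure_power_law_removed_to_float_precision(self):
        prof = self._power_profile()
        out = saxs.subtract_background(prof, exclude_windows=[(0.1, 0.15)])
        assert np.max(np.abs(out.intensity)) < 1e-6 * np.max(prof.intensity)
        A, b = out.background
        assert A == pytest.approx(100.0, rel=1e-9)
        assert b == pytest.approx(3.0, rel=1e-9)

    def test_eight_fit_bins_suffice_fewer_reject(self):
        prof = self._power_profile(n=30)
        ok_window = [(prof.q[8] - 1e-9, prof.q[-1] + 1)]  # leaves exactly 8 bins
        out = saxs.subtract_background(prof, ok_window)
        assert out.background[1] == pytest.approx(3.0, rel=1e-6)
        with pytest.raises(ValueError, match="bins"):
            saxs.subtract_background(prof, [(prof.q[7] - 1e-9, prof.q[-1] + 1)])

    def test_nonpositive_intensities_rejected(self):
        prof = self._power_profile()
        dead_tail = prof.intensity.copy()
        dead_tail[-5:] = 0.0
        bad = dataclasses.replace(prof, intensity=dead_tail)
        with pytest.raises(ValueError, match="log"):
            saxs.subtract_background(bad, [])


class TestLocatePeak:
    def _profile(self, intensity):
        n = len(intensity)
        q = np.linspace(0.05, 0.15, n)
        return saxs.RadialProfile(
            q=q, intensity=np.asarray(intensity, float),
            pixel_radius=q / 0.00186, pixel_count=np.full(n, 10),
        )

    def test_symmetric_triangle_returns_midpoint(self):
        prof = self._profile([0, 1, 2, 3, 2, 1, 0])
        res = saxs.locate_peak(prof, (prof.q[0], prof.q[-1]))
        assert res.q_peak == pytest.approx(prof.q[3], rel=1e-9)

    def test_higher_second_peak_wins_tie_goes_low(self):
        prof = self._profile([0, 2, 0, 0, 3, 0, 0])
        res = saxs.locate_peak(prof, (prof.q[0], prof.q[-1]))
        assert abs(res.q_peak - prof.q[4]) < (prof.q[1] - prof.q[0])
        tie = self._profile([0, 3, 0, 0, 3, 0, 0])
        res_tie = saxs.locate_peak(tie, (tie.q[0], tie.q[-1]))
        assert abs(res_tie.q_peak - tie.q[1]) < (tie.q[1] - tie.q[0])

    def test_no_positive_maximum_rejected(self):
        prof = self._profile([-1, -2, -3, -2, -4, -5, -6])
        with pytest.raises(ValueError, match="maximum"):
            saxs.locate_peak(prof, (prof.q[0], prof.q[-1]))


class TestBraggSpacing:
    @pytest.mark.parametrize(
        "q,expected", [(2.0 * np.pi / 65.0, 65.0), (0.1, 62.832)]
    )
    def test_spacing_arithmetic(self, q, expected):
        assert saxs.bragg_spacing(q) == pytest.approx(expected, abs=5e-4)

    def test_monotone_decreasing_in_q(self):
        qs = np.linspace(0.05, 0.2, 10)
        ds = [saxs.bragg_spacing(q) for q in qs]
        assert np.all(np.diff(ds) < 0)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            saxs.bragg_spacing(0.0)


class TestDPeriod:
    def test_exact_orders_give_exact_period(self):
        q = {m: 2.0 * np.pi * m / 65.0 for m in (1, 2, 3)}
        D, resid = saxs.measure_d_period(q)
        assert D == pytest.approx(65.0, rel=1e-12)
        assert all(abs(r) < 1e-12 for r in resid.values())

    def test_single_order_closed_form(self):
        D, _ = saxs.measure_d_period({1: 0.095})
        assert D == pytest.approx(2.0 * np.pi / 0.095, rel=1e-12)

    def test_perturbed_orders_recovered_within_half_percent(self):
        rng = np.random.default_rng(3)
        q = {m: 2.0 * np.pi * m / 65.0 * (1 + rng.uniform(-3e-3, 3e-3)) for m in (1, 2, 3)}
        D, _ = saxs.measure_d_period(q)
        assert abs(D - 65.0) / 65.0 < 5e-3

    def test_misassigned_orders_rejected(self):
        q = {1: 0.09, 2: 0.30, 3: 0.28}
        with pytest.raises(ValueError, match="order"):
            saxs.measure_d_period(q)


class TestTransect:
    def _u_transect(self, d_values, seed=20):
        patterns = []
        for i, d in enumerate(d_values):
            truth = synth.SAXSPhantomTruth(d_nm=d, seed=seed + i)
            pat = synth.gen_saxs_pattern(truth)
            patterns.append(
                dataclasses.replace(pat, transect_position_mm=0.2 * i)
            )
        return patterns

    def test_u_profile_center_and_periphery_labels(self):
        d_true = [80.0, 72.0, 66.0, 63.7, 65.0, 73.0, 79.0]
        table, summary = saxs.analyze_transect(self._u_transect(d_true))
        assert summary["center_position_mm"] == pytest.approx(0.6)
        assert abs(summary["center_ifs_nm"] - 63.7) < 0.5
        peri_true = np.mean([80.0, 72.0, 73.0, 79.0])
        assert abs(summary["peripheral_ifs_nm"] - peri_true) < 0.5
        assert summary["percent_increase"] > 15.0

    def test_constant_transect_zero_percent_increase(self):
        table, summary = saxs.analyze_transect(self._u_transect([68.0] * 5, seed=40))
        assert abs(summary["percent_increase"]) < 0.5

    def test_two_positions_rejected(self):
        with pytest.raises(ValueError, match="3 positions"):
            saxs.analyze_transect(self._u_transect([65.0, 70.0], seed=60))
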