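import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import vitaxrd as vx
from vitaxrd.exceptions import (
    AmbiguousOrderAssignment,
    DomainError,
    EmptyFrame,
    NoDefinedCenter,
    NoRingsFound,
)
from vitaxrd.geometry import load_agbh, max_q


class TestQFromD:
    def test_inter_fatty_acid_spacing(self):
        # d = 0.45204 nm is the real-space periodicity of the 13.9 nm⁻¹ peak
        assert vx.q_from_d(0.45204) == pytest.approx(13.90, abs=0.005)

    def test_agbh_first_order(self):
        assert vx.q_from_d(5.8380) == pytest.approx(1.0762, abs=5e-4)

    def test_large_d_limit(self):
        assert vx.q_from_d(1e6) == pytest.approx(0.0, abs=1e-5)

    def test_rejects_nonpositive(self):
        with pytest.raises(DomainError):
            vx.q_from_d(0.0)


class TestPixelToQ:
    def test_zero_radius_both_modes(self, geom16):
        for mode in ("paper_sin", "exact_tan"):
            g = vx.BeamGeometry(128, 128, 160.0, mapping_mode=mode)
            assert vx.pixel_to_q(0.0, g) == 0.0

    def test_r_equals_D_paper_sin(self):
        # sin 2θ = 1 → 2θ = 90°, q = 4π sin(45°)/0.154 = 57.70 nm⁻¹
        g = vx.BeamGeometry(128, 128, 160.0, mapping_mode="paper_sin")
        assert vx.pixel_to_q(160.0, g) == pytest.approx(57.70, abs=0.005)

    def test_small_angle_modes_agree(self):
        gs = vx.BeamGeometry(128, 128, 100.0, mapping_mode="paper_sin")
        gt = vx.BeamGeometry(128, 128, 100.0, mapping_mode="exact_tan")
        qs, qt = vx.pixel_to_q(1.0, gs), vx.pixel_to_q(1.0, gt)
        assert qs == pytest.approx(qt, rel=1e-4)

    def test_domain_error_beyond_D(self):
        g = vx.BeamGeometry(128, 128, 20.0, mapping_mode="paper_sin")
        with pytest.raises(DomainError):
            vx.pixel_to_q(25.0, g)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(r=st.floats(0.0, 15.0), mode=st.sampled_from(["paper_sin", "exact_tan"]))
    def test_inverse_round_trip(self, r, mode):
        g = vx.BeamGeometry(128, 128, 20.0, mapping_mode=mode)
        q = vx.pixel_to_q(r, g)
        assert vx.q_to_radius_mm(q, g) == pytest.approx(r, rel=1e-9, abs=1e-9)

    def test_strictly_monotone(self):
        g = vx.BeamGeometry(128, 128, 20.0)
        r = np.linspace(0, 14, 500)
        q = vx.pixel_to_q(r, g)
        assert np.all(np.diff(q) > 0)


class TestFindBeamCenter:
    def test_recovers_centered_beam(self, frame16):
        est = vx.find_beam_center(frame16)
        assert abs(est.row - 128.0) < 0.5 and abs(est.col - 128.0) < 0.5

    def test_recovers_off_center_beam(self, geom2, detector):
        model = vx.default_templates()[("2cm", "non-cancer")]
        counts = vx.render_frame(model, geom2, detector, 2e6, rng=4)
        est = vx.find_beam_center(vx.DetectorImage(counts))
        assert abs(est.row - 128.0) < 0.5 and abs(est.col - 52.0) < 0.5

    def test_all_zero_frame_is_empty(self):
        with pytest.raises(EmptyFrame):
            vx.find_beam_center(vx.DetectorImage(np.zeros((256, 256), int)))

    def test_translation_equivariance(self, frame16):
        base = vx.find_beam_center(frame16)
        shifted = np.roll(np.roll(frame16.counts, 3, axis=0), -2, axis=1)
        est = vx.find_beam_center(vx.DetectorImage(shifted))
        assert est.row - base.row == pytest.approx(3.0, abs=0.5)
        assert est.col - base.col == pytest.approx(-2.0, abs=0.5)

    def test_flat_noise_has_no_center(self):
        rng = np.random.default_rng(42)
        flat = rng.poisson(20.0, size=(256, 256))
        with pytest.raises(NoDefinedCenter):
            vx.find_beam_center(vx.DetectorImage(flat))


class TestCalibration:
    @pytest.mark.parametrize("mode", ["paper_sin", "exact_tan"])
    @pytest.mark.parametrize("D,center,tol", [(160.0, (128.0, 128.0), 0.005),
                                              (20.0, (128.0, 52.0), 0.01)])
    def test_distance_round_trip(self, detector, mode, D, center, tol):
        agbh = load_agbh()
        g = vx.BeamGeometry(center[0], center[1], D, mapping_mode=mode)
        counts = vx.render_calibrant_frame(agbh, g, detector, rng=3,
                                           photon_budget=2e6)
        img = vx.DetectorImage(counts)
        est = vx.find_beam_center(img)
        cal = vx.calibrate_distance(img, agbh, (est.row, est.col), detector,
                                    mapping_mode=mode)
        assert cal.distance_mm == pytest.approx(D, rel=tol)

    def test_first_ring_radius_matches_inverse_map(self, geom16, detector):
        agbh = load_agbh()
        counts = vx.render_calibrant_frame(agbh, geom16, detector, rng=5,
                                           photon_budget=2e6)
        cal = vx.calibrate_distance(vx.DetectorImage(counts), agbh,
                                    (128.0, 128.0), detector)
        r_expect = vx.q_to_radius_mm(vx.q_from_d(5.8380), geom16)
        r_found = cal.ring_radii_px[0] * detector.pixel_pitch_mm
        assert r_found == pytest.approx(r_expect, rel=0.02)

    def test_first_ring_radius_doubles_with_distance(self, detector):
        # small-angle regime: r ≈ D·2θ, so doubling D doubles the radius
        agbh = load_agbh()
        radii = {}
        for D in (80.0, 160.0):
            g = vx.BeamGeometry(128.0, 128.0, D)
            counts = vx.render_calibrant_frame(agbh, g, detector, rng=6,
                                               photon_budget=2e6)
            cal = vx.calibrate_distance(vx.DetectorImage(counts), agbh,
                                        (128.0, 128.0), detector)
            radii[D] = cal.ring_radii_px[0]
        assert radii[160.0] / radii[80.0] == pytest.approx(2.0, rel=0.03)

    def test_background_only_frame_has_no_rings(self, geom16, detector):
        model = vx.RingModel(background_amplitude=1.0, background_scale=1.0)
        counts = vx.render_frame(model, geom16, detector, 2e6, rng=7)
        with pytest.raises((NoRingsFound, AmbiguousOrderAssignment)):
            vx.calibrate_distance(vx.DetectorImage(counts), load_agbh(),
                                  (128.0, 128.0), detector)


def test_max_q_grows_when_distance_shrinks(detector):
    q2 = max_q(vx.BeamGeometry(128, 128, 20.0), detector)
    q16 = max_q(vx.BeamGeometry(128, 128, 160.0), detector)
    assert q2 > 5 * q16
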