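import numpy as np
import pytest

from sonoquant.datatypes import CineLoop, Ecg, LVTrace
from sonoquant.errors import TrackingError
from sonoquant.cardiac import (
    area_length_volume,
    heart_rate,
    lv_metrics,
    speckle_track,
    strain_curves,
)
from sonoquant.phantom import PhantomTruth, make_ecg, make_lv_cine, make_lv_contour_trace, speckle_field


def rect_contour(width, height, n_side=8):
    """Rectangle traced as an ordered point loop (long axis = x)."""
    xs = np.linspace(-width / 2, width / 2, n_side)
    ys = np.linspace(-height / 2, height / 2, n_side)
    top = np.column_stack([xs, np.full(n_side, height / 2)])
    right = np.column_stack([np.full(n_side, width / 2), ys[::-1]])
    bottom = np.column_stack([xs[::-1], np.full(n_side, -height / 2)])
    left = np.column_stack([np.full(n_side, -width / 2), ys])
    return np.vstack([top[:-1], right[:-1], bottom[:-1], left[:-1]])


def rect_trace(vol_d, vol_s, width=5.0, hr_frames=3):
    """Two-phase rectangular 'contours' with exact area-length volumes."""
    def height_for(v):
        return float(np.sqrt(v * 3 * np.pi / (8 * width)))

    h_d, h_s = height_for(vol_d), height_for(vol_s)
    contours = [rect_contour(width, h_d), rect_contour(width, h_s),
                rect_contour(width, h_d)]
    return LVTrace(time=np.arange(3) * 0.1, endo=contours,
                   long_axis_mm=np.full(3, width))


class TestLVMetrics:
    def test_constructed_volumes_exact(self):
        m = lv_metrics(rect_trace(50.0, 25.0), hr_bpm=400.0)
        assert m.edv_ul == pytest.approx(50.0, abs=1e-9)
        assert m.esv_ul == pytest.approx(25.0, abs=1e-9)
        assert m.sv_ul == pytest.approx(25.0, abs=1e-9)
        assert m.ef_pct == pytest.approx(50.0, abs=1e-9)

    def test_co_unit_conversion(self):
        m = lv_metrics(rect_trace(90.0, 50.0), hr_bpm=400.0)
        assert m.sv_ul == pytest.approx(40.0, abs=1e-9)
        assert m.co_ml_min == pytest.approx(16.0, abs=1e-9)

    def test_fs_from_mid_cavity_chord(self):
        m = lv_metrics(rect_trace(50.0, 25.0), hr_bpm=400.0)
        # rectangle chord = height; V ~ h^2 so h_s/h_d = sqrt(1/2)
        assert m.fs_pct == pytest.approx(100 * (1 - np.sqrt(0.5)), rel=1e-9)

    def test_ellipsoid_volume_within_2pct(self):
        trace = make_lv_contour_trace(edv_ul=50.0, esv_ul=25.0)
        m = lv_metrics(trace, hr_bpm=400.0)
        assert m.edv_ul == pytest.approx(50.0, rel=0.02)
        assert m.esv_ul == pytest.approx(25.0, rel=0.02)

    def test_lv_mass_positive_and_zero_iff_no_wall(self):
        trace = make_lv_contour_trace(edv_ul=50.0, esv_ul=25.0)
        m = lv_metrics(trace, hr_bpm=400.0)
        assert m.lv_mass_mg > 0
        degenerate = LVTrace(time=trace.time, endo=trace.endo, epi=trace.endo,
                             long_axis_mm=trace.long_axis_mm)
        assert lv_metrics(degenerate, hr_bpm=400.0).lv_mass_mg == pytest.approx(0.0,
                                                                               abs=1e-9)

    def test_ef_scale_invariance(self):
        trace = make_lv_contour_trace(edv_ul=50.0, esv_ul=25.0)
        scaled = LVTrace(time=trace.time, endo=[c * 2.0 for c in trace.endo],
                         long_axis_mm=trace.long_axis_mm * 2.0)
        m1 = lv_metrics(trace, hr_bpm=400.0)
        m2 = lv_metrics(scaled, hr_bpm=400.0)
        assert m1.ef_pct == pytest.approx(m2.ef_pct, rel=1e-9)

    def test_nonpositive_hr_rejected(self):
        with pytest.raises(ValueError):
            lv_metrics(rect_trace(50.0, 25.0), hr_bpm=0.0)


class TestSpeckleTrack:
    def _translating_loop(self, step_px=2.0, n=8, shape=(100, 100)):
        from scipy.ndimage import shift as ndshift

        tex = 200 * speckle_field(shape, np.random.default_rng(0), 1.5)
        frames = [ndshift(tex, (0, step_px * i), order=3, mode="wrap")
                  for i in range(n)]
        return CineLoop(frames=np.asarray(frames), pixel_spacing=(0.05, 0.05),
                        frame_rate=100.0, view="SAX")

    def test_rigid_translation_slope(self):
        loop = self._translating_loop(step_px=2.0)
        pts = np.array([[-1.0, -1.0], [0.5, 0.3], [-0.5, 1.0], [0.0, 0.0]])
        traj = speckle_track(loop, pts)
        steps = np.diff(traj[:, :, 0], axis=1) / 0.05
        assert np.all(np.abs(steps - 2.0) < 0.1)

    def test_static_sequence_zero_displacement(self):
        tex = 200 * speckle_field((80, 80), np.random.default_rng(1), 1.5)
        loop = CineLoop(frames=np.repeat(tex[None], 6, axis=0),
                        pixel_spacing=(0.05, 0.05), frame_rate=100.0, view="SAX")
        traj = speckle_track(loop, np.array([[0.0, 0.0], [0.5, -0.5]]))
        disp = np.linalg.norm(traj - traj[:, :1], axis=2) / 0.05
        assert disp.max() < 0.1

    def test_phantom_field_within_third_pixel(self):
        truth = PhantomTruth(seed=2, true_strain={"radial": 0.20})
        ph = make_lv_cine(truth, frame_rate=150)
        true_traj = np.stack(ph.contours["endo"], axis=1)
        traj = speckle_track(ph.loop, ph.contours["endo"][0], block_px=11,
                             search_px=5)
        err_px = np.linalg.norm(traj - true_traj, axis=2) / 0.05
        assert err_px.mean() < 0.3

    def test_featureless_loop_raises(self):
        frames = np.full((5, 60, 60), 50.0)
        loop = CineLoop(frames=frames, pixel_spacing=(0.05, 0.05),
                        frame_rate=100.0, view="SAX")
        with pytest.raises(TrackingError):
            speckle_track(loop, np.array([[0.0, 0.0], [0.3, 0.3]]))

    def test_seed_block_outside_frame_raises(self):
        loop = self._translating_loop(n=3)
        with pytest.raises(TrackingError):
            speckle_track(loop, np.array([[2.6, 0.0]]))  # 52 px off a 50 px half


class TestStrainCurves:
    def _ring_trajectories(self, scales, radius=1.5, n_pts=24):
        theta = np.linspace(0, 2 * np.pi, n_pts, endpoint=False)
        ring = np.column_stack([radius * np.cos(theta), radius * np.sin(theta)])
        return np.stack([ring * s for s in scales], axis=1)  # (P, T, 2)

    def test_global_peak_is_mean_of_segment_peaks(self):
        traj = self._ring_trajectories([1.0, 1.1, 1.2, 1.1])
        res = strain_curves(traj, "circumferential", frame_rate=100.0)
        assert res.global_strain == pytest.approx(res.segment_peaks.mean(), abs=1e-12)
        assert np.allclose(res.segment_strain[:, 0], 0.0)

    def test_lagrangian_composition_21pct(self):
        # 10% then another 10% composes to 1.1*1.1 - 1 = 21% vs frame 0
        traj = self._ring_trajectories([1.0, 1.1, 1.21])
        res = strain_curves(traj, "circumferential", frame_rate=100.0)
        assert np.allclose(res.segment_strain[:, 1], 10.0, atol=1e-9)
        assert np.allclose(res.segment_strain[:, 2], 21.0, atol=1e-9)

    def test_radial_needs_pair(self):
        traj = self._ring_trajectories([1.0, 1.1])
        with pytest.raises(ValueError):
            strain_curves(traj, "radial", frame_rate=100.0)

    def test_unknown_direction_rejected(self):
        traj = self._ring_trajectories([1.0, 1.1])
        with pytest.raises(ValueError):
            strain_curves(traj, "torsional", frame_rate=100.0)

    def test_too_few_points_per_segment(self):
        traj = self._ring_trajectories([1.0, 1.1], n_pts=6)
        with pytest.raises(ValueError):
            strain_curves(traj, "circumferential", frame_rate=100.0)

    def test_strain_rate_is_derivative(self):
        traj = self._ring_trajectories([1.0, 1.05, 1.1, 1.15])
        res = strain_curves(traj, "circumferential", frame_rate=100.0)
        # linear 5%-per-frame growth at 100 fps -> 5 /s constant rate
        assert res.segment_strain_rate[:, 1] == pytest.approx(5.0, rel=0.01)


class TestStrainRecovery:
    @pytest.mark.parametrize("peak", [0.10, 0.30])
    def test_radial_thickening_recovery(self, peak):
        truth = PhantomTruth(seed=2, true_strain={"radial": peak})
        ph = make_lv_cine(truth, frame_rate=150)
        endo = speckle_track(ph.loop, ph.contours["endo"][0], block_px=11, search_px=5)
        epi = speckle_track(ph.loop, ph.contours["epi"][0], block_px=11, search_px=5)
        res = strain_curves(endo, "radial", frame_rate=ph.loop.frame_rate,
                            pair_trajectories_mm=epi)
        assert res.global_strain == pytest.approx(100 * peak, abs=2.0)
        assert res.global_strain > 0  # thickening positive

    def test_circumferential_shortening_recovery(self):
        truth = PhantomTruth(seed=2, true_strain={"circumferential": -0.20})
        ph = make_lv_cine(truth, frame_rate=150)
        mid = speckle_track(ph.loop, ph.contours["mid"][0], block_px=11, search_px=5)
        res = strain_curves(mid, "circumferential", frame_rate=ph.loop.frame_rate)
        assert res.global_strain == pytest.approx(-20.0, abs=2.0)
        assert res.global_strain < 0  # shortening negative

    def test_longitudinal_shortening_recovery(self):
        truth = PhantomTruth(seed=2, true_strain={"longitudinal": -0.15})
        ph = make_lv_cine(truth, view="PLAX", frame_rate=150)
        mid = speckle_track(ph.loop, ph.contours["mid"][0], block_px=11, search_px=5)
        res = strain_curves(mid, "longitudinal", frame_rate=ph.loop.frame_rate)
        assert res.global_strain == pytest.approx(-15.0, abs=2.0)

    def test_zero_motion_zero_strain(self):
        truth = PhantomTruth(seed=2, true_strain={})
        ph = make_lv_cine(truth, frame_rate=150)
        endo = speckle_track(ph.loop, ph.contours["endo"][0], block_px=11, search_px=5)
        epi = speckle_track(ph.loop, ph.contours["epi"][0], block_px=11, search_px=5)
        res = strain_curves(endo, "radial", frame_rate=ph.loop.frame_rate,
                            pair_trajectories_mm=epi)
        assert np.abs(res.segment_strain).max() < 0.5
        assert np.abs(res.segment_strain_rate).max() < 0.5


class TestHeartRate:
    def test_impulse_ecg_300bpm(self):
        assert heart_rate(make_ecg(1.05, hr_bpm=300.0)) == pytest.approx(300.0,
                                                                         rel=1e-6)

    def test_wt_median_spacing(self):
        samples = np.zeros(3001)
        for k in range(18):
            samples[int(round(k * 158.7))] = 1.0  # 158.7 ms at 1 kHz
        hr = heart_rate(Ecg(samples=samples, sample_rate=1000.0))
        assert hr == pytest.approx(60.0 / 0.1587, rel=0.005)

    def test_jittered_intervals_median_rule(self):
        samples = np.zeros(1000)
        for t_ms in (0, 190, 390, 600):  # gaps 190, 200, 210 ms
            samples[t_ms] = 1.0
        assert heart_rate(Ecg(samples=samples, sample_rate=1000.0)) \
            == pytest.approx(300.0, rel=1e-9)

    def test_cine_periodicity_fallback(self, noiseless_vessel):
        _, loop, _ = noiseless_vessel
        assert heart_rate(loop) == pytest.approx(300.0, rel=0.05)

    def test_single_beat_raises(self):
        samples = np.zeros(500)
        samples[100] = 1.0
        with pytest.raises(ValueError):
            heart_rate(Ecg(samples=samples, sample_rate=1000.0))


class TestAreaLengthVolume:
    def test_closed_form_ellipse(self):
        theta = np.linspace(0, 2 * np.pi, 512, endpoint=False)
        a, b = 4.0, 2.0
        contour = np.column_stack([a * np.cos(theta), b * np.sin(theta)])
        v = area_length_volume(contour, long_axis_mm=2 * a)
        assert v == pytest.approx(4.0 / 3.0 * np.pi * a * b ** 2, rel=1e-3)

    def test_degenerate_contour_rejected(self):
        line = np.column_stack([np.linspace(0, 1, 10), np.zeros(10)])
        with pytest.raises(ValueError):
            area_length_volume(line, long_axis_mm=1.0)
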