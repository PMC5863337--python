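import numpy as np
import pytest

from sonoquant.datatypes import CineLoop, Spectrogram
from sonoquant.errors import AliasingError, SizingError
from sonoquant.phantom import (
    DiameterWaveform,
    MitralWaveform,
    NoiseSpec,
    PhantomTruth,
    PulsatileWaveform,
    make_coupled_vessel,
    make_doppler_trace,
    make_ecg,
    make_liver_kidney_image,
    make_lv_cine,
    make_vessel_cine,
    nyquist_velocity,
    speckle_field,
)
from sonoquant.doppler import renal_indices
from sonoquant.steatosis import roi_mean, steatoscore


class TestTruthSpecs:
    def test_ds_below_dd_rejected(self):
        with pytest.raises(ValueError):
            DiameterWaveform(dd_mm=1.2, ds_mm=1.0)

    def test_nonpositive_period_rejected(self):
        with pytest.raises(ValueError):
            DiameterWaveform(period_s=0.0)

    def test_gray_means_bounded(self):
        with pytest.raises(ValueError):
            PhantomTruth(gray_means=(120.0, 300.0))

    def test_nonpositive_pwv_rejected(self):
        with pytest.raises(ValueError):
            PhantomTruth(true_pwv_m_s=0.0)

    def test_diameter_waveform_extremes(self):
        w = DiameterWaveform(dd_mm=1.0, ds_mm=1.2, period_s=0.2, upstroke_fraction=0.25)
        t = np.linspace(0, 0.2, 20001)
        d = w(t)
        assert d.min() == pytest.approx(1.0, abs=1e-12)
        assert d.max() == pytest.approx(1.2, abs=1e-9)
        # periodic
        assert w(0.0) == pytest.approx(w(0.2), abs=1e-12)

    def test_pulsatile_mean_hits_mv_target(self):
        w = PulsatileWaveform(psv_mm_s=120, edv_mm_s=40, mv_mm_s=80)
        t = np.linspace(0, w.period_s, 200001, endpoint=False)
        assert w(t).mean() == pytest.approx(80.0, rel=1e-4)
        assert w(t).max() == pytest.approx(120.0, abs=1e-6)
        assert w(t).min() == pytest.approx(40.0, abs=1e-12)

    def test_pulsatile_mv_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            PulsatileWaveform(psv_mm_s=120, edv_mm_s=40, mv_mm_s=130)

    def test_mitral_peaks(self):
        w = MitralWaveform(e_mm_s=800, a_mm_s=400)
        t = np.linspace(0, w.period_s, 100001)
        v = w(t)
        assert v.max() == pytest.approx(800.0, rel=1e-6)
        assert v.min() >= 0.0


class TestVesselCine:
    def test_systolic_band_separation_matches_geometry(self):
        # Dd=1.0, Ds=1.2 mm at 0.02 mm/px -> 60 px center separation in systole
        truth = PhantomTruth(seed=0, diameter=DiameterWaveform(dd_mm=1.0, ds_mm=1.2))
        loop, ref = make_vessel_cine(truth)
        i_sys = int(np.argmax(ref.diameter))
        frame = loop.frames[i_sys]
        col = frame[:, frame.shape[1] // 2]
        # centroid of each band above background
        rows = np.arange(col.size)
        top = col[: col.size // 2]
        bot = col[col.size // 2:]
        c_top = np.average(rows[: col.size // 2], weights=np.maximum(top - top.min(), 0))
        c_bot = np.average(rows[col.size // 2:], weights=np.maximum(bot - bot.min(), 0))
        assert c_bot - c_top == pytest.approx(60.0, abs=0.1)

    def test_static_vessel_reference_constant(self, static_vessel):
        _, _, ref = static_vessel
        assert np.ptp(ref.diameter) == 0.0
        b = ref.beats[0]
        assert 100.0 * (b.ds_mm - b.dd_mm) / b.dd_mm == 0.0

    def test_determinism_same_seed_bit_identical(self):
        spec = dict(seed=7, diameter=DiameterWaveform(dd_mm=0.9, ds_mm=1.05),
                    noise=NoiseSpec(speckle=0.4, additive=3.0))
        loop1, _ = make_vessel_cine(PhantomTruth(**spec))
        loop2, _ = make_vessel_cine(PhantomTruth(**spec))
        assert loop1.frames.tobytes() == loop2.frames.tobytes()

    def test_oversized_vessel_raises_sizing_error(self):
        truth = PhantomTruth(diameter=DiameterWaveform(dd_mm=3.0, ds_mm=3.5))
        with pytest.raises(SizingError):
            make_vessel_cine(truth)  # 3.5 mm at 0.02 mm/px > 160 px frame

    def test_reference_trace_is_analytic_evaluation(self, noiseless_vessel):
        truth, loop, ref = noiseless_vessel
        assert np.allclose(ref.diameter, truth.diameter(loop.times), atol=0)

    def test_ecg_spans_loop(self, noiseless_vessel):
        _, loop, _ = noiseless_vessel
        assert loop.ecg.duration >= loop.duration


class TestCoupledVessel:
    def test_envelope_peak_matches_loop_relation(self):
        # V_peak = 2 * 2000 * ln(1.1) ~= 381.2 mm/s
        truth = PhantomTruth(seed=0, true_pwv_m_s=2.0,
                             diameter=DiameterWaveform(dd_mm=1.0, ds_mm=1.1))
        _, spec, _, vref = make_coupled_vessel(truth)
        expected = 2.0 * 2.0 * 1000.0 * np.log(1.1)
        assert vref.psv == pytest.approx(expected, rel=1e-6)
        assert isinstance(spec, Spectrogram)

    def test_static_diameter_gives_zero_velocity(self):
        truth = PhantomTruth(seed=0, true_pwv_m_s=3.0,
                             diameter=DiameterWaveform(dd_mm=1.0, ds_mm=1.0))
        _, _, _, vref = make_coupled_vessel(truth)
        assert np.allclose(vref.velocity, 0.0)


class TestLVCine:
    def test_radial_thickening_truth_by_construction(self):
        truth = PhantomTruth(seed=3, true_strain={"radial": 0.30})
        ph = make_lv_cine(truth, frame_rate=125)
        assert ph.true_strain["radial"] == pytest.approx(30.0, abs=1e-9)

    def test_zero_deformation_zero_truth(self):
        truth = PhantomTruth(seed=3, true_strain={})
        ph = make_lv_cine(truth, frame_rate=125)
        assert all(abs(v) < 1e-12 for v in ph.true_strain.values())
        assert np.ptp(ph.loop.frames, axis=0).max() == 0.0

    def test_circumferential_shortening_truth(self):
        truth = PhantomTruth(seed=3, true_strain={"circumferential": -0.20})
        ph = make_lv_cine(truth, frame_rate=125)
        assert ph.true_strain["circumferential"] == pytest.approx(-20.0, abs=1e-9)

    def test_contour_counts_stable(self):
        ph = make_lv_cine(PhantomTruth(seed=3, true_strain={"radial": 0.2}),
                          frame_rate=125)
        n = ph.contours["endo"][0].shape[0]
        assert all(c.shape == (n, 2) for c in ph.contours["endo"])
        assert len(ph.contours["endo"]) == ph.loop.n_frames

    def test_oversized_deformation_raises(self):
        truth = PhantomTruth(seed=3, true_strain={"circumferential": 0.9})
        with pytest.raises(SizingError):
            make_lv_cine(truth, image_shape=(64, 64))


class TestDopplerPhantom:
    def test_renal_reference_ri(self):
        spec, ref = make_doppler_trace(PulsatileWaveform(psv_mm_s=120, edv_mm_s=40))
        idx = renal_indices(ref.psv, ref.edv, ref.mv)
        assert idx.ri == pytest.approx((120 - 40) / 120, abs=1e-9)

    def test_mitral_reference_ea(self):
        _, ref = make_doppler_trace(MitralWaveform(e_mm_s=800, a_mm_s=400))
        assert ref.psv / 400.0 == pytest.approx(2.0, rel=1e-6)

    def test_flat_waveform_reference(self):
        _, ref = make_doppler_trace(PulsatileWaveform(psv_mm_s=50, edv_mm_s=50))
        assert ref.psv == ref.edv == 50.0
        assert ref.mv == pytest.approx(50.0, abs=1e-9)

    def test_aliasing_refused(self):
        w = PulsatileWaveform(psv_mm_s=1000, edv_mm_s=100)
        with pytest.raises(AliasingError):
            make_doppler_trace(w, prf=5000)  # Nyquist ~160 mm/s at 5 kHz

    def test_nyquist_velocity_formula(self):
        # v = c * (prf/2) / (2 f0 cos60) ; at 9.5 kHz, 24 MHz -> ~304.8 mm/s
        assert nyquist_velocity(9500.0) == pytest.approx(
            1540.0 * 4750.0 / (2 * 24e6 * 0.5) * 1000.0, rel=1e-12)

    def test_spectrogram_axes_monotone_power_nonneg(self):
        spec, _ = make_doppler_trace(PulsatileWaveform(), seed=5,
                                     noise=NoiseSpec(speckle=0.4, additive=2))
        assert np.all(np.diff(spec.time_axis) > 0)
        assert np.all(np.diff(spec.velocity_axis) > 0)
        assert np.all(spec.power >= 0)


class TestLiverKidney:
    def test_noiseless_means_forced(self):
        img, l_roi, k_roi = make_liver_kidney_image((120.0, 100.0), seed=0)
        assert steatoscore(roi_mean(img, l_roi), roi_mean(img, k_roi)) \
            == pytest.approx(1.2, abs=1e-12)

    def test_equal_means_unity(self):
        img, l_roi, k_roi = make_liver_kidney_image((90.0, 90.0), seed=0)
        assert steatoscore(roi_mean(img, l_roi), roi_mean(img, k_roi)) == 1.0

    def test_dbdb_direction_by_construction(self):
        img, l_roi, k_roi = make_liver_kidney_image((95.0, 100.0), seed=0)
        assert steatoscore(roi_mean(img, l_roi), roi_mean(img, k_roi)) \
            == pytest.approx(0.95, abs=1e-12)

    def test_noise_contract_roi_mean(self):
        # expected ROI mean equals the prescribed mean within 3 sigma / sqrt(N)
        noise = NoiseSpec(speckle=0.3, correlation_px=1.5)
        img, l_roi, _ = make_liver_kidney_image((120.0, 100.0), seed=4, noise=noise)
        r0, r1, c0, c1 = l_roi
        patch = img[r0:r1, c0:c1]
        n_eff = patch.size / (2 * np.pi * noise.correlation_px ** 2)  # correlated pixels
        tol = 3.0 * patch.std() / np.sqrt(n_eff)
        assert abs(patch.mean() - 120.0) < tol


class TestEcgAndSpeckle:
    def test_ecg_impulse_times(self):
        ecg = make_ecg(1.05, hr_bpm=300.0)
        idx = np.flatnonzero(ecg.samples > 0)
        assert np.allclose(np.diff(idx) / ecg.sample_rate, 0.2)
        assert idx[0] == 0

    def test_speckle_field_unit_mean_deterministic(self, rng):
        f1 = speckle_field((64, 64), np.random.default_rng(9))
        f2 = speckle_field((64, 64), np.random.default_rng(9))
        assert np.array_equal(f1, f2)
        assert f1.mean() == pytest.approx(1.0, abs=1e-12)
        assert np.all(f1 >= 0)


class TestContainers:
    def test_cineloop_rejects_short_stack(self):
        with pytest.raises(ValueError):
            CineLoop(frames=np.zeros((1, 4, 4)), pixel_spacing=(0.02, 0.02),
                     frame_rate=700)

    def test_cineloop_rejects_short_ecg(self):
        from sonoquant.datatypes import Ecg
        ecg = Ecg(samples=np.zeros(10), sample_rate=1000.0)  # 9 ms
        with pytest.raises(ValueError):
            CineLoop(frames=np.zeros((5, 4, 4)), pixel_spacing=(0.02, 0.02),
                     frame_rate=100, ecg=ecg)  # loop lasts 40 ms

    def test_spectrogram_rejects_negative_power(self):
        with pytest.raises(ValueError):
            Spectrogram(power=-np.ones((3, 4)), time_axis=np.arange(3.0),
                        velocity_axis=np.arange(4.0), prf=1000.0)
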