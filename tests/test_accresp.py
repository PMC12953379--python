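"""Respiration extraction: gravity estimation, both PCA modes, rate
estimation, and the orientation-robustness contrast."""

import dataclasses

import numpy as np
import pytest
from scipy import signal as sps
from scipy.spatial.transform import Rotation

from cardiosleep.accresp import (DegenerateGravityError, ExtractionConfig,
                                 ExtractionMode, estimate_breath_rate,
                                 estimate_gravity, extract_resp,
                                 extract_resp_gravity_plane,
                                 extract_resp_orientation_robust)
from cardiosleep.synthetic import generate_night
from cardiosleep.types import AccelTrace, Hypnogram, RespSignal, Stage

FS = 125.0


def _trace(samples):
    return AccelTrace(samples, rate=FS)


def _sine_trace(freq, axis, amp=0.01, gravity=(0, 0, 1), dur=300.0,
                noise=0.002, seed=0):
    t = np.arange(0, dur, 1 / FS)
    acc = np.tile(np.asarray(gravity, float), (t.size, 1))
    acc[:, axis] += amp * np.sin(2 * np.pi * freq * t)
    acc += noise * np.random.default_rng(seed).standard_normal(acc.shape)
    return _trace(acc)


def _peak_freq(resp: RespSignal) -> float:
    x = resp.samples - resp.samples.mean()
    f = np.fft.rfftfreq(x.size, 1 / resp.rate)
    spec = np.abs(np.fft.rfft(x * np.hanning(x.size)))
    sel = (f > 0.05) & (f < 1.0)
    return f[sel][np.argmax(spec[sel])]


class TestGravity:
    def test_constant_input_constant_output(self):
        acc = np.tile([0.0, 0.0, 1.0], (int(FS * 120), 1))
        g = estimate_gravity(_trace(acc), ExtractionConfig())
        assert np.allclose(g, [0, 0, 1], atol=1e-9)

    def test_breathing_band_rejected(self):
        """0.3 Hz motion barely perturbs the low-passed gravity estimate."""
        tr = _sine_trace(0.3, axis=0, amp=0.05, noise=0.0)
        g = estimate_gravity(tr, ExtractionConfig())
        ang = np.degrees(np.arccos(np.clip(g @ np.array([0, 0, 1.0]), -1, 1)))
        assert ang.max() < 3.0

    def test_step_rotation_convergence(self):
        """Posture change: estimate settles near the new orientation within
        a few filter time constants."""
        cfg = ExtractionConfig()
        n = int(FS * 600)
        acc = np.zeros((n, 3))
        acc[:n // 2, 2] = 1.0
        acc[n // 2:, 1] = 1.0  # supine -> lateral
        g = estimate_gravity(_trace(acc), cfg)
        settle = n // 2 + int(3.0 / cfg.gravity_lp_hz * FS)
        ang = np.degrees(np.arccos(np.clip(g[settle:] @ np.array([0, 1.0, 0]),
                                           -1, 1)))
        assert ang.max() < 10.0

    def test_all_zero_trace_degenerate(self):
        with pytest.raises(DegenerateGravityError):
            estimate_gravity(_trace(np.zeros((int(FS * 60), 3))),
                             ExtractionConfig())

    def test_too_short_trace_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            estimate_gravity(_trace(np.ones((int(FS * 10), 3))),
                             ExtractionConfig())


class TestGravityPlaneMode:
    def test_recovers_rate_perpendicular_to_gravity(self):
        tr = _sine_trace(0.25, axis=0)  # resp x, gravity z
        cfg = ExtractionConfig(mode=ExtractionMode.GRAVITY_PLANE)
        resp = extract_resp_gravity_plane(tr, cfg)
        assert _peak_freq(resp) == pytest.approx(0.25, abs=0.02)

    def test_blind_to_gravity_parallel_motion(self):
        """Respiration along gravity: in-plane projection removes it."""
        tr = _sine_trace(0.2, axis=2, noise=0.0)  # resp z, gravity z
        cfg = ExtractionConfig(mode=ExtractionMode.GRAVITY_PLANE)
        resp = extract_resp_gravity_plane(tr, cfg)
        sos = sps.butter(4, [0.08 / (FS / 2), 0.8 / (FS / 2)], btype="band",
                         output="sos")
        bp = sps.sosfiltfilt(sos, tr.samples, axis=0)
        assert resp.samples.var() < 0.05 * bp.var(axis=0).sum()

    def test_white_noise_adds_no_breath_band_structure(self):
        rng = np.random.default_rng(3)
        x = 0.01 * rng.standard_normal((int(FS * 300), 3))
        x[:, 2] += 1.0
        cfg = ExtractionConfig(mode=ExtractionMode.GRAVITY_PLANE)
        resp = extract_resp_gravity_plane(_trace(x), cfg)

        def band_fraction(sig, rate):
            f = np.fft.rfftfreq(sig.size, 1 / rate)
            p = np.abs(np.fft.rfft(sig - sig.mean())) ** 2
            core = (f >= 0.15) & (f <= 0.5)
            band = (f >= 0.08) & (f <= 0.8)
            return p[core].sum() / p[band].sum()

        sos = sps.butter(4, [0.08 / (FS / 2), 0.8 / (FS / 2)], btype="band",
                         output="sos")
        filt_only = sps.sosfiltfilt(sos, x[:, 0])
        assert (band_fraction(resp.samples, resp.rate)
                <= band_fraction(filt_only, FS) + 0.10)


class TestOrientationRobustMode:
    def test_recovers_gravity_parallel_rate(self):
        """The headline contrast: breathing along gravity is recovered."""
        tr = _sine_trace(0.2, axis=2)  # resp z, gravity z (supine)
        cfg = ExtractionConfig(mode=ExtractionMode.ORIENTATION_ROBUST)
        resp = extract_resp_orientation_robust(tr, cfg)
        assert _peak_freq(resp) == pytest.approx(0.20, abs=0.02)

    def test_rotation_equivariance(self):
        tr = _sine_trace(0.25, axis=0)
        R = Rotation.from_euler("xyz", [35, 65, 20], degrees=True).as_matrix()
        cfg = ExtractionConfig(mode=ExtractionMode.ORIENTATION_ROBUST)
        a = extract_resp_orientation_robust(tr, cfg)
        b = extract_resp_orientation_robust(_trace(tr.samples @ R.T), cfg)
        corr = np.corrcoef(a.samples, b.samples)[0, 1]
        assert abs(corr) > 0.99

    def test_zero_motion_zero_output(self):
        acc = np.tile([0.0, 0.0, 1.0], (int(FS * 120), 1))
        cfg = ExtractionConfig(mode=ExtractionMode.ORIENTATION_ROBUST)
        resp = extract_resp_orientation_robust(_trace(acc), cfg)
        assert np.sqrt(np.mean(resp.samples ** 2)) < 1e-6

    def test_amplitude_equivariance(self):
        base = _sine_trace(0.25, axis=0, noise=0.0)
        cfg = ExtractionConfig(mode=ExtractionMode.ORIENTATION_ROBUST)
        a = extract_resp_orientation_robust(base, cfg)
        motion = base.samples - [0, 0, 1.0]
        scaled = _trace(motion * 3.0 + [0, 0, 1.0])
        b = extract_resp_orientation_robust(scaled, cfg)
        ratio = np.linalg.norm(b.samples) / np.linalg.norm(a.samples)
        assert ratio == pytest.approx(3.0, rel=0.02)

    def test_output_length_matches_grid(self):
        for dur in (61.0, 150.0, 300.0):
            tr = _sine_trace(0.25, axis=0, dur=dur)
            resp = extract_resp(tr, ExtractionConfig())
            assert abs(resp.n_samples - round(dur * 307_200 / 36_000)) <= 1

    def test_dispatch_by_mode(self):
        tr = _sine_trace(0.25, axis=0)
        for mode in ExtractionMode:
            resp = extract_resp(tr, ExtractionConfig(mode=mode))
            assert resp.rate == pytest.approx(307_200 / 36_000)


class TestBreathRate:
    def test_pure_tone_rate(self):
        t = np.arange(0, 300, 1 / 8.0)
        resp = RespSignal(np.sin(2 * np.pi * 0.25 * t), rate=8.0)
        rates = estimate_breath_rate(resp, window_sec=60.0)
        assert np.allclose(rates, 15.0, atol=0.5)

    def test_two_tone_dominant_frequency(self):
        t = np.arange(0, 300, 1 / 8.0)
        x = np.sin(2 * np.pi * 0.2 * t) + 0.3 * np.sin(2 * np.pi * 0.4 * t)
        rates = estimate_breath_rate(RespSignal(x, rate=8.0), window_sec=60.0)
        assert np.allclose(rates, 12.0, atol=0.5)

    def test_flat_signal_missing(self):
        rates = estimate_breath_rate(RespSignal(np.zeros(2400), rate=8.0),
                                     window_sec=60.0)
        assert np.all(np.isnan(rates))

    def test_synthetic_night_rate_recovered(self, physio_params):
        """Median estimated rate over an all-N3 night matches the generator."""
        phys = dataclasses.replace(physio_params, posture_change_rate=0.0)
        hyp = Hypnogram(np.full(20, int(Stage.N3)))
        rec = generate_night(hyp, phys)
        cfg = ExtractionConfig(mode=ExtractionMode.ORIENTATION_ROBUST)
        resp = extract_resp(rec.accel, cfg)
        rates = estimate_breath_rate(resp, window_sec=60.0)
        expected = phys.resp_rate_by_stage[Stage.N3]
        assert np.nanmedian(rates) == pytest.approx(expected, abs=0.5)


class TestConfigValidation:
    def test_band_order_enforced(self):
        with pytest.raises(ValueError):
            ExtractionConfig(band_low_hz=0.8, band_high_hz=0.08)

    def test_overlap_range_enforced(self):
        with pytest.raises(ValueError):
            ExtractionConfig(overlap_frac=1.0)
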