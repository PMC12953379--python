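"""Accelerometer-derived respiration (ACC-RESP).

A chest patch measures three-axis acceleration in the device frame; the
quasi-static component is gravity (re-oriented by posture changes) and the
small oscillatory component in the breathing band is respiratory chest-wall
displacement along a body-fixed axis. Two extraction modes are provided:

``GRAVITY_PLANE``
    The classical approach: estimate the gravity direction with a low-pass
    filter, project the band-passed residual onto the plane perpendicular to
    local gravity, and take the first principal component of the in-plane
    motion per window. Blind to respiratory motion parallel to gravity
    (e.g., anterior-posterior chest motion while supine).

``ORIENTATION_ROBUST``
    Band-pass all three axes (the high-pass edge removes the quasi-static
    gravity term instead of a geometric projection) and take the first
    principal axis of the full 3-D windowed covariance, so respiratory
    motion is recovered regardless of its angle to gravity — mimicking what
    a thoracic impedance band measures.

Both modes use Hann-weighted 50%-overlap windows with sign-continuity
between consecutive principal axes, and resample the result to the model's
respiratory input grid (8.5333... Hz) by exact rational polyphase
resampling.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .types import AccelTrace, RespSignal, RESP_MODEL_RATE

__all__ = [
    "ExtractionMode",
    "ExtractionConfig",
    "estimate_gravity",
    "extract_resp",
    "extract_resp_gravity_plane",
    "extract_resp_orientation_robust",
    "estimate_breath_rate",
]

log = logging.getLogger(__name__)


class ExtractionMode(enum.Enum):
    GRAVITY_PLANE = "gravity-plane"
    ORIENTATION_ROBUST = "orientation-robust"


class DegenerateGravityError(ValueError):
    """Raised when the gravity direction cannot be estimated (zero signal)."""


@dataclass
class ExtractionConfig:
    """Free parameters of the respiration extraction.

    ``band_low_hz``/``band_high_hz`` bracket the adult breathing band
    (default 0.08-0.8 Hz, i.e. 4.8-48 breaths/min); ``gravity_lp_hz`` is the
    low-pass cutoff separating posture/gravity from motion.
    """

    window_sec: float = 30.0
    overlap_frac: float = 0.5
    band_low_hz: float = 0.08
    band_high_hz: float = 0.8
    gravity_lp_hz: float = 0.04
    mode: ExtractionMode = ExtractionMode.ORIENTATION_ROBUST
    output_rate: float = RESP_MODEL_RATE

    def __post_init__(self) -> None:
        if not 0 < self.band_low_hz < self.band_high_hz:
            raise ValueError("need 0 < band_low_hz < band_high_hz")
        if not 0 < self.overlap_frac < 1:
            raise ValueError("overlap_frac must be in (0, 1)")
        if self.window_sec <= 0 or self.gravity_lp_hz <= 0:
            raise ValueError("window_sec and gravity_lp_hz must be positive")


def _bandpass(x: np.ndarray, fs: float, lo: float, hi: float) -> np.ndarray:
    sos = sps.butter(4, [lo / (fs / 2), hi / (fs / 2)], btype="band", output="sos")
    return sps.sosfiltfilt(sos, x, axis=0)


def estimate_gravity(acc: AccelTrace, cfg: ExtractionConfig) -> np.ndarray:
    """Per-sample unit gravity direction from low-pass filtered acceleration.

    Returns an (N, 3) array of unit vectors. Raises
    :class:`DegenerateGravityError` if the low-passed signal vanishes.
    """
    if acc.duration_sec <= 1.0 / cfg.gravity_lp_hz:
        raise ValueError(
            f"trace of {acc.duration_sec:.1f}s too short for gravity cutoff "
            f"{cfg.gravity_lp_hz} Hz"
        )
    sos = sps.butter(2, cfg.gravity_lp_hz / (acc.rate / 2), btype="low", output="sos")
    g = sps.sosfiltfilt(sos, acc.samples, axis=0)
    norm = np.linalg.norm(g, axis=1, keepdims=True)
    if np.any(norm < 1e-6):
        raise DegenerateGravityError("gravity magnitude vanished; all-zero trace?")
    return g / norm


def _plane_basis(g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal basis (u, v) of the plane perpendicular to unit vector g."""
    ref = np.array([1.0, 0.0, 0.0])
    if abs(g @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(g, ref)
    u /= np.linalg.norm(u)
    v = np.cross(g, u)
    return u, v


def _principal_axis(x: np.ndarray, w: np.ndarray) -> np.ndarray | None:
    """First principal axis of windowed samples; None if rank-deficient."""
    xw = x * w[:, None]
    cov = xw.T @ xw
    tr = np.trace(cov)
    if not np.isfinite(tr) or tr < 1e-18:
        return None
    vals, vecs = np.linalg.eigh(cov)
    return vecs[:, -1]


def _align_sign(axis: np.ndarray, prev: np.ndarray | None) -> np.ndarray:
    if prev is None:
        # first window: make the largest-magnitude component positive
        k = int(np.argmax(np.abs(axis)))
        return axis if axis[k] >= 0 else -axis
    return axis if axis @ prev >= 0 else -axis


def _windowed_projection(comp, fs: float, cfg: ExtractionConfig) -> np.ndarray:
    """Hann overlap-add of per-window first-principal-axis projections.

    ``comp(i0, i1)`` returns the windowed multi-channel samples to which
    PCA is applied.
    """
    n = comp(0, None).shape[0]
    win = int(round(cfg.window_sec * fs))
    hop = max(int(round(win * (1.0 - cfg.overlap_frac))), 1)
    hann = np.hanning(win)
    out = np.zeros(n)
    wsum = np.zeros(n)
    prev_axis: np.ndarray | None = None
    starts = range(0, max(n - win, 0) + 1, hop) if n >= win else [0]
    for i0 in starts:
        i1 = min(i0 + win, n)
        x = comp(i0, i1)
        w = hann[: i1 - i0]
        axis = _principal_axis(x, w)
        if axis is None:
            if prev_axis is None:
                continue
            log.warning("rank-deficient window at sample %d; reusing previous axis", i0)
            axis = prev_axis
        axis = _align_sign(axis, prev_axis)
        prev_axis = axis
        proj = x @ axis
        proj = proj - proj.mean()
        out[i0:i1] += proj * w
        wsum[i0:i1] += w
    nz = wsum > 1e-12
    out[nz] /= wsum[nz]
    return out


def _resample_to_grid(x: np.ndarray, fs: float, out_rate: float) -> np.ndarray:
    ratio = Fraction(out_rate / fs).limit_denominator(1_000_000)
    return sps.resample_poly(x, ratio.numerator, ratio.denominator)


def extract_resp_gravity_plane(acc: AccelTrace, cfg: ExtractionConfig) -> RespSignal:
    """Gravity-plane baseline: in-plane band-passed motion, windowed PCA."""
    gravity = estimate_gravity(acc, cfg)
    residual = acc.samples - gravity * np.sum(
        acc.samples * gravity, axis=1, keepdims=True
    )
    bp = _bandpass(residual, acc.rate, cfg.band_low_hz, cfg.band_high_hz)

    def comp(i0: int, i1: int | None) -> np.ndarray:
        seg = bp[i0:i1]
        gseg = gravity[i0:i1].mean(axis=0)
        gseg /= np.linalg.norm(gseg)
        u, v = _plane_basis(gseg)
        return np.stack([seg @ u, seg @ v], axis=1)

    out = _windowed_projection(comp, acc.rate, cfg)
    samples = _resample_to_grid(out, acc.rate, cfg.output_rate)
    return RespSignal(samples, rate=cfg.output_rate, start_time=acc.start_time)


def extract_resp_orientation_robust(
    acc: AccelTrace, cfg: ExtractionConfig
) -> RespSignal:
    """Orientation-robust mode: full 3-D band-pass plus windowed 3-D PCA."""
    bp = _bandpass(acc.samples, acc.rate, cfg.band_low_hz, cfg.band_high_hz)

    def comp(i0: int, i1: int | None) -> np.ndarray:
        return bp[i0:i1]

    out = _windowed_projection(comp, acc.rate, cfg)
    samples = _resample_to_grid(out, acc.rate, cfg.output_rate)
    return RespSignal(samples, rate=cfg.output_rate, start_time=acc.start_time)


def extract_resp(acc: AccelTrace, cfg: ExtractionConfig) -> RespSignal:
    """Dispatch on ``cfg.mode``."""
    if cfg.mode is ExtractionMode.GRAVITY_PLANE:
        return extract_resp_gravity_plane(acc, cfg)
    return extract_resp_orientation_robust(acc, cfg)


def estimate_breath_rate(
    resp: RespSignal,
    window_sec: float = 60.0,
    band_low_hz: float = 0.08,
    band_high_hz: float = 0.8,
) -> np.ndarray:
    """Dominant-frequency breathing-rate series in breaths/min.

    One estimate per non-overlapping window; windows with negligible power
    yield NaN. Estimates are clipped to the breathing band.
    """
    fs = resp.rate
    win = int(round(window_sec * fs))
    if win > resp.n_samples:
        win = resp.n_samples
    nfft = max(4096, 1 << int(np.ceil(np.log2(win * 8))))
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    sel = (freqs >= band_low_hz) & (freqs <= band_high_hz)
    rates = []
    for i0 in range(0, resp.n_samples - win + 1, win):
        seg = resp.samples[i0 : i0 + win]
        seg = seg - seg.mean()
        if np.sqrt(np.mean(seg**2)) < 1e-12:
            rates.append(np.nan)
            continue
        spec = np.abs(np.fft.rfft(seg * np.hanning(win), n=nfft))
        f = freqs[sel][np.argmax(spec[sel])]
        rates.append(np.clip(f, band_low_hz, band_high_hz) * 60.0)
    return np.asarray(rates)
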