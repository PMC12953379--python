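"""Alignment, resampling, windowing and quality screening.

Turns a :class:`~cardiosleep.types.NightRecord` into a fixed-length
:class:`~cardiosleep.types.ModelInput` on the staging model's input grids,
and applies the cohort inclusion rules: a night fails screening if any
contiguous missing-data run exceeds 30 minutes, and a participant is
included only if at least 75% of their study nights pass.

The default grid is the full-scale one: a 10-h window of 1,200 epochs with
1,024 ECG samples per epoch (34.1333... Hz; 1,228,800 samples) and 256
respiratory samples per epoch (8.5333... Hz; 307,200 samples). Reduced grids
for desk-scale experiments use the same machinery with a smaller window
and/or fewer samples per epoch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .types import EPOCH_SEC, ModelInput, NightRecord, Stage

__all__ = [
    "GridSpec",
    "FULL_GRID",
    "resample_to_model_grid",
    "night_quality",
    "participant_inclusion",
    "QualityResult",
]

log = logging.getLogger(__name__)

MAX_GAP_MIN = 30.0  # per-gap exclusion threshold, minutes


@dataclass(frozen=True)
class GridSpec:
    """Model input grid: window length and per-epoch sample counts."""

    n_epochs: int = 1200
    ecg_samples_per_epoch: int = 1024
    resp_samples_per_epoch: int = 256

    @property
    def ecg_rate(self) -> float:
        return self.ecg_samples_per_epoch / EPOCH_SEC

    @property
    def resp_rate(self) -> float:
        return self.resp_samples_per_epoch / EPOCH_SEC

    @property
    def ecg_len(self) -> int:
        return self.n_epochs * self.ecg_samples_per_epoch

    @property
    def resp_len(self) -> int:
        return self.n_epochs * self.resp_samples_per_epoch


FULL_GRID = GridSpec()
assert FULL_GRID.ecg_len == 1_228_800 and FULL_GRID.resp_len == 307_200


def _resample(x: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    if abs(fs_in - fs_out) < 1e-12:
        return np.asarray(x, dtype=np.float64)
    ratio = Fraction(fs_out / fs_in).limit_denominator(1_000_000)
    return sps.resample_poly(np.asarray(x, dtype=np.float64),
                             ratio.numerator, ratio.denominator)


def _fill_gaps(x: np.ndarray, fs: float, max_interp_sec: float = 5.0) -> np.ndarray:
    """Linearly interpolate short NaN runs; zero-fill longer ones."""
    x = np.array(x, dtype=np.float64)
    isnan = np.isnan(x)
    if not isnan.any():
        return x
    idx = np.arange(x.size)
    for i0, i1 in _nan_runs(isnan):
        if (i1 - i0) / fs <= max_interp_sec and 0 < i0 and i1 < x.size:
            x[i0:i1] = np.interp(idx[i0:i1], [i0 - 1, i1], [x[i0 - 1], x[i1]])
        else:
            log.warning("zero-filling %.1f s gap", (i1 - i0) / fs)
            x[i0:i1] = 0.0
    return x


def _nan_runs(isnan: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index ranges of consecutive-NaN runs."""
    d = np.diff(isnan.astype(np.int8), prepend=0, append=0)
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), stops.tolist()))


def _robust_normalize(x: np.ndarray) -> np.ndarray:
    """Per-night median/IQR normalization with +/-10 clipping."""
    med = np.median(x)
    q75, q25 = np.percentile(x, [75, 25])
    iqr = q75 - q25
    # scale-relative guard: resampling a constant leaves ~1e-5 filter ripple
    scale = max(abs(med), float(np.max(np.abs(x))), 1e-30)
    if iqr <= 1e-4 * scale:
        log.warning("degenerate waveform (IQR=0); normalized output is all zeros")
        return np.zeros_like(x)
    return np.clip((x - med) / iqr, -10.0, 10.0)


def _fit_window(x: np.ndarray, target_len: int) -> np.ndarray:
    if x.size >= target_len:
        return x[:target_len]
    return np.concatenate([x, np.zeros(target_len - x.size)])


def resample_to_model_grid(
    night: NightRecord, grid: GridSpec = FULL_GRID
) -> ModelInput:
    """Resample a night onto the model grid, pad/truncate, and normalize.

    ECG is mandatory; the respiratory channel is optional (ECG-only
    pathway). Nights shorter than the window are right-padded with zeros
    and PAD labels; longer nights are truncated to the window's first part
    (sleep onset is kept, since onset latency matters downstream).
    """
    if night.ecg is None:
        raise ValueError("night has no ECG channel; cannot build model input")
    ecg = _fill_gaps(night.ecg, night.ecg_rate)
    ecg = _resample(ecg, night.ecg_rate, grid.ecg_rate)
    ecg = _fit_window(_robust_normalize(ecg), grid.ecg_len).astype(np.float32)

    resp = None
    if night.resp is not None:
        r = _fill_gaps(night.resp.samples, night.resp.rate)
        r = _resample(r, night.resp.rate, grid.resp_rate)
        resp = _fit_window(_robust_normalize(r), grid.resp_len).astype(np.float32)

    stages = night.hypnogram.stages
    labels = np.full(grid.n_epochs, int(Stage.PAD), dtype=np.int64)
    n_real = min(stages.size, grid.n_epochs)
    labels[:n_real] = stages[:n_real]
    loss_mask = (labels != Stage.ARTIFACT) & (labels != Stage.PAD)
    return ModelInput(
        ecg=ecg,
        resp=resp,
        labels=labels,
        loss_mask=loss_mask,
        participant_id=night.participant_id,
        night_label=night.night_label,
    )


def unpad_labels(inp: ModelInput, n_real: int) -> np.ndarray:
    """Recover the original (un-padded) label sequence from a model window."""
    return inp.labels[:n_real]


@dataclass
class QualityResult:
    passed: bool
    reasons: list[str]


def night_quality(night: NightRecord) -> QualityResult:
    """Screen one night: fail on any >30-min missing-data run.

    Missing data are NaN runs in the ECG or any accelerometer axis. A night
    whose hypnogram is entirely ARTIFACT also fails (nothing scorable).
    """
    reasons: list[str] = []
    channels: list[tuple[np.ndarray, float]] = []
    if night.ecg is not None:
        channels.append((night.ecg, night.ecg_rate))
    if night.accel is not None:
        for ax in range(3):
            channels.append((night.accel.samples[:, ax], night.accel.rate))
    for x, fs in channels:
        for i0, i1 in _nan_runs(np.isnan(np.asarray(x))):
            if (i1 - i0) / fs > MAX_GAP_MIN * 60.0:
                reasons.append("gap>30min")
                break
        if reasons:
            break
    if np.all(night.hypnogram.stages == Stage.ARTIFACT):
        reasons.append("all-artifact hypnogram")
    return QualityResult(passed=not reasons, reasons=reasons)


def participant_inclusion(night_results: list[QualityResult | bool]) -> bool:
    """Include a participant iff >= 75% of their study nights pass screening."""
    if not night_results:
        raise ValueError("participant has no nights")
    flags = [r.passed if isinstance(r, QualityResult) else bool(r)
             for r in night_results]
    return sum(flags) / len(flags) >= 0.75
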