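"""Core domain types shared across the pipeline.

Conventions used everywhere in this package:

* An *epoch* is a 30-second scoring window; epoch indices are 0-based and
  intervals are half-open, so epoch ``k`` covers samples
  ``[k * 30 * rate, (k + 1) * 30 * rate)`` of an aligned waveform.
* Waveforms are 1-D (or ``N x 3`` for accelerometry) numpy arrays with an
  explicit sampling rate in Hz.
* Night labels follow the longitudinal study layout: ``B1`` (baseline),
  ``I1``..``I7`` (intervention nights under restricted time in bed), and
  ``F1`` (follow-up).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

EPOCH_SEC = 30
"""Duration of one scoring epoch in seconds."""

EPOCHS_PER_HOUR = 3600 // EPOCH_SEC  # 120

NIGHT_LABELS = ("B1", "I1", "I2", "I3", "I4", "I5", "I6", "I7", "F1")


class Stage(enum.IntEnum):
    """Four-class sleep stages plus bookkeeping labels.

    ``N1N2`` is the merged light-sleep class conventional in cardiorespiratory
    staging (N1 and N2 are pooled because of N1's low incidence and poor
    inter-rater agreement). ``ARTIFACT`` marks epochs an expert scorer deemed
    unscorable; ``PAD`` marks synthetic epochs appended when a night shorter
    than the model window is zero-padded. Both are excluded from the loss and
    from all agreement metrics.
    """

    WAKE = 0
    N1N2 = 1
    N3 = 2
    REM = 3
    ARTIFACT = 4
    PAD = 5

    @property
    def is_scored(self) -> bool:
        return self not in (Stage.ARTIFACT, Stage.PAD)

    @property
    def is_sleep(self) -> bool:
        return self in (Stage.N1N2, Stage.N3, Stage.REM)


CLASS_STAGES = (Stage.WAKE, Stage.N1N2, Stage.N3, Stage.REM)
STAGE_TOKENS = {s.name: s for s in Stage}


@dataclass
class Hypnogram:
    """Per-epoch sleep stage labels for one night.

    Parameters
    ----------
    stages
        Integer array of :class:`Stage` values, one per 30-s epoch.
    """

    stages: np.ndarray

    def __post_init__(self) -> None:
        self.stages = np.asarray(self.stages, dtype=np.int64)
        if self.stages.ndim != 1:
            raise ValueError("hypnogram stages must be 1-D")

    def __len__(self) -> int:
        return int(self.stages.size)

    @property
    def duration_sec(self) -> float:
        return len(self) * EPOCH_SEC

    def counts(self) -> dict[Stage, int]:
        return {s: int(np.sum(self.stages == s)) for s in Stage}


@dataclass
class AccelTrace:
    """Three-axis acceleration in units of g, device frame, fixed rate."""

    samples: np.ndarray  # (N, 3)
    rate: float = 125.0
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError("accelerometer samples must have shape (N, 3)")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return int(self.samples.shape[0])

    @property
    def duration_sec(self) -> float:
        return self.n_samples / self.rate


# The model's respiratory input grid: 307,200 samples per 10-h window.
RESP_MODEL_RATE = 307_200 / 36_000  # 8.5333... Hz
# The model's ECG input grid: 1,228,800 samples per 10-h window.
ECG_MODEL_RATE = 1_228_800 / 36_000  # 34.1333... Hz


@dataclass
class RespSignal:
    """Single-channel unitless respiratory displacement waveform."""

    samples: np.ndarray
    rate: float = RESP_MODEL_RATE
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64).ravel()
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration_sec(self) -> float:
        return self.n_samples / self.rate


@dataclass
class NightRecord:
    """Aligned waveforms and labels for one participant-night."""

    participant_id: str
    night_label: str
    ecg: np.ndarray | None  # 1-D @ ecg_rate
    accel: AccelTrace | None
    hypnogram: Hypnogram
    ecg_rate: float = 125.0
    resp: RespSignal | None = None
    quality_flags: set = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.night_label not in NIGHT_LABELS:
            raise ValueError(
                f"unknown night label {self.night_label!r}; "
                f"expected one of {NIGHT_LABELS}"
            )


@dataclass
class ModelInput:
    """Fixed-length model window: waveforms on the model grid plus labels.

    ``loss_mask`` is False wherever the label is ARTIFACT or PAD; those epochs
    contribute neither gradient nor agreement statistics.
    """

    ecg: np.ndarray | None
    resp: np.ndarray | None
    labels: np.ndarray  # (n_epochs,) Stage values
    loss_mask: np.ndarray  # (n_epochs,) bool
    participant_id: str = ""
    night_label: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.loss_mask = np.asarray(self.loss_mask, dtype=bool)
        if self.labels.shape != self.loss_mask.shape:
            raise ValueError("labels and loss_mask must have the same length")
        bad = self.loss_mask & (
            (self.labels == Stage.ARTIFACT) | (self.labels == Stage.PAD)
        )
        if np.any(bad):
            raise ValueError("loss_mask must be False on ARTIFACT/PAD epochs")

    @property
    def n_epochs(self) -> int:
        return int(self.labels.size)
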