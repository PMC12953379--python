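"""File formats: EDF waveforms, hypnogram CSVs, model-input containers.

EDF (European Data Format) is the de-facto container for sleep waveforms;
CSV keeps hypnograms human-diffable. Reading EDF goes through ``mne``;
writing uses a deliberately small EDF writer (one data record per second,
or per 30 s when the sampling rate is not an integer, int16 samples with
per-channel physical scaling) that round-trips against mne within 16-bit
quantization.

Every artifact written here gets a JSON provenance sidecar (tool version,
seed, config hash) so runs can be traced.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd

from .types import Hypnogram, ModelInput, Stage, STAGE_TOKENS

__all__ = [
    "write_edf",
    "read_edf",
    "EdfChannel",
    "read_hypnogram_csv",
    "write_hypnogram_csv",
    "save_model_input",
    "load_model_input",
    "provenance",
    "write_provenance",
]


def provenance(seed: int | None = None, config: object | None = None) -> dict:
    from . import __version__

    d: dict = {"tool": "cardiosleep", "version": __version__}
    if seed is not None:
        d["seed"] = int(seed)
    if config is not None:
        blob = json.dumps(config, sort_keys=True, default=str)
        d["config_hash"] = hashlib.sha256(blob.encode()).hexdigest()[:16]
    return d


def write_provenance(path: Path, seed: int | None = None,
                     config: object | None = None) -> None:
    Path(path).write_text(json.dumps(provenance(seed, config), indent=2))


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

_EDF_DIG_MIN, _EDF_DIG_MAX = -32768, 32767


def _pad_field(value: str, width: int) -> bytes:
    b = value.encode("ascii")[:width]
    return b + b" " * (width - len(b))


def _record_layout(rate: float) -> tuple[float, int]:
    """Choose (record_duration_sec, samples_per_record) for a channel rate."""
    for dur in (1, 2, 5, 10, 30, 60):
        spr = rate * dur
        if abs(spr - round(spr)) < 1e-9 and round(spr) >= 1:
            return float(dur), int(round(spr))
    raise ValueError(f"cannot express rate {rate} Hz in whole EDF records")


def write_edf(path, channels: dict[str, np.ndarray], rates: dict[str, float],
              start_time: float = 0.0) -> None:
    """Write channels to a minimal EDF file.

    All channels must share one record duration; int16 quantization uses a
    symmetric physical range derived per channel. NaNs are written as zeros
    (gap semantics live upstream).
    """
    names = list(channels)
    durs = {name: _record_layout(rates[name]) for name in names}
    rec_dur = max(d for d, _ in durs.values())
    sprs = {}
    for name in names:
        spr = rates[name] * rec_dur
        if abs(spr - round(spr)) > 1e-9:
            raise ValueError(
                f"channel {name}: rate {rates[name]} incompatible with "
                f"record duration {rec_dur}s"
            )
        sprs[name] = int(round(spr))
    n_samp = {name: int(np.asarray(channels[name]).size) for name in names}
    n_records = max(
        int(np.ceil(n_samp[name] / sprs[name])) for name in names
    )

    phys_ranges = {}
    digital = {}
    for name in names:
        x = np.nan_to_num(np.asarray(channels[name], dtype=np.float64))
        amax = float(np.max(np.abs(x))) if x.size else 1.0
        amax = max(amax, 1e-6)
        phys_ranges[name] = amax
        scaled = np.clip(x / amax, -1.0, 1.0) * _EDF_DIG_MAX
        pad = n_records * sprs[name] - x.size
        d = np.concatenate([scaled, np.zeros(pad)]) if pad else scaled
        digital[name] = np.round(d).astype("<i2")

    n_sig = len(names)
    header_bytes = 256 * (1 + n_sig)
    with open(path, "wb") as f:
        f.write(_pad_field("0", 8))
        f.write(_pad_field("X X X X", 80))
        f.write(_pad_field("Startdate 01-JAN-2000 X X X", 80))
        f.write(_pad_field("01.01.00", 8))
        h = int(start_time // 3600) % 24
        m = int(start_time // 60) % 60
        s = int(start_time) % 60
        f.write(_pad_field(f"{h:02d}.{m:02d}.{s:02d}", 8))
        f.write(_pad_field(str(header_bytes), 8))
        f.write(_pad_field("", 44))
        f.write(_pad_field(str(n_records), 8))
        g = str(Fraction(rec_dur).limit_denominator(1000))
        f.write(_pad_field(str(float(rec_dur)) if "/" in g else g, 8))
        f.write(_pad_field(str(n_sig), 4))

        for name in names:
            f.write(_pad_field(name, 16))
        for _ in names:
            f.write(_pad_field("", 80))  # transducer
        for _ in names:
            f.write(_pad_field("au", 8))  # physical dimension (arbitrary units)
        for name in names:
            f.write(_pad_field(f"{-phys_ranges[name]:.6g}"[:8], 8))
        for name in names:
            f.write(_pad_field(f"{phys_ranges[name]:.6g}"[:8], 8))
        for _ in names:
            f.write(_pad_field(str(_EDF_DIG_MIN), 8))
        for _ in names:
            f.write(_pad_field(str(_EDF_DIG_MAX), 8))
        for _ in names:
            f.write(_pad_field("", 80))  # prefiltering
        for name in names:
            f.write(_pad_field(str(sprs[name]), 8))
        for _ in names:
            f.write(_pad_field("", 32))

        for r in range(n_records):
            for name in names:
                spr = sprs[name]
                f.write(digital[name][r * spr:(r + 1) * spr].tobytes())


@dataclass
class EdfChannel:
    samples: np.ndarray
    rate: float


def read_edf(path) -> tuple[dict[str, EdfChannel], float]:
    """Read an EDF file via mne; returns channels and start-of-day seconds."""
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    channels: dict[str, EdfChannel] = {}
    for name in raw.ch_names:
        idx = raw.ch_names.index(name)
        channels[name] = EdfChannel(
            samples=raw.get_data(picks=[idx])[0],
            rate=float(raw.info["sfreq"]),
        )
    meas = raw.info.get("meas_date")
    start = 0.0
    if meas is not None:
        start = meas.hour * 3600 + meas.minute * 60 + meas.second
    return channels, start


def require_channel(channels: dict[str, EdfChannel], name: str) -> EdfChannel:
    if name not in channels:
        raise KeyError(
            f"channel {name!r} not present; available: {sorted(channels)}"
        )
    return channels[name]


# ---------------------------------------------------------------------------
# Hypnogram CSV
# ---------------------------------------------------------------------------


def write_hypnogram_csv(hyp: Hypnogram, path, participant_id: str = "",
                        night_label: str = "") -> None:
    df = pd.DataFrame({
        "epoch_index": np.arange(len(hyp)),
        "stage": [Stage(s).name for s in hyp.stages],
    })
    if participant_id:
        df["participant_id"] = participant_id
    if night_label:
        df["night_label"] = night_label
    df.to_csv(path, index=False)


def read_hypnogram_csv(path) -> tuple[Hypnogram, dict]:
    """Read a hypnogram CSV; returns the hypnogram and any identity columns.

    Stage tokens must come from the fixed vocabulary (WAKE, N1N2, N3, REM,
    ARTIFACT, PAD); in particular unmerged "N1"/"N2" tokens are rejected.
    """
    df = pd.read_csv(path)
    for col in ("epoch_index", "stage"):
        if col not in df.columns:
            raise ValueError(f"hypnogram CSV missing column {col!r}")
    idx = df["epoch_index"].to_numpy()
    if len(np.unique(idx)) != len(idx):
        raise ValueError("duplicate epoch_index values")
    order = np.argsort(idx)
    if not np.array_equal(idx[order], np.arange(len(idx))):
        raise ValueError("epoch_index must be 0-based and contiguous")
    stages = []
    for tok in df["stage"].astype(str).str.strip().to_numpy()[order]:
        if tok not in STAGE_TOKENS:
            raise ValueError(
                f"unknown stage token {tok!r}; accepted tokens: "
                f"{sorted(STAGE_TOKENS)} (N1 and N2 are merged as 'N1N2')"
            )
        stages.append(int(STAGE_TOKENS[tok]))
    meta = {}
    for col in ("participant_id", "night_label"):
        if col in df.columns:
            meta[col] = str(df[col].iloc[0])
    return Hypnogram(np.asarray(stages)), meta


# ---------------------------------------------------------------------------
# Model-input container (npz + JSON sidecar)
# ---------------------------------------------------------------------------


def save_model_input(inp: ModelInput, path) -> None:
    path = Path(path)
    arrays = {"labels": inp.labels, "loss_mask": inp.loss_mask}
    if inp.ecg is not None:
        arrays["ecg"] = inp.ecg
    if inp.resp is not None:
        arrays["resp"] = inp.resp
    np.savez(path, **arrays)
    sidecar = {
        "participant_id": inp.participant_id,
        "night_label": inp.night_label,
        "n_epochs": inp.n_epochs,
        "masked_epochs": int((~inp.loss_mask).sum()),
        **provenance(),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_model_input(path) -> ModelInput:
    path = Path(path)
    with np.load(path) as f:
        ecg = f["ecg"] if "ecg" in f.files else None
        resp = f["resp"] if "resp" in f.files else None
        labels = f["labels"]
        loss_mask = f["loss_mask"]
    meta = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return ModelInput(
        ecg=ecg, resp=resp, labels=labels, loss_mask=loss_mask,
        participant_id=meta.get("participant_id", ""),
        night_label=meta.get("night_label", ""),
    )
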