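"""Typed pipeline configuration with strict YAML round-tripping.

Unknown keys are rejected with a location-bearing error (pydantic reports
the offending path), and ``to_yaml``/``from_yaml`` round-trip losslessly.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict

from .accresp import ExtractionConfig, ExtractionMode
from .model import ModelConfig
from .training import TrainConfig

__all__ = ["PipelineConfig"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ExtractionSettings(_Strict):
    window_sec: float = 30.0
    overlap_frac: float = 0.5
    band_low_hz: float = 0.08
    band_high_hz: float = 0.8
    gravity_lp_hz: float = 0.04
    mode: str = "orientation-robust"

    def build(self) -> ExtractionConfig:
        return ExtractionConfig(
            window_sec=self.window_sec,
            overlap_frac=self.overlap_frac,
            band_low_hz=self.band_low_hz,
            band_high_hz=self.band_high_hz,
            gravity_lp_hz=self.gravity_lp_hz,
            mode=ExtractionMode(self.mode),
        )


class ModelSettings(_Strict):
    ecg_encoder_features: list[int] = [16, 16, 32, 32, 64, 64, 128, 128]
    resp_encoder_features: list[int] = [16, 32, 64, 64, 128, 128]
    encoder_out_features: int = 256
    epoch_feature_dim: int = 128
    n_epochs: int = 1200
    mixer_blocks: int = 2
    mixer_dropout: float = 0.1
    mixer_heads: int = 8
    mixer_ff_dim: int = 512
    seq_dilations: list[int] = [1, 2, 4, 8, 16, 32, 1, 2, 4, 8, 16, 32]
    seq_kernel: int = 7
    seed: int = 0

    def build(self) -> ModelConfig:
        return ModelConfig(
            ecg_encoder_features=tuple(self.ecg_encoder_features),
            resp_encoder_features=tuple(self.resp_encoder_features),
            encoder_out_features=self.encoder_out_features,
            epoch_feature_dim=self.epoch_feature_dim,
            n_epochs=self.n_epochs,
            mixer_blocks=self.mixer_blocks,
            mixer_dropout=self.mixer_dropout,
            mixer_heads=self.mixer_heads,
            mixer_ff_dim=self.mixer_ff_dim,
            seq_dilations=tuple(self.seq_dilations),
            seq_kernel=self.seq_kernel,
            seed=self.seed,
        )


class TrainSettings(_Strict):
    learning_rate: float = 1e-5
    weight_decay: float = 0.01
    batch_size: int = 16
    patience: int = 5
    max_epochs: int = 100
    seed: int = 0

    def build(self) -> TrainConfig:
        return TrainConfig(
            learning_rate=self.learning_rate,
            weight_decay=self.weight_decay,
            batch_size=self.batch_size,
            patience=self.patience,
            max_epochs=self.max_epochs,
            seed=self.seed,
        )


class PipelineConfig(_Strict):
    seed: int = 0
    extraction: ExtractionSettings = ExtractionSettings()
    model: ModelSettings = ModelSettings()
    train: TrainSettings = TrainSettings()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.model_dump(), sort_keys=False)
        )
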