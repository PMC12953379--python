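"""Cardiorespiratory sleep-staging network.

The architecture classifies a whole recording window (up to 10 h, 1,200
30-s epochs) at once from raw cardiorespiratory waveforms:

* **Signal encoders** — one residual-CNN ladder per modality (ECG on a
  34.13 Hz grid, respiration on an 8.53 Hz grid). Each block applies three
  kernel-3 convolutions with batch norm, a projection skip connection, and
  halves the time axis by max pooling, ending in a width-256 feature map of
  4 frames per epoch.
* **Per-epoch fusion** — the 4 frames x 256 channels of each epoch are
  reshaped to a 1,024-vector and reduced to 128 features by a
  time-distributed dense layer shared across epochs.
* **Epoch mixer** — modality features are summed per epoch (a learned null
  vector stands in for an absent modality), sinusoidal positional encoding
  is added, and two transformer encoder blocks attend over all epochs of
  the night.
* **Sequence mixer** — a dilated residual CNN over the epoch axis
  (kernel 7, dilations 1..32 twice, receptive field 757 epochs) followed by
  a dense 4-class head produces one stage posterior per epoch.

The default configuration reproduces the full-scale layer dimensions
exactly; :func:`reduced_config` gives a narrow variant with the same
topology for desk-scale training experiments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .types import CLASS_STAGES, ModelInput

__all__ = [
    "ModelConfig",
    "StagePosterior",
    "SleepStager",
    "reduced_config",
    "receptive_field_epochs",
    "save_checkpoint",
    "load_checkpoint",
]

MODALITIES = ("ecg", "resp")


@dataclass(frozen=True)
class ModelConfig:
    """Architecture constants; defaults are the full-scale parameterization."""

    ecg_encoder_features: tuple[int, ...] = (16, 16, 32, 32, 64, 64, 128, 128)
    resp_encoder_features: tuple[int, ...] = (16, 32, 64, 64, 128, 128)
    encoder_out_features: int = 256
    conv_kernel: int = 3
    convs_per_block: int = 3
    pool_factor: int = 2
    frames_per_epoch: int = 4
    epoch_feature_dim: int = 128
    n_epochs: int = 1200
    mixer_blocks: int = 2
    mixer_dropout: float = 0.1
    mixer_heads: int = 8
    mixer_ff_dim: int = 512
    seq_dilations: tuple[int, ...] = (1, 2, 4, 8, 16, 32, 1, 2, 4, 8, 16, 32)
    seq_kernel: int = 7
    n_classes: int = 4
    seed: int = 0

    def samples_per_epoch(self, modality: str) -> int:
        feats = self._features(modality)
        return self.frames_per_epoch * self.pool_factor ** len(feats)

    def input_len(self, modality: str) -> int:
        return self.n_epochs * self.samples_per_epoch(modality)

    def _features(self, modality: str) -> tuple[int, ...]:
        if modality == "ecg":
            return self.ecg_encoder_features
        if modality == "resp":
            return self.resp_encoder_features
        raise ValueError(f"unknown modality {modality!r}")

    @property
    def fused_reshape_dim(self) -> int:
        return self.frames_per_epoch * self.encoder_out_features


# Full-scale arithmetic: 2**8 * 4 * 1200 = 1,228,800 and 2**6 * 4 * 1200 = 307,200
assert ModelConfig().input_len("ecg") == 1_228_800
assert ModelConfig().input_len("resp") == 307_200


def reduced_config(n_epochs: int = 240, seed: int = 0) -> ModelConfig:
    """Narrow configuration with identical topology for CPU-scale training.

    ECG uses 6 blocks (256 samples/epoch, 8.53 Hz) and respiration 4 blocks
    (64 samples/epoch, 2.13 Hz); widths are cut ~8x throughout.
    """
    return ModelConfig(
        ecg_encoder_features=(8, 8, 16, 16, 32, 32),
        resp_encoder_features=(8, 8, 16, 16),
        encoder_out_features=32,
        epoch_feature_dim=32,
        n_epochs=n_epochs,
        mixer_heads=4,
        mixer_ff_dim=128,
        seed=seed,
    )


def receptive_field_epochs(cfg: ModelConfig) -> int:
    """Receptive field of the sequence mixer in epochs."""
    return 1 + (cfg.seq_kernel - 1) * int(sum(cfg.seq_dilations))


@dataclass
class StagePosterior:
    """Per-epoch 4-class posterior over the scoring classes."""

    logits: np.ndarray  # (n_epochs, 4)
    probabilities: np.ndarray = field(init=False)
    stages: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.probabilities = nn.softmax(self.logits.astype(np.float64), axis=-1)
        self.stages = np.array(
            [int(CLASS_STAGES[i]) for i in self.logits.argmax(axis=-1)],
            dtype=np.int64,
        )


class _ResBlock(nn.Layer):
    """Three convolutions + batch norm with a projection skip, then pooling."""

    def __init__(self, c_in: int, c_out: int, cfg: ModelConfig,
                 rng: np.random.Generator, dtype):
        k = cfg.conv_kernel
        layers: list[nn.Layer] = []
        c = c_in
        for i in range(cfg.convs_per_block):
            layers.append(nn.Conv1d(c, c_out, k, rng=rng, dtype=dtype))
            layers.append(nn.BatchNorm1d(c_out, dtype=dtype))
            if i < cfg.convs_per_block - 1:
                layers.append(nn.ReLU())
            c = c_out
        self.main = nn.Sequential(*layers)
        self.skip = (nn.Conv1d(c_in, c_out, 1, rng=rng, dtype=dtype)
                     if c_in != c_out else None)
        self.relu = nn.ReLU()
        self.pool = nn.MaxPool1d(cfg.pool_factor)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        h = self.main.forward(x, train=train)
        s = self.skip.forward(x, train=train) if self.skip is not None else x
        return self.pool.forward(self.relu.forward(h + s), train=train)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        g = self.relu.backward(self.pool.backward(gy))
        gx = self.main.backward(g)
        if self.skip is not None:
            gx = gx + self.skip.backward(g)
        else:
            gx = gx + g
        return gx

    def params(self) -> list[nn.Param]:
        ps = self.main.params()
        if self.skip is not None:
            ps += self.skip.params()
        return ps


class _Encoder(nn.Layer):
    """Residual-block ladder plus final width-projection convolution."""

    def __init__(self, modality: str, cfg: ModelConfig,
                 rng: np.random.Generator, dtype):
        feats = cfg._features(modality)
        blocks: list[nn.Layer] = []
        c = 1
        for f in feats:
            blocks.append(_ResBlock(c, f, cfg, rng, dtype))
            c = f
        blocks.append(nn.Conv1d(c, cfg.encoder_out_features, 1, rng=rng, dtype=dtype))
        blocks.append(nn.BatchNorm1d(cfg.encoder_out_features, dtype=dtype))
        blocks.append(nn.ReLU())
        self.net = nn.Sequential(*blocks)
        self.modality = modality
        self.expected_len = cfg.input_len(modality)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.asarray(x)
        if x.ndim == 1:
            x = x[None, :]
        if x.shape != (1, self.expected_len):
            raise ValueError(
                f"{self.modality} input must have length {self.expected_len}, "
                f"got {x.shape[-1]}"
            )
        return self.net.forward(x, train=train)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return self.net.backward(gy)

    def params(self) -> list[nn.Param]:
        return self.net.params()


class _FeedForward(nn.Layer):
    def __init__(self, d: int, d_ff: int, rng: np.random.Generator, dtype):
        self.net = nn.Sequential(
            nn.Linear(d, d_ff, rng=rng, dtype=dtype),
            nn.ReLU(),
            nn.Linear(d_ff, d, rng=rng, dtype=dtype),
        )

    def forward(self, x, train=False):
        return self.net.forward(x, train=train)

    def backward(self, gy):
        return self.net.backward(gy)

    def params(self):
        return self.net.params()


class _TransformerBlock(nn.Layer):
    """Post-norm transformer encoder block (attention + position-wise FF)."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator,
                 drop_rng: np.random.Generator, dtype):
        d = cfg.epoch_feature_dim
        self.attn = nn.MultiHeadSelfAttention(d, cfg.mixer_heads, rng=rng, dtype=dtype)
        self.drop1 = nn.Dropout(cfg.mixer_dropout, rng=drop_rng)
        self.ln1 = nn.LayerNorm(d, dtype=dtype)
        self.ff = _FeedForward(d, cfg.mixer_ff_dim, rng, dtype)
        self.drop2 = nn.Dropout(cfg.mixer_dropout, rng=drop_rng)
        self.ln2 = nn.LayerNorm(d, dtype=dtype)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        a = self.ln1.forward(x + self.drop1.forward(self.attn.forward(x, train), train),
                             train)
        return self.ln2.forward(a + self.drop2.forward(self.ff.forward(a, train), train),
                                train)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        g = self.ln2.backward(gy)
        ga = g + self.ff.backward(self.drop2.backward(g))
        g = self.ln1.backward(ga)
        return g + self.attn.backward(self.drop1.backward(g))

    def params(self) -> list[nn.Param]:
        return (self.attn.params() + self.ln1.params()
                + self.ff.params() + self.ln2.params())


class _DilatedUnit(nn.Layer):
    """Residual dilated convolution unit of the sequence mixer, on (D, T)."""

    def __init__(self, d: int, kernel: int, dilation: int,
                 rng: np.random.Generator, dtype):
        self.conv = nn.Conv1d(d, d, kernel, dilation=dilation, rng=rng, dtype=dtype)
        self.relu = nn.ReLU()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return x + self.relu.forward(self.conv.forward(x, train), train)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return gy + self.conv.backward(self.relu.backward(gy))

    def params(self) -> list[nn.Param]:
        return self.conv.params()


def _positional_encoding(n: int, d: int) -> np.ndarray:
    pos = np.arange(n)[:, None]
    i = np.arange(d)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / d)
    pe = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return pe.astype(np.float32)


class SleepStager:
    """Whole-night four-class sleep stager over cardiorespiratory waveforms.

    Parameters
    ----------
    cfg
        Architecture constants (defaults are full scale).
    modalities
        Which input pathways to build: ``("ecg",)`` or ``("ecg", "resp")``.
    dtype
        Parameter dtype; float64 is used by the gradient-check tests.
    """

    def __init__(self, cfg: ModelConfig = ModelConfig(),
                 modalities: tuple[str, ...] = MODALITIES,
                 dtype=np.float32):
        if not modalities:
            raise ValueError("need at least one modality")
        for m in modalities:
            if m not in MODALITIES:
                raise ValueError(f"unknown modality {m!r}")
        self.cfg = cfg
        self.modalities = tuple(modalities)
        self.dtype = dtype
        rng = np.random.default_rng(cfg.seed)
        self._drop_rng = np.random.default_rng(cfg.seed + 1)

        d = cfg.epoch_feature_dim
        self.encoders = {m: _Encoder(m, cfg, rng, dtype) for m in self.modalities}
        self.fusers = {
            m: nn.Linear(cfg.fused_reshape_dim, d, rng=rng, dtype=dtype)
            for m in self.modalities
        }
        self.null_tokens = {
            m: nn.Param((rng.standard_normal(d) * 0.02).astype(dtype))
            for m in self.modalities
        }
        self.pos = _positional_encoding(cfg.n_epochs, d).astype(dtype)
        self.mixer = [
            _TransformerBlock(cfg, rng, self._drop_rng, dtype)
            for _ in range(cfg.mixer_blocks)
        ]
        self.seq_units = [
            _DilatedUnit(d, cfg.seq_kernel, dil, rng, dtype)
            for dil in cfg.seq_dilations
        ]
        self.head = nn.Linear(d, cfg.n_classes, rng=rng, dtype=dtype)
        # keep initial logits near zero so training starts at ~ln(n_classes)
        self.head.w.value *= 0.05

    # ---------------------------------------------------------- components

    def encode(self, x: np.ndarray, modality: str, train: bool = False) -> np.ndarray:
        """Signal encoder: raw waveform -> (out_features, frames) map."""
        return self.encoders[modality].forward(
            np.asarray(x, dtype=self.dtype), train=train
        )

    def fuse_per_epoch(self, feat: np.ndarray, modality: str,
                       train: bool = False) -> np.ndarray:
        """Group encoder frames per epoch and reduce with a shared dense map."""
        C, L = feat.shape
        T, f = self.cfg.n_epochs, self.cfg.frames_per_epoch
        if L != T * f:
            raise ValueError(f"feature length {L} not divisible into {T} epochs")
        grouped = feat.reshape(C, T, f).transpose(1, 2, 0).reshape(T, f * C)
        return self.fusers[modality].forward(grouped, train=train)

    def _unfuse_backward(self, gy: np.ndarray, modality: str) -> np.ndarray:
        g = self.fusers[modality].backward(gy)
        C = self.cfg.encoder_out_features
        T, f = self.cfg.n_epochs, self.cfg.frames_per_epoch
        return g.reshape(T, f, C).transpose(2, 0, 1).reshape(C, T * f)

    def epoch_mixer(self, fused: dict[str, np.ndarray | None],
                    train: bool = False) -> np.ndarray:
        """Sum modality maps (null token for absent ones), add positions, attend."""
        present = {m: v for m, v in fused.items() if v is not None}
        if not present:
            raise ValueError("epoch mixer needs at least one modality")
        z = np.zeros((self.cfg.n_epochs, self.cfg.epoch_feature_dim),
                     dtype=self.dtype)
        for m in self.modalities:
            v = fused.get(m)
            z = z + (v if v is not None else self.null_tokens[m].value[None, :])
        z = z + self.pos
        for blk in self.mixer:
            z = blk.forward(z, train=train)
        return z

    def sequence_mixer(self, z: np.ndarray, train: bool = False) -> StagePosterior:
        """Dilated residual CNN over epochs plus the 4-class dense head."""
        T, d = self.cfg.n_epochs, self.cfg.epoch_feature_dim
        if z.shape != (T, d):
            raise ValueError(f"sequence mixer expects shape {(T, d)}, got {z.shape}")
        h = z.T.copy()  # (D, T)
        for unit in self.seq_units:
            h = unit.forward(h, train=train)
        logits = self.head.forward(h.T.copy(), train=train)
        return StagePosterior(logits=logits)

    # ------------------------------------------------------------- forward

    def forward(self, inp: ModelInput, train: bool = False) -> StagePosterior:
        """Full forward pass on one night."""
        fused: dict[str, np.ndarray | None] = {}
        self._present = []
        for m in self.modalities:
            x = getattr(inp, m)
            if x is None:
                fused[m] = None
            else:
                feat = self.encode(x, m, train=train)
                fused[m] = self.fuse_per_epoch(feat, m, train=train)
                self._present.append(m)
        z = self.epoch_mixer(fused, train=train)
        return self.sequence_mixer(z, train=train)

    def predict(self, inp: ModelInput) -> StagePosterior:
        with nn.no_grad():
            return self.forward(inp, train=False)

    def backward(self, glogits: np.ndarray) -> None:
        """Backpropagate from d(loss)/d(logits) into parameter gradients."""
        g = self.head.backward(glogits).T.copy()
        for unit in reversed(self.seq_units):
            g = unit.backward(g)
        g = g.T.copy()
        for blk in reversed(self.mixer):
            g = blk.backward(g)
        for m in self.modalities:
            if m in self._present:
                gfeat = self._unfuse_backward(g, m)
                self.encoders[m].backward(gfeat)
            else:
                self.null_tokens[m].grad += g.sum(axis=0)

    def loss_and_grad(self, inp: ModelInput, train: bool = True) -> float:
        """Masked cross-entropy on one night; accumulates parameter gradients."""
        post = self.forward(inp, train=train)
        class_labels = inp.labels.copy()
        loss, glog = nn.masked_cross_entropy(
            post.logits, class_labels, inp.loss_mask
        )
        if train and np.isfinite(loss):
            self.backward(glog.astype(self.dtype))
        return loss

    # ---------------------------------------------------------- parameters

    def named_params(self) -> list[tuple[str, nn.Param]]:
        out: list[tuple[str, nn.Param]] = []
        for m in self.modalities:
            out += [(f"enc.{m}.{i}", p)
                    for i, p in enumerate(self.encoders[m].params())]
            out += [(f"fuse.{m}.{i}", p)
                    for i, p in enumerate(self.fusers[m].params())]
            out.append((f"null.{m}", self.null_tokens[m]))
        for b, blk in enumerate(self.mixer):
            out += [(f"mixer.{b}.{i}", p) for i, p in enumerate(blk.params())]
        for u, unit in enumerate(self.seq_units):
            out += [(f"seq.{u}.{i}", p) for i, p in enumerate(unit.params())]
        out += [(f"head.{i}", p) for i, p in enumerate(self.head.params())]
        return out

    def params(self) -> list[nn.Param]:
        return [p for _, p in self.named_params()]

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    def _bn_layers(self) -> list[nn.BatchNorm1d]:
        bns: list[nn.BatchNorm1d] = []

        def walk(layer):
            if isinstance(layer, nn.BatchNorm1d):
                bns.append(layer)
            for attr in ("layers",):
                for sub in getattr(layer, attr, []):
                    walk(sub)
            for attr in ("main", "skip", "net"):
                sub = getattr(layer, attr, None)
                if sub is not None:
                    walk(sub)

        for enc in self.encoders.values():
            walk(enc)
        return bns

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.value.copy() for name, p in self.named_params()}
        for i, bn in enumerate(self._bn_layers()):
            state[f"bnstat.{i}.mean"] = bn.run_mean.copy()
            state[f"bnstat.{i}.var"] = bn.run_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, p in self.named_params():
            v = np.asarray(state[name], dtype=p.value.dtype)
            if v.shape != p.value.shape:
                raise ValueError(f"shape mismatch for {name}")
            p.value = v.copy()
            p.grad = np.zeros_like(p.value)
        for i, bn in enumerate(self._bn_layers()):
            if f"bnstat.{i}.mean" in state:
                bn.run_mean = np.array(state[f"bnstat.{i}.mean"],
                                       dtype=np.float64, copy=True)
                bn.run_var = np.array(state[f"bnstat.{i}.var"],
                                      dtype=np.float64, copy=True)


CHECKPOINT_VERSION = 1


def save_checkpoint(model: SleepStager, path) -> None:
    """Single-file, version-tagged checkpoint (.npz)."""
    meta = json.dumps({
        "version": CHECKPOINT_VERSION,
        "config": asdict(model.cfg),
        "modalities": list(model.modalities),
    })
    np.savez(path, __meta__=np.array(meta), **model.state_dict())


def load_checkpoint(path) -> SleepStager:
    with np.load(path, allow_pickle=False) as f:
        meta = json.loads(str(f["__meta__"]))
        state = {k: f[k] for k in f.files if k != "__meta__"}
    if meta["version"] != CHECKPOINT_VERSION:
        raise ValueError(f"unsupported checkpoint version {meta['version']}")
    c = meta["config"]
    for k in ("ecg_encoder_features", "resp_encoder_features", "seq_dilations"):
        c[k] = tuple(c[k])
    model = SleepStager(ModelConfig(**c), modalities=tuple(meta["modalities"]))
    model.load_state_dict(state)
    return model
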