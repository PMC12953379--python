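"""Training harness: leave-one-subject-out transfer learning.

Implements the evaluation protocol used for small longitudinal cohorts:
every participant serves once as the held-out test subject; the remaining
participants are split deterministically into training and validation sets;
the model is fitted (from scratch or from a pretrained checkpoint) with
AdamW on masked cross-entropy, early-stopped on validation loss with a
patience counter, and the weights of the best validation state are restored
before the test participant's nights are predicted.

Batches are assembled by gradient accumulation: each night is a full model
window, and ``batch_size`` nights contribute gradients to one optimizer
step.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .model import SleepStager
from .types import ModelInput

__all__ = [
    "TrainConfig",
    "LosoSplit",
    "EarlyStopper",
    "make_loso_splits",
    "fit",
    "run_loso",
    "FitHistory",
]

log = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    """Optimization settings.

    The transfer-learning defaults follow the home-monitoring protocol:
    AdamW, fixed learning rate 1e-5, batches of 16 nights, early stopping
    after 5 validation epochs without improvement, best-weight reversion.
    From-scratch training on synthetic cohorts uses a larger rate (1e-3).
    """

    learning_rate: float = 1e-5
    weight_decay: float = 0.01
    batch_size: int = 16
    patience: int = 5
    max_epochs: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class LosoSplit:
    test_participant: str
    train_participants: list[str]
    val_participants: list[str]

    def __post_init__(self) -> None:
        sets = [{self.test_participant}, set(self.train_participants),
                set(self.val_participants)]
        for i in range(3):
            for j in range(i + 1, 3):
                if sets[i] & sets[j]:
                    raise ValueError("train/val/test participant sets overlap")


def make_loso_splits(participants: list[str], seed: int = 0) -> list[LosoSplit]:
    """One split per participant, with deterministic train/validation draws.

    The validation set holds ``max(2, ceil(remaining / 6))`` participants
    (2 of 12 in the reference 13-participant layout).
    """
    participants = list(participants)
    if len(participants) < 4:
        raise ValueError("leave-one-subject-out needs at least 4 participants")
    rng = np.random.default_rng(seed)
    splits = []
    for test in participants:
        rest = [p for p in participants if p != test]
        order = list(rng.permutation(len(rest)))
        n_val = max(2, math.ceil(len(rest) / 6))
        val = [rest[i] for i in order[:n_val]]
        train = [rest[i] for i in order[n_val:]]
        splits.append(LosoSplit(test, sorted(train), sorted(val)))
    return splits


class EarlyStopper:
    """Patience-based early stopping on validation loss.

    Stops after ``patience`` consecutive validation evaluations without a
    strict improvement over the running minimum; remembers the index of the
    best evaluation.
    """

    def __init__(self, patience: int):
        self.patience = patience
        self.best = math.inf
        self.best_index: int | None = None
        self.bad_count = 0
        self.n_seen = 0

    def update(self, val_loss: float) -> bool:
        """Record one validation loss; returns True if training should stop."""
        if val_loss < self.best:
            self.best = val_loss
            self.best_index = self.n_seen
            self.bad_count = 0
        else:
            self.bad_count += 1
        self.n_seen += 1
        return self.bad_count >= self.patience


@dataclass
class FitHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1  # 0-based index into the per-epoch lists
    stopped_early: bool = False


def _mean_loss(model: SleepStager, nights: list[ModelInput]) -> float:
    losses = []
    with nn.no_grad():
        for night in nights:
            post = model.forward(night, train=False)
            loss, _ = nn.masked_cross_entropy(
                post.logits, night.labels, night.loss_mask
            )
            if math.isfinite(loss):
                losses.append(loss)
    return float(np.mean(losses)) if losses else math.nan


def fit(
    model: SleepStager,
    train_nights: list[ModelInput],
    val_nights: list[ModelInput],
    cfg: TrainConfig,
) -> FitHistory:
    """Fit in place; restores the minimum-validation-loss weights on return."""
    if not train_nights or not val_nights:
        raise ValueError("need non-empty training and validation sets")
    rng = np.random.default_rng(cfg.seed)
    opt = nn.AdamW(model.params(), lr=cfg.learning_rate,
                   weight_decay=cfg.weight_decay)
    stopper = EarlyStopper(cfg.patience)
    history = FitHistory()
    best_state = model.state_dict()

    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(train_nights))
        epoch_losses = []
        pending = 0
        opt.zero_grad()
        for idx in order:
            night = train_nights[idx]
            if not night.loss_mask.any():
                log.warning("skipping night with empty loss mask (%s/%s)",
                            night.participant_id, night.night_label)
                continue
            loss = model.loss_and_grad(night, train=True)
            epoch_losses.append(loss)
            pending += 1
            if pending == cfg.batch_size:
                _scale_grads(model, 1.0 / pending)
                opt.step()
                opt.zero_grad()
                pending = 0
        if pending:
            _scale_grads(model, 1.0 / pending)
            opt.step()
            opt.zero_grad()

        val_loss = _mean_loss(model, val_nights)
        history.train_loss.append(
            float(np.mean(epoch_losses)) if epoch_losses else math.nan)
        history.val_loss.append(val_loss)
        improved = val_loss < stopper.best
        stop = stopper.update(val_loss)
        if improved:
            best_state = model.state_dict()
        log.info("epoch %d train %.4f val %.4f%s", epoch,
                 history.train_loss[-1], val_loss, " *" if improved else "")
        if stop:
            history.stopped_early = True
            break

    history.best_epoch = stopper.best_index if stopper.best_index is not None else -1
    model.load_state_dict(best_state)
    return history


def _scale_grads(model: SleepStager, scale: float) -> None:
    for p in model.params():
        p.grad *= scale


@dataclass
class LosoResult:
    predictions: dict[str, dict[str, np.ndarray]]  # participant -> night -> stages
    histories: dict[str, FitHistory]


def run_loso(
    cohort: list[ModelInput],
    cfg: TrainConfig,
    model_factory,
    base_state: dict[str, np.ndarray] | None = None,
) -> LosoResult:
    """Leave-one-subject-out evaluation over a cohort of model windows.

    ``model_factory()`` builds a fresh model for each split;
    ``base_state`` (a ``state_dict``) initializes it for transfer learning.
    Returns per-participant, per-night predicted stage sequences (every
    included night of every participant predicted exactly once, always by a
    model that never saw that participant).
    """
    participants = sorted({n.participant_id for n in cohort})
    splits = make_loso_splits(participants, seed=cfg.seed)
    predictions: dict[str, dict[str, np.ndarray]] = {}
    histories: dict[str, FitHistory] = {}
    for split in splits:
        train = [n for n in cohort if n.participant_id in split.train_participants]
        val = [n for n in cohort if n.participant_id in split.val_participants]
        test = [n for n in cohort if n.participant_id == split.test_participant]
        model = model_factory()
        if base_state is not None:
            model.load_state_dict(base_state)
        histories[split.test_participant] = fit(model, train, val, cfg)
        preds: dict[str, np.ndarray] = {}
        for night in test:
            preds[night.night_label] = model.predict(night).stages
        predictions[split.test_participant] = preds
        log.info("finished split test=%s", split.test_participant)
    return LosoResult(predictions=predictions, histories=histories)
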