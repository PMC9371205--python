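"""The stacked bidirectional-LSTM activity classifier and its training regime.

Architecture (default "paper" layout, input = 6 channel-steps x 90-frame
feature vectors):

    BiLSTM 64 -> BiLSTM 32 -> BiLSTM 16 -> BiLSTM 16 (final state)
    -> Flatten -> Dense 50 (ReLU) -> BatchNorm -> Dropout 0.5 -> Dense 8 (softmax)

with dropout 0.25 and recurrent dropout 0.25 on every recurrent layer. The
per-layer parameter counts of this stack are
79,360 / 41,216 / 10,368 / 6,272 / 0 / 1,650 / 200 / 408 (the bidirectional
closed form is 2*4u*(d+u+1)); ``strict_paper`` turns any deviation into a
construction error.

Training: Adam, sparse categorical cross-entropy, Xavier uniform
initialisation, batch size 64, ten epochs, initial learning rate 1e-3
declining per epoch as ``lr(e) = 1e-3 * 800**(-e/100)``.

Subject-wise evaluation uses hold-one-subject-out splitting: whole subjects
are removed from training to form the validation and test sets, so reported
performance reflects generalisation to unseen swimmers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import nn
from .activities import ImuRecording, LabelSequence, N_CLASSES
from .preprocess import ChannelScaler, preprocess
from .windowing import WINDOW_FRAMES, WindowBatch, make_windows, shuffle_windows

__all__ = [
    "ModelConfig",
    "TrainingConfig",
    "SwimClassifier",
    "TABLE_PARAM_COUNTS",
    "build_model",
    "lr_schedule",
    "split_hoscv",
    "train",
    "bidirectional_param_count",
]

#: Published per-layer parameter counts the strict build must reproduce
#: (recurrent x4, flatten, dense-50, batch-norm, dense-8).
TABLE_PARAM_COUNTS = (79360, 41216, 10368, 6272, 0, 1650, 200, 408)


def bidirectional_param_count(units: int, input_dim: int) -> int:
    """Closed-form parameter count of a bidirectional LSTM layer: 2*4u*(d+u+1)."""
    return 2 * 4 * units * (input_dim + units + 1)


@dataclass
class ModelConfig:
    units: tuple[int, ...] = (64, 32, 16, 16)
    dense_units: int = 50
    n_classes: int = N_CLASSES
    dropout: float = 0.25
    recurrent_dropout: float = 0.25
    dense_dropout: float = 0.5
    batch_size: int = 64
    window: int = WINDOW_FRAMES
    n_channels: int = 6
    layout: str = "paper"

    @property
    def input_shape(self) -> tuple[int, int]:
        """(sequence steps, features per step) seen by the first recurrent layer."""
        if self.layout == "paper":
            return (self.n_channels, self.window)
        return (self.window, self.n_channels)


@dataclass
class TrainingConfig:
    epochs: int = 10
    initial_lr: float = 1e-3
    lr_decay_base: float = 800.0
    lr_decay_scale: float = 100.0
    seed: int = 0
    class_weighted_loss: bool = False
    stride: int = 1  # training-window stride; affects dataset size only

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.initial_lr <= 0:
            raise ValueError("initial learning rate must be positive")


def lr_schedule(epoch: int, cfg: TrainingConfig | None = None) -> float:
    """Per-epoch learning rate: lr0 * base**(-epoch/scale), non-increasing."""
    cfg = cfg or TrainingConfig()
    if epoch < 0:
        raise ValueError("epoch must be non-negative")
    return cfg.initial_lr * cfg.lr_decay_base ** (-epoch / cfg.lr_decay_scale)


@dataclass
class SwimClassifier:
    """A trained (or trainable) network plus everything needed to apply it:
    the architecture config, the channel scaler fitted on training subjects,
    and the per-epoch training history."""

    net: nn.Sequential
    config: ModelConfig
    scaler: ChannelScaler | None = None
    training_config: TrainingConfig | None = None
    history: dict = field(default_factory=dict)

    def layer_param_counts(self) -> list[int]:
        """Parameter counts for the table layers (dropout rows excluded)."""
        return [
            layer.n_params()
            for layer in self.net.layers
            if not isinstance(layer, nn.Dropout)
        ]

    @property
    def n_params(self) -> int:
        return sum(self.layer_param_counts())

    def predict_proba_windows(self, batch: WindowBatch) -> np.ndarray:
        """Per-window class probabilities (rows sum to 1), evaluation mode."""
        if batch.layout != self.config.layout:
            raise ValueError(
                f"window layout {batch.layout!r} does not match model layout "
                f"{self.config.layout!r}"
            )
        bs = self.config.batch_size
        out = np.empty((batch.n_windows, self.config.n_classes))
        for i in range(0, batch.n_windows, bs):
            logits = self.net.forward(
                batch.tensor[i : i + bs].astype(self.net.dtype, copy=False)
            )
            out[i : i + bs] = nn.softmax(logits)
        return out

    def predict_sequence(
        self, rec: ImuRecording, stride: int = 1
    ) -> tuple[LabelSequence, np.ndarray]:
        """Predict one activity label per working-rate frame.

        Raw recordings are conditioned internally with the stored scaler;
        preprocessed recordings are consumed as-is.
        """
        if not rec.preprocessed:
            if self.scaler is None:
                raise ValueError("model has no scaler; preprocess the recording first")
            rec = preprocess(rec, self.scaler)
        batch = make_windows(
            rec, stride=stride, pad_edges=True,
            window=self.config.window, layout=self.config.layout,
        )
        probs = self.predict_proba_windows(batch)
        labels = probs.argmax(axis=1)
        seq = LabelSequence(labels, sample_rate=rec.sample_rate, provenance="raw_prediction")
        return seq, probs


def build_model(
    cfg: ModelConfig | None = None,
    seed: int = 0,
    strict_paper: bool = False,
    scaler: ChannelScaler | None = None,
    dtype=np.float64,
) -> SwimClassifier:
    """Construct the untrained network with Xavier-uniform initial weights.

    ``strict_paper`` asserts that the resulting per-layer parameter counts
    equal :data:`TABLE_PARAM_COUNTS` exactly and raises otherwise.
    """
    cfg = cfg or ModelConfig()
    rng = np.random.default_rng(seed)
    steps, feats = cfg.input_shape
    layers: list[nn.Layer] = []
    d = feats
    for k, u in enumerate(cfg.units):
        layers.append(
            nn.BiLSTM(
                d, u,
                return_sequences=(k < len(cfg.units) - 1),
                dropout=cfg.dropout,
                recurrent_dropout=cfg.recurrent_dropout,
                rng=rng, dtype=dtype,
            )
        )
        d = 2 * u
    layers.append(nn.Flatten())
    layers.append(nn.Dense(d, cfg.dense_units, activation="relu", rng=rng, dtype=dtype))
    layers.append(nn.BatchNorm(cfg.dense_units, dtype=dtype))
    layers.append(nn.Dropout(cfg.dense_dropout))
    layers.append(nn.Dense(cfg.dense_units, cfg.n_classes, activation="linear",
                           rng=rng, dtype=dtype))
    clf = SwimClassifier(nn.Sequential(layers), cfg, scaler=scaler)
    if strict_paper:
        counts = tuple(clf.layer_param_counts())
        if counts != TABLE_PARAM_COUNTS:
            raise ValueError(
                "strict_paper build: layer parameter counts "
                f"{counts} != required {TABLE_PARAM_COUNTS}"
            )
    return clf


def split_hoscv(
    sessions: Sequence,
    seed: int = 0,
    single_holdout_subject: bool = False,
) -> tuple[list, list, list]:
    """Hold-one-subject-out split into (train, validation, test) session lists.

    Subject-wise and disjoint: by default one randomly chosen subject forms
    the validation set and a second, distinct subject the test set; with
    ``single_holdout_subject`` the same held-out subject serves as both
    (at the cost of validation-based monitoring leaking into testing).
    """
    subjects = sorted({s.subject_id for s in sessions})
    if len(subjects) < 3:
        raise ValueError("HOSCV needs at least 3 subjects")
    rng = np.random.default_rng(seed)
    if single_holdout_subject:
        held = rng.choice(len(subjects), size=1, replace=False)
        val_subj = test_subj = subjects[int(held[0])]
    else:
        held = rng.choice(len(subjects), size=2, replace=False)
        val_subj, test_subj = subjects[int(held[0])], subjects[int(held[1])]
    val = [s for s in sessions if s.subject_id == val_subj]
    test = [s for s in sessions if s.subject_id == test_subj]
    train_set = [s for s in sessions if s.subject_id not in (val_subj, test_subj)]
    return train_set, val, test


def _class_weights(targets: np.ndarray, n_classes: int) -> np.ndarray:
    counts = np.bincount(targets, minlength=n_classes).astype(float)
    counts[counts == 0] = 1.0
    w = counts.sum() / (n_classes * counts)
    return w


def train(
    model: SwimClassifier,
    train_batch: WindowBatch,
    val_batch: WindowBatch | None,
    tcfg: TrainingConfig | None = None,
) -> SwimClassifier:
    """Train in place for ``tcfg.epochs`` epochs; returns the same handle.

    Deterministic given the seed (single-threaded): the window order is
    reshuffled each epoch and the dropout masks are drawn from one seeded
    generator.
    """
    tcfg = tcfg or TrainingConfig()
    if train_batch.targets is None:
        raise ValueError("training batch must carry targets")
    net = model.net
    opt = nn.Adam(net, lr=tcfg.initial_lr)
    drop_rng = np.random.default_rng((tcfg.seed * 2654435761 + 97) % (2**31))
    weights = (
        _class_weights(train_batch.targets, model.config.n_classes)
        if tcfg.class_weighted_loss
        else None
    )
    bs = model.config.batch_size
    history = {"epoch": [], "lr": [], "train_loss": [], "val_accuracy": []}
    for epoch in range(tcfg.epochs):
        opt.lr = lr_schedule(epoch, tcfg)
        shuffled = shuffle_windows(train_batch, seed=(tcfg.seed + epoch) % (2**31))
        losses = []
        for i in range(0, shuffled.n_windows, bs):
            xb = shuffled.tensor[i : i + bs].astype(net.dtype, copy=False)
            yb = shuffled.targets[i : i + bs]
            logits = net.forward(xb, train=True, rng=drop_rng)
            loss, dlogits = nn.sparse_ce_loss_and_grad(logits, yb, weights)
            net.backward(dlogits)
            opt.step()
            losses.append(loss)
        val_acc = np.nan
        if val_batch is not None and val_batch.targets is not None:
            probs = model.predict_proba_windows(val_batch)
            val_acc = float((probs.argmax(axis=1) == val_batch.targets).mean())
        history["epoch"].append(epoch)
        history["lr"].append(opt.lr)
        history["train_loss"].append(float(np.mean(losses)))
        history["val_accuracy"].append(val_acc)
    model.history = history
    model.training_config = tcfg
    return model
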