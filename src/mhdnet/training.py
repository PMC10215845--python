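"""Training loop and whole-record inference.

The network's sigmoid output is optimized against the binary pulse-train
targets with (binary) cross-entropy under Adam at a fixed learning rate.
Model selection keeps the parameter snapshot with the best validation Dice
score. Everything is deterministic under a fixed seed on one device: the
parameter init, the batch shuffling and the synthetic data all derive from
explicit generators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .evaluation import segmentation_metrics
from .exceptions import ConfigurationError, LeakageError
from .labeling import SegmentSet
from .network import MhdNet, ModelConfig
from .preprocess import normalize_segment


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 100
    batch_size: int = 128
    learning_rate: float = 1e-3
    loss: str = "binary_cross_entropy"
    pos_weight: float = 1.0
    seed: int = 0
    model_selection: str = "best_val_dsc"
    device: str = "cpu"

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("epochs/batch_size/learning_rate out of range")
        if self.loss != "binary_cross_entropy":
            raise ValueError(f"unsupported loss {self.loss!r}")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_dsc: list[float] = field(default_factory=list)
    best_epoch: int = -1


def _stack_segments(segments: SegmentSet, dtype=np.float32):
    x = np.stack([normalize_segment(s) for s in segments.inputs]).astype(dtype)
    y = np.stack(segments.targets).astype(dtype)[:, None, :]
    return x, y


def _evaluate_val(model: MhdNet, xv, yv, batch_size, pos_weight):
    losses = []
    dsc_pred = []
    for lo in range(0, len(xv), batch_size):
        xb = xv[lo : lo + batch_size]
        yb = yv[lo : lo + batch_size]
        logits = model.forward(ad.Tensor(xb))
        losses.append(
            float(ad.bce_with_logits(logits, yb, pos_weight).data) * len(xb)
        )
        dsc_pred.append(logits.data >= 0.0)  # sigmoid(z) >= 0.5 <=> z >= 0
    pred = np.concatenate(dsc_pred, axis=0)
    dsc = segmentation_metrics(pred, yv >= 0.5).dsc_pct
    return sum(losses) / len(xv), dsc


def train_model(
    train_segments: SegmentSet,
    val_segments: SegmentSet,
    model_config: ModelConfig,
    train_config: TrainConfig,
) -> tuple[MhdNet, TrainHistory]:
    """Train on the train split, select the best epoch on validation DSC."""
    if len(train_segments) == 0 or len(val_segments) == 0:
        raise ConfigurationError("empty train or validation segment set")
    overlap = train_segments.subjects & val_segments.subjects
    if overlap:
        raise LeakageError(f"subjects shared between train and val: {sorted(overlap)}")

    model = MhdNet(model_config, seed=train_config.seed)
    rng = np.random.default_rng(np.random.SeedSequence([train_config.seed, 7]))
    xt, yt = _stack_segments(train_segments, model.dtype)
    xv, yv = _stack_segments(val_segments, model.dtype)
    opt = ad.Adam(model.parameters(), lr=train_config.learning_rate)
    history = TrainHistory()
    best_dsc = -1.0
    best_state = model.get_state()
    bs = train_config.batch_size
    for _epoch in range(train_config.epochs):
        order = rng.permutation(len(xt))
        epoch_loss = 0.0
        for lo in range(0, len(order), bs):
            idx = order[lo : lo + bs]
            logits = model.forward(ad.Tensor(xt[idx]))
            loss = ad.bce_with_logits(logits, yt[idx], train_config.pos_weight)
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(idx)
        vloss, vdsc = _evaluate_val(model, xv, yv, bs, train_config.pos_weight)
        history.train_loss.append(epoch_loss / len(xt))
        history.val_loss.append(vloss)
        history.val_dsc.append(vdsc)
        if vdsc > best_dsc:
            best_dsc = vdsc
            history.best_epoch = _epoch
            best_state = model.get_state()
    model.set_state(best_state)
    return model, history


def overfit_batch(
    segments: SegmentSet,
    model_config: ModelConfig,
    iterations: int = 200,
    learning_rate: float = 1e-3,
    seed: int = 0,
    pos_weight: float = 1.0,
) -> tuple[MhdNet, float]:
    """Memorize one batch; returns the model and its training-set DSC.

    Sanity check that the architecture + optimizer can drive the loss to a
    near-perfect fit on data it has seen.
    """
    model = MhdNet(model_config, seed=seed)
    x, y = _stack_segments(segments, model.dtype)
    opt = ad.Adam(model.parameters(), lr=learning_rate)
    for _ in range(iterations):
        logits = model.forward(ad.Tensor(x))
        loss = ad.bce_with_logits(logits, y, pos_weight)
        opt.zero_grad()
        loss.backward()
        opt.step()
    pred = model.forward(ad.Tensor(x)).data >= 0.0
    return model, segmentation_metrics(pred, y >= 0.5).dsc_pct


def predict_masks(
    record,
    model: MhdNet,
    window_s: float = 4.0,
    batch_size: int = 32,
) -> np.ndarray:
    """Per-sample R-pulse probabilities for a whole (preprocessed) record.

    The record is tiled into non-overlapping windows; a trailing partial
    window is zero-padded to full length and the prediction cropped back.
    """
    w = int(round(window_s * record.fs))
    n = record.signals.shape[-1]
    n_windows = max(1, -(-n // w))
    windows = np.zeros((n_windows, record.signals.shape[0], w), dtype=model.dtype)
    for i in range(n_windows):
        lo = i * w
        chunk = record.signals[:, lo : lo + w]
        windows[i, :, : chunk.shape[-1]] = normalize_segment(chunk)
    probs = np.empty((n_windows, w), dtype=float)
    for lo in range(0, n_windows, batch_size):
        logits = model.forward_np(windows[lo : lo + batch_size])
        probs[lo : lo + batch_size] = 1.0 / (1.0 + np.exp(-logits))
    return probs.reshape(-1)[:n]
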