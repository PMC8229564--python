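"""Semantic beta-cell segmentation: compact U-Net, training and evaluation.

A U-Net maps selected channel planes to a per-pixel cell probability; masks
are obtained by thresholding at 0.5.  The network here is deliberately
desk-scale (a few base filters, reduced input size) - the point of the module
is the training/evaluation protocol (per-pixel binary cross-entropy, early
stopping on validation loss, K-fold cross-validation partitioned by image
with optional transfer pretraining, pixel confusion-matrix metrics), which is
model-agnostic: the pipeline equally accepts externally predicted masks.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np

from ._nn import Adam, Conv2D, MaxPool2, ReLU, Upsample2, bce_with_logits, sigmoid

__all__ = [
    "UNetConfig",
    "SegMetrics",
    "CrossValConfig",
    "UNet",
    "build_unet",
    "train",
    "predict_proba",
    "predict_mask",
    "evaluate",
    "iou",
    "cross_validate",
    "make_training_pairs",
]


@dataclass(frozen=True)
class UNetConfig:
    input_size: int = 512
    in_channels: int = 2
    depth: int = 2
    base_filters: int = 8
    threshold: float = 0.5
    epochs_max: int = 20
    early_stop_patience: int = 10
    learning_rate: float = 1e-2
    batch_size: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if not (0 < self.threshold < 1):
            raise ValueError("threshold must lie in (0, 1)")


@dataclass(frozen=True)
class SegMetrics:
    """Pixel-wise segmentation scores; all in [0, 1] except loss and epoch."""

    accuracy: float
    loss: float
    precision: float
    recall: float
    f1: float
    epoch: float = float("nan")


@dataclass(frozen=True)
class CrossValConfig:
    K: int = 10
    seed: int = 0
    pretrain_dataset: list | None = None

    def __post_init__(self) -> None:
        if self.K < 2:
            raise ValueError("K must be >= 2")


class UNet:
    """Contracting/expanding fully convolutional network with skip links."""

    def __init__(self, cfg: UNetConfig):
        if cfg.input_size % (2**cfg.depth) != 0:
            raise ValueError(
                f"input_size {cfg.input_size} not divisible by 2^depth={2**cfg.depth}"
            )
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        f = cfg.base_filters
        self.enc = []
        c_in = cfg.in_channels
        for level in range(cfg.depth):
            c_out = f * 2**level
            self.enc.append(
                {
                    "conv1": Conv2D(c_in, c_out, 3, rng),
                    "relu1": ReLU(),
                    "conv2": Conv2D(c_out, c_out, 3, rng),
                    "relu2": ReLU(),
                    "pool": MaxPool2(),
                }
            )
            c_in = c_out
        c_mid = f * 2**cfg.depth
        self.mid = {
            "conv1": Conv2D(c_in, c_mid, 3, rng),
            "relu1": ReLU(),
            "conv2": Conv2D(c_mid, c_mid, 3, rng),
            "relu2": ReLU(),
        }
        self.dec = []
        c_in = c_mid
        for level in reversed(range(cfg.depth)):
            c_skip = f * 2**level
            self.dec.append(
                {
                    "up": Upsample2(),
                    "conv1": Conv2D(c_in + c_skip, c_skip, 3, rng),
                    "relu1": ReLU(),
                    "conv2": Conv2D(c_skip, c_skip, 3, rng),
                    "relu2": ReLU(),
                }
            )
            c_in = c_skip
        self.head = Conv2D(c_in, 1, 1, rng)

    # -- parameter plumbing -------------------------------------------------
    def _conv_layers(self):
        for block in [*self.enc, self.mid, *self.dec]:
            for key in ("conv1", "conv2"):
                if key in block:
                    yield block[key]
        yield self.head

    def params(self):
        out = []
        for conv in self._conv_layers():
            out.extend(conv.params())
        return out

    def get_weights(self):
        return [(c.W.copy(), c.b.copy()) for c in self._conv_layers()]

    def set_weights(self, weights):
        for conv, (W, b) in zip(self._conv_layers(), weights):
            conv.W[...] = W
            conv.b[...] = b

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        """Logits of shape (B, 1, H, W) for input (B, C, H, W)."""
        x = np.ascontiguousarray(x, dtype=np.float32)
        skips = []
        for blk in self.enc:
            x = blk["relu1"].forward(blk["conv1"].forward(x))
            x = blk["relu2"].forward(blk["conv2"].forward(x))
            skips.append(x)
            x = blk["pool"].forward(x)
        x = self.mid["relu1"].forward(self.mid["conv1"].forward(x))
        x = self.mid["relu2"].forward(self.mid["conv2"].forward(x))
        self._skip_channels = []
        for blk, skip in zip(self.dec, reversed(skips)):
            x = blk["up"].forward(x)
            self._skip_channels.append(skip.shape[1])
            x = np.concatenate([skip, x], axis=1)
            x = blk["relu1"].forward(blk["conv1"].forward(x))
            x = blk["relu2"].forward(blk["conv2"].forward(x))
        return self.head.forward(x)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.head.backward(dlogits)
        dskips = []  # gradients w.r.t. skips, shallowest level first
        for blk, c_skip in zip(reversed(self.dec), reversed(self._skip_channels)):
            d = blk["conv1"].backward(blk["relu1"].backward(
                blk["conv2"].backward(blk["relu2"].backward(d))
            ))
            dskips.append(d[:, :c_skip])
            d = blk["up"].backward(d[:, c_skip:])
        d = self.mid["conv1"].backward(self.mid["relu1"].backward(
            self.mid["conv2"].backward(self.mid["relu2"].backward(d))
        ))
        for blk, dskip in zip(reversed(self.enc), reversed(dskips)):
            d = blk["pool"].backward(d) + dskip
            d = blk["conv1"].backward(blk["relu1"].backward(
                blk["conv2"].backward(blk["relu2"].backward(d))
            ))


def build_unet(cfg: UNetConfig) -> UNet:
    return UNet(cfg)


# ---------------------------------------------------------------------------
# data handling


def make_training_pairs(islets, channel_names=("insulin", "nuclei")):
    """Turn generated islets into (input, target) training pairs.

    Inputs are the selected channels stacked to (C, H, W) and scaled to
    [0, 1]; targets are the {0,1} semantic masks.
    """
    pairs = []
    for islet in islets:
        x = np.stack(
            [islet.channels[name].pixels.astype(np.float32) / 255.0 for name in channel_names]
        )
        y = islet.semantic_mask().astype(np.float32)
        pairs.append((x, y))
    return pairs


def _batches(pairs, batch_size, order):
    for start in range(0, len(order), batch_size):
        idx = order[start : start + batch_size]
        x = np.stack([pairs[i][0] for i in idx])
        y = np.stack([pairs[i][1] for i in idx])[:, None]
        yield x, y


# ---------------------------------------------------------------------------
# training / prediction


def train(model: UNet, train_pairs, val_pairs, cfg: UNetConfig | None = None):
    """Fit by mini-batch Adam on per-pixel binary cross-entropy.

    Stops at ``epochs_max`` or once validation loss has failed to improve for
    ``early_stop_patience`` epochs, restoring the best weights.  Returns
    ``(model, history)`` where history is one dict per run epoch with
    train/validation losses; ``history[-1]["stopped_epoch"]`` is the epoch
    whose weights are kept.
    """
    cfg = cfg or model.cfg
    if len(train_pairs) == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(cfg.seed + 1)
    opt = Adam(model.params(), lr=cfg.learning_rate)
    history = []
    best_val = np.inf
    best_weights = model.get_weights()
    best_epoch = 0
    since_best = 0
    for epoch in range(1, cfg.epochs_max + 1):
        order = rng.permutation(len(train_pairs))
        train_losses = []
        for x, y in _batches(train_pairs, cfg.batch_size, order):
            logits = model.forward(x)
            loss, dz = bce_with_logits(logits, y)
            opt.zero_grad()
            model.backward(dz)
            opt.step()
            train_losses.append(loss)
        row = {"epoch": epoch, "train_loss": float(np.mean(train_losses))}
        if val_pairs:
            val_losses = [
                bce_with_logits(model.forward(x), y)[0]
                for x, y in _batches(val_pairs, cfg.batch_size, np.arange(len(val_pairs)))
            ]
            row["val_loss"] = float(np.mean(val_losses))
            if row["val_loss"] < best_val - 1e-9:
                best_val = row["val_loss"]
                best_weights = model.get_weights()
                best_epoch = epoch
                since_best = 0
            else:
                since_best += 1
        history.append(row)
        if val_pairs and since_best >= cfg.early_stop_patience:
            break
    if val_pairs:
        model.set_weights(best_weights)
        history[-1]["stopped_epoch"] = best_epoch
    else:
        history[-1]["stopped_epoch"] = history[-1]["epoch"]
    return model, history


def predict_proba(model: UNet, x: np.ndarray) -> np.ndarray:
    """Per-pixel cell probability for one (C, H, W) input."""
    x = np.asarray(x, dtype=np.float32)
    if x.ndim == 2:
        x = x[None]
    if x.shape[-1] != model.cfg.input_size or x.shape[-2] != model.cfg.input_size:
        raise ValueError(
            f"plane shape {x.shape[-2:]} does not match input_size {model.cfg.input_size}"
        )
    return sigmoid(model.forward(x[None]))[0, 0]


def predict_mask(model: UNet, x: np.ndarray) -> np.ndarray:
    """{0,1} mask: probability map thresholded at ``cfg.threshold``."""
    return (predict_proba(model, x) > model.cfg.threshold).astype(np.uint8)


# ---------------------------------------------------------------------------
# evaluation


def evaluate(pred: np.ndarray, truth: np.ndarray, prob: np.ndarray | None = None) -> SegMetrics:
    """Pixel confusion-matrix metrics of a predicted mask against truth.

    accuracy=(TP+TN)/N, precision=TP/(TP+FP), recall=TP/(TP+FN) and the F1
    harmonic mean, with zero-denominator ratios defined as 0.  ``loss`` is the
    mean binary cross-entropy of the probability map when one is supplied
    (NaN otherwise).
    """
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if pred.shape != truth.shape:
        raise ValueError("shape mismatch")
    tp = int(np.sum(pred & truth))
    fp = int(np.sum(pred & ~truth))
    fn = int(np.sum(~pred & truth))
    tn = int(np.sum(~pred & ~truth))
    return _metrics_from_counts(tp, fp, fn, tn, _bce_loss(prob, truth))


def _bce_loss(prob, truth) -> float:
    if prob is None:
        return float("nan")
    p = np.clip(np.asarray(prob, dtype=float), 1e-7, 1 - 1e-7)
    y = np.asarray(truth).astype(float)
    return float(np.mean(-(y * np.log(p) + (1 - y) * np.log(1 - p))))


def _metrics_from_counts(tp, fp, fn, tn, loss, epoch=float("nan")) -> SegMetrics:
    n = tp + fp + fn + tn
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return SegMetrics(
        accuracy=(tp + tn) / n if n else 0.0,
        loss=loss,
        precision=precision,
        recall=recall,
        f1=f1,
        epoch=epoch,
    )


def iou(pred: np.ndarray, truth: np.ndarray) -> float:
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    union = np.sum(pred | truth)
    return float(np.sum(pred & truth) / union) if union else 1.0


# ---------------------------------------------------------------------------
# cross-validation


@dataclass
class CrossValResult:
    fold_metrics: list
    mean: SegMetrics
    fold_indices: list


def cross_validate(dataset, cv_cfg: CrossValConfig, unet_cfg: UNetConfig) -> CrossValResult:
    """K-fold cross-validation partitioned by image.

    Images (never pixels) are shuffled and split into K folds; each fold in
    turn is the validation set for a freshly initialised model trained on the
    other K-1 folds (optionally pretrained on ``cv_cfg.pretrain_dataset``
    first, i.e. transfer learning).  Per-fold metrics pool the pixel
    confusion counts over the fold's validation images; the mean row is the
    arithmetic mean across folds, with the mean stopping epoch.
    """
    n = len(dataset)
    if cv_cfg.K > n:
        raise ValueError(f"K={cv_cfg.K} exceeds dataset size {n}")
    rng = np.random.default_rng(cv_cfg.seed)
    order = rng.permutation(n)
    folds = [list(f) for f in np.array_split(order, cv_cfg.K)]
    fold_metrics = []
    for fold_i, val_idx in enumerate(folds):
        train_idx = [i for f in folds for i in f if f is not val_idx]
        model = build_unet(replace(unet_cfg, seed=unet_cfg.seed + 1000 * fold_i))
        if cv_cfg.pretrain_dataset:
            model, _ = train(model, cv_cfg.pretrain_dataset, None, model.cfg)
        model, history = train(
            model, [dataset[i] for i in train_idx], [dataset[i] for i in val_idx], model.cfg
        )
        tp = fp = fn = tn = 0
        losses = []
        for i in val_idx:
            x, y = dataset[i]
            prob = predict_proba(model, x)
            pred = prob > model.cfg.threshold
            truth = y.astype(bool)
            tp += int(np.sum(pred & truth))
            fp += int(np.sum(pred & ~truth))
            fn += int(np.sum(~pred & truth))
            tn += int(np.sum(~pred & ~truth))
            losses.append(_bce_loss(prob, truth))
        fold_metrics.append(
            _metrics_from_counts(
                tp, fp, fn, tn, float(np.mean(losses)), float(history[-1]["stopped_epoch"])
            )
        )
    mean = SegMetrics(
        **{
            name: float(np.mean([getattr(m, name) for m in fold_metrics]))
            for name in ("accuracy", "loss", "precision", "recall", "f1", "epoch")
        }
    )
    return CrossValResult(fold_metrics, mean, folds)
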