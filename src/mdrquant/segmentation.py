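"""U-Net tissue segmentation of MLO mammograms and DICE evaluation.

The segmenter maps a normalized grayscale image to a four-class label mask
(background / fat / gland / pectoral muscle) with a classic encoder–decoder
U-Net: per level two 3x3 conv + ReLU blocks, 2x2 max-pool downsampling,
nearest-neighbour upsampling, and skip connections concatenating encoder
features into the decoder for pixel-precise boundaries. Channel width
doubles per level. The final 1x1 convolution emits per-class logits; the
predicted label is the per-pixel argmax (ties resolved to the lowest class
index).

Segmentation accuracy is reported with the DICE coefficient
``2|X ∩ Y| / (|X| + |Y|)`` per tissue class, and as the unweighted (macro)
mean over the three tissue classes, background excluded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from skimage.transform import resize

from . import nn
from .errors import ConfigurationError, DataError, ShapeError
from .types import (
    IntensityImage,
    LabelMask,
    N_CLASSES,
    TISSUE_LABELS,
    LABEL_NAMES,
    as_labels,
    as_pixels,
    check_same_shape,
)

__all__ = [
    "TrainConfig",
    "TrainingHistory",
    "UNetSegmenter",
    "train_segmenter",
    "predict_mask",
    "dice_coefficient",
    "macro_dice",
    "per_class_dice",
    "resample_pair",
]


# ---------------------------------------------------------------------------
# DICE
# ---------------------------------------------------------------------------

def dice_coefficient(pred, truth, class_id: int) -> float:
    """DICE overlap for one tissue class between two label masks.

    Returns ``2|X∩Y| / (|X|+|Y|)`` where X, Y are the binary masks of
    ``class_id``. Defined as 1.0 when both masks are empty for that class
    and 0.0 when exactly one is empty.
    """
    if class_id not in TISSUE_LABELS:
        raise ValueError(f"class_id must be one of {TISSUE_LABELS}, got {class_id}")
    p = as_labels(pred)
    t = as_labels(truth)
    check_same_shape(p, t)
    x = p == class_id
    y = t == class_id
    denom = int(x.sum()) + int(y.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((x & y).sum()) / denom


def per_class_dice(pred, truth) -> dict[int, float]:
    """DICE for each tissue class (fat, gland, pectoral)."""
    return {c: dice_coefficient(pred, truth, c) for c in TISSUE_LABELS}


def macro_dice(pred, truth) -> float:
    """Unweighted mean DICE over the three tissue classes."""
    d = per_class_dice(pred, truth)
    return float(np.mean([d[c] for c in TISSUE_LABELS]))


def _pooled_dice(preds: np.ndarray, truths: np.ndarray) -> dict[int, float]:
    """Per-class DICE pooled over a whole stack of masks (N, H, W)."""
    out = {}
    for c in TISSUE_LABELS:
        x = preds == c
        y = truths == c
        denom = int(x.sum()) + int(y.sum())
        out[c] = 1.0 if denom == 0 else 2.0 * int((x & y).sum()) / denom
    return out


# ---------------------------------------------------------------------------
# configuration and history
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainConfig:
    """Training hyper-parameters.

    ``target_size`` is (width, height); both must be divisible by
    ``2**depth`` so pooling/upsampling round-trips exactly. The defaults
    mirror the full protocol (100 epochs at 320x384, 4 levels); tests and
    the synthetic-phantom benchmark use a thin variant for CPU speed.
    """

    epochs: int = 100
    batch_size: int = 4
    learning_rate: float = 3e-3
    depth: int = 4
    base_channels: int = 16
    loss: str = "cross-entropy"  # or "cross-entropy+dice"
    seed: int = 0
    target_size: tuple[int, int] = (320, 384)
    dice_loss_weight: float = 0.5

    def validate(self) -> None:
        if self.epochs < 0:
            raise ConfigurationError("epochs must be >= 0")
        if self.batch_size < 1 or self.base_channels < 1 or self.depth < 1:
            raise ConfigurationError("batch_size, base_channels and depth must be >= 1")
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be positive")
        if self.loss not in ("cross-entropy", "cross-entropy+dice"):
            raise ConfigurationError(f"unknown loss {self.loss!r}")
        f = 2 ** self.depth
        w, h = self.target_size
        if w % f or h % f:
            raise ConfigurationError(
                f"target_size {self.target_size} must be divisible by 2**depth = {f}"
            )


@dataclass
class TrainingHistory:
    """Per-epoch training loss and held-out DICE scores."""

    records: list[dict] = field(default_factory=list)

    def append(self, **kw) -> None:
        self.records.append(kw)

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        cols = ["epoch", "loss", "macro_dice", "dice_fat", "dice_gland", "dice_pectoral"]
        return pd.DataFrame(self.records, columns=cols)

    @property
    def final_macro_dice(self) -> float:
        return float(self.records[-1]["macro_dice"]) if self.records else float("nan")


# ---------------------------------------------------------------------------
# the network
# ---------------------------------------------------------------------------

class _UNet:
    """Plain U-Net over the numpy layer kit; fixed 4-class head."""

    def __init__(self, depth: int, base_channels: int, rng: np.random.Generator,
                 dtype=np.float32) -> None:
        self.depth = depth
        self.dtype = dtype
        ch = [base_channels * 2 ** l for l in range(depth + 1)]
        self.enc: list[list] = []
        self.pool = [nn.MaxPool2x2() for _ in range(depth)]
        c_prev = 1
        for l in range(depth):
            self.enc.append(self._block(c_prev, ch[l], rng, dtype))
            c_prev = ch[l]
        self.bottleneck = self._block(c_prev, ch[depth], rng, dtype)
        self.up = [nn.Upsample2x() for _ in range(depth)]
        self.dec: list[list] = []
        c_prev = ch[depth]
        for l in reversed(range(depth)):
            self.dec.append(self._block(c_prev + ch[l], ch[l], rng, dtype))
            c_prev = ch[l]
        self.head = nn.Conv1x1(c_prev, N_CLASSES, rng, dtype)

    @staticmethod
    def _block(c_in: int, c_out: int, rng, dtype) -> list:
        return [nn.Conv3x3(c_in, c_out, rng, dtype), nn.ReLU(),
                nn.Conv3x3(c_out, c_out, rng, dtype), nn.ReLU()]

    def _run_block(self, block, x, train):
        for layer in block:
            x = layer.forward(x, train=train)
        return x

    def _back_block(self, block, dy):
        for layer in reversed(block):
            dy = layer.backward(dy)
        return dy

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        skips = []
        for l in range(self.depth):
            x = self._run_block(self.enc[l], x, train)
            skips.append(x)
            x = self.pool[l].forward(x, train=train)
        x = self._run_block(self.bottleneck, x, train)
        self._skip_channels = [s.shape[-1] for s in skips]
        for i, l in enumerate(reversed(range(self.depth))):
            x = self.up[i].forward(x, train=train)
            x = np.concatenate([skips[l], x], axis=-1)
            x = self._run_block(self.dec[i], x, train)
        return self.head.forward(x, train=train)

    def backward(self, dlogits: np.ndarray) -> None:
        dy = self.head.backward(dlogits)
        dskips: list[np.ndarray | None] = [None] * self.depth
        for i in reversed(range(self.depth)):
            l = self.depth - 1 - i  # encoder level this decoder block attaches to
            dy = self._back_block(self.dec[i], dy)
            c_skip = self._skip_channels[l]
            dskips[l] = dy[..., :c_skip]
            dy = self.up[i].backward(dy[..., c_skip:])
        dy = self._back_block(self.bottleneck, dy)
        for l in reversed(range(self.depth)):
            dy = self.pool[l].backward(dy)
            dy = dy + dskips[l]
            dy = self._back_block(self.enc[l], dy)

    def params(self):
        out = []
        for block in self.enc + [self.bottleneck] + self.dec:
            for layer in block:
                out.extend(layer.params())
        out.extend(self.head.params())
        return out

    def state_arrays(self) -> dict[str, np.ndarray]:
        return {f"p{i}_{name}": getattr(layer, name)
                for i, (name, layer) in enumerate(self.params())}

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for i, (name, layer) in enumerate(self.params()):
            setattr(layer, name, np.asarray(arrays[f"p{i}_{name}"], dtype=self.dtype))


class UNetSegmenter:
    """A (possibly trained) U-Net with its input-size contract."""

    def __init__(self, config: TrainConfig, dtype=np.float32) -> None:
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.net = _UNet(config.depth, config.base_channels, rng, dtype)

    @property
    def input_shape(self) -> tuple[int, int]:
        """(height, width) the network expects."""
        w, h = self.config.target_size
        return (h, w)

    def logits(self, batch: np.ndarray, train: bool = False) -> np.ndarray:
        return self.net.forward(batch, train=train)

    def save(self, path: str | Path) -> None:
        arrays = self.net.state_arrays()
        np.savez(path, __config__=np.frombuffer(
            json.dumps(asdict(self.config)).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "UNetSegmenter":
        with np.load(path) as data:
            cfg_raw = bytes(data["__config__"].tobytes()).decode()
            cfg_dict = json.loads(cfg_raw)
            cfg_dict["target_size"] = tuple(cfg_dict["target_size"])
            seg = cls(TrainConfig(**cfg_dict))
            seg.net.load_state_arrays({k: data[k] for k in data.files if k != "__config__"})
        return seg


# ---------------------------------------------------------------------------
# data preparation, training, prediction
# ---------------------------------------------------------------------------

def resample_pair(image, mask, target_size: tuple[int, int]):
    """Resample an image/mask pair to (width, height): bilinear for the
    image, nearest-neighbour for the mask (labels preserved)."""
    px = as_pixels(image)
    lab = as_labels(mask) if mask is not None else None
    w, h = target_size
    if px.shape != (h, w):
        px = resize(px, (h, w), order=1, anti_aliasing=True, preserve_range=True)
        px = np.clip(px, 0.0, 1.0)
    if lab is not None and lab.shape != (h, w):
        lab = resize(lab, (h, w), order=0, anti_aliasing=False, preserve_range=True).astype(np.uint8)
    return px, lab


def _stack(dataset, target_size, dtype) -> tuple[np.ndarray, np.ndarray]:
    xs, ys = [], []
    for image, mask in dataset:
        px, lab = resample_pair(image, mask, target_size)
        check_same_shape(px, lab)
        xs.append(px.astype(dtype))
        ys.append(lab)
    return np.stack(xs)[..., None], np.stack(ys)


def _soft_dice_grad(probs: np.ndarray, onehot: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean soft-DICE loss over classes and its gradient w.r.t. probs."""
    eps = 1e-7
    axes = (0, 1, 2)  # channel axis is last
    inter = (probs * onehot).sum(axis=axes)
    sums = probs.sum(axis=axes) + onehot.sum(axis=axes)
    dice = (2 * inter + eps) / (sums + eps)
    loss = float(1.0 - dice.mean())
    # d(1 - dice_c)/d p_c = -(2 t (sums + eps) - (2 inter + eps)) / (sums + eps)^2
    g = -(2 * onehot * (sums + eps) - (2 * inter + eps)) / (sums + eps) ** 2
    return loss, g / probs.shape[-1]


def train_segmenter(
    train_set: Sequence, test_set: Sequence, config: TrainConfig | None = None,
    verbose: bool = False,
) -> tuple[UNetSegmenter, TrainingHistory]:
    """Train the U-Net on (image, mask) pairs and track held-out DICE.

    ``train_set`` / ``test_set`` are sequences of ``(IntensityImage | array,
    LabelMask | array)`` pairs (a :class:`~mdrquant.phantom.PhantomSet`'s
    ``items`` qualifies); everything is resampled to ``config.target_size``.
    Returns the segmenter and a :class:`TrainingHistory` with one record per
    epoch: training loss plus pooled test-set DICE per class and macro.
    ``epochs=0`` returns the untrained (randomly initialized) segmenter with
    an empty history. Fixed ``config.seed`` makes the run reproducible on a
    single device.
    """
    config = config or TrainConfig()
    config.validate()
    if len(train_set) == 0:
        raise DataError("empty training set")

    seg = UNetSegmenter(config)
    history = TrainingHistory()
    if config.epochs == 0:
        return seg, history

    dtype = seg.net.dtype
    x_tr, y_tr = _stack(train_set, config.target_size, dtype)
    x_te, y_te = (None, None)
    if len(test_set):
        x_te, y_te = _stack(test_set, config.target_size, dtype)

    n = x_tr.shape[0]
    onehot_eye = np.eye(N_CLASSES, dtype=dtype)
    rng = np.random.default_rng(config.seed + 1)
    opt = nn.Adam(seg.net.params(), lr=config.learning_rate)

    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb, yb = x_tr[idx], y_tr[idx]
            logits = seg.net.forward(xb, train=True)
            probs = nn.softmax(logits, axis=-1)
            onehot = onehot_eye[yb]
            n_pix = yb.size
            p_true = np.take_along_axis(probs, yb[..., None].astype(np.intp), axis=-1)
            ce = float(-np.log(np.maximum(p_true, 1e-12)).mean())
            dlogits = nn.softmax_xent_backward(probs, onehot, n_pix)
            loss = ce
            if config.loss == "cross-entropy+dice":
                dloss, gprobs = _soft_dice_grad(probs, onehot)
                loss = ce + config.dice_loss_weight * dloss
                # chain soft-dice gradient through the softmax
                g = config.dice_loss_weight * gprobs
                dlogits = dlogits + probs * (g - (g * probs).sum(axis=-1, keepdims=True))
            seg.net.backward(dlogits.astype(dtype))
            opt.step()
            losses.append(loss)

        rec = {"epoch": epoch, "loss": float(np.mean(losses))}
        if x_te is not None:
            preds = _predict_stack(seg, x_te)
            pooled = _pooled_dice(preds, y_te)
            rec.update(
                macro_dice=float(np.mean(list(pooled.values()))),
                **{f"dice_{LABEL_NAMES[c]}": pooled[c] for c in TISSUE_LABELS},
            )
        else:
            rec.update(macro_dice=float("nan"))
        history.append(**rec)
        if verbose:
            print(f"epoch {epoch:3d}  loss {rec['loss']:.4f}  macro_dice "
                  f"{rec.get('macro_dice', float('nan')):.4f}")
    return seg, history


def _predict_stack(seg: UNetSegmenter, x: np.ndarray, batch: int = 8) -> np.ndarray:
    outs = []
    for start in range(0, x.shape[0], batch):
        logits = seg.logits(x[start:start + batch], train=False)
        outs.append(np.argmax(logits, axis=-1).astype(np.uint8))
    return np.concatenate(outs)


def predict_mask(segmenter: UNetSegmenter, image) -> LabelMask:
    """Segment one image (already at the model's input size) into a 4-class
    label mask via per-pixel argmax; deterministic in inference mode."""
    px = as_pixels(image)
    if px.shape != segmenter.input_shape:
        raise ShapeError(
            f"image shape {px.shape} does not match model input {segmenter.input_shape}; "
            "resample first (see resample_pair)"
        )
    logits = segmenter.logits(px.astype(segmenter.net.dtype)[None, ..., None], train=False)
    return LabelMask(np.argmax(logits[0], axis=-1).astype(np.uint8))
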