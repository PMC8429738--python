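"""Learned 3-class segmentation of head and reference coin.

The model is a U-Net-style fully convolutional encoder-decoder: four
encoder levels of pre-activation residual blocks (ResNet-style 3x3 conv
pairs with identity skips), 2x2 max-pool downsampling, nearest-neighbour
upsampling, and concatenation of each encoder output with the matching
decoder level.  A 1x1 convolution and channel softmax produce per-pixel
probabilities for {background, head, coin}.

Training minimizes ``lambda * dice + (1 - lambda) * focal``:

* class-weighted soft dice, ``1 - sum_c w_c (2 sum p_c t_c + eps) /
  (sum p_c + sum t_c + eps)``, with weights emphasizing the head and coin
  classes over the dominant background;
* categorical focal loss, ``mean( -(1 - p_true)^gamma log p_true )``,
  which down-weights easy pixels (gamma = 0 recovers cross-entropy).

Optimization is Adam.  Everything runs on the CPU via the package's own
numpy autodiff (:mod:`craniometry._nn`) and is deterministic per seed.
An encoder pretrained elsewhere can be loaded from a checkpoint file;
nothing is ever downloaded.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from skimage import measure as skmeasure

from . import _nn
from ._nn import Tensor
from .morphometry import BACKGROUND, COIN, HEAD
from .preprocess import Sample

N_CLASSES = 3


class SegmentationError(RuntimeError):
    pass


@dataclass
class TrainConfig:
    epochs: int = 15
    batch_size: int = 4
    learning_rate: float = 3e-3
    class_weights: tuple[float, float, float] = (0.2, 1.0, 1.0)
    focal_gamma: float = 2.0
    loss_mix: float = 0.5          # lambda: dice weight; 1-lambda goes to focal
    seed: int = 0
    pretrained_encoder: Optional[str] = None  # checkpoint path, never a URL
    lr_milestones: tuple[int, ...] = ()       # epochs at which lr *= lr_decay
    lr_decay: float = 0.3

    def __post_init__(self) -> None:
        if not 0.0 <= self.loss_mix <= 1.0:
            raise ValueError("loss_mix must lie in [0, 1]")
        if any(w <= 0 for w in self.class_weights):
            raise ValueError("class weights must be positive")

    def content_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# losses (public numpy forms; autodiff twins used during training)
# ---------------------------------------------------------------------------

def one_hot(mask: np.ndarray, n_classes: int = N_CLASSES) -> np.ndarray:
    """(H, W) labels -> (H, W, C) one-hot float array."""
    return np.eye(n_classes, dtype=np.float32)[mask]


def dice_loss(
    pred: np.ndarray,
    truth: np.ndarray,
    class_weights: Sequence[float] = (0.2, 1.0, 1.0),
    eps: float = 1e-6,
) -> float:
    """Class-weighted soft dice loss on (..., C) probability/one-hot arrays.

    Weights are normalized to sum to one, so scaling them all by the same
    factor leaves the loss unchanged.  Zero iff prediction equals the
    one-hot truth (up to eps).
    """
    w = np.asarray(class_weights, dtype=float)
    if (w <= 0).any():
        raise ValueError("class weights must be positive")
    w = w / w.sum()
    p = np.asarray(pred, dtype=float).reshape(-1, len(w))
    t = np.asarray(truth, dtype=float).reshape(-1, len(w))
    inter = (p * t).sum(axis=0)
    dice = (2.0 * inter + eps) / (p.sum(axis=0) + t.sum(axis=0) + eps)
    return float(1.0 - (w * dice).sum())


def focal_loss(
    pred: np.ndarray,
    truth: np.ndarray,
    gamma: float = 2.0,
    clip: float = 1e-7,
) -> float:
    """Categorical focal loss, mean over pixels of -(1-p_t)^gamma log p_t."""
    if gamma < 0:
        raise ValueError("gamma must be non-negative")
    p = np.asarray(pred, dtype=float).reshape(-1, N_CLASSES)
    t = np.asarray(truth, dtype=float).reshape(-1, N_CLASSES)
    p_true = np.clip((p * t).sum(axis=1), clip, 1.0)
    return float(np.mean(-np.power(1.0 - p_true, gamma) * np.log(p_true)))


def _dice_loss_t(p: Tensor, t: np.ndarray, class_weights, eps: float = 1e-6) -> Tensor:
    """Autodiff dice on (N, C, H, W) probabilities against one-hot labels."""
    w = np.asarray(class_weights, dtype=np.float32)
    w = w / w.sum()
    tt = Tensor(t)
    inter = (p * tt).sum(axis=(0, 2, 3))
    denom = p.sum(axis=(0, 2, 3)) + Tensor(t.sum(axis=(0, 2, 3)))
    dice = (inter * 2.0 + eps) * (denom + eps).power(-1.0)
    return 1.0 - (dice * Tensor(w)).sum()


def _focal_loss_t(p: Tensor, t: np.ndarray, gamma: float, clip: float = 1e-7) -> Tensor:
    p_true = (p * Tensor(t)).sum(axis=1).clip_min(clip)
    mod = (1.0 - p_true).power(gamma) if gamma > 0 else 1.0
    return (mod * -1.0 * p_true.log()).mean()


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

class Segmenter(_nn.Module):
    """Encoder-decoder with residual blocks and skip concatenations."""

    def __init__(self, depth: int = 4, base_channels: int = 8,
                 in_channels: int = 3, seed: int = 0):
        rng = np.random.default_rng(seed)
        chans = [min(base_channels * 2**i, base_channels * 8) for i in range(depth + 1)]
        self.depth = depth
        self.base_channels = base_channels
        self.in_channels = in_channels
        self.stem = _nn.Conv2d(in_channels, chans[0], 3, rng)
        self.enc_blocks = [_nn.ResidualBlock(chans[i], chans[i], rng) for i in range(depth)]
        self.down_blocks = [
            _nn.ResidualBlock(chans[i], chans[i + 1], rng) for i in range(depth)
        ]
        self.bottleneck = _nn.ResidualBlock(chans[depth], chans[depth], rng)
        self.dec_blocks = [
            _nn.ResidualBlock(chans[i + 1] + chans[i], chans[i], rng)
            for i in reversed(range(depth))
        ]
        self.head_norm = _nn.GroupNorm(chans[0])
        self.head_conv = _nn.Conv2d(chans[0], N_CLASSES, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        """Logits (N, 3, H, W); H and W must be divisible by 2**depth."""
        _, _, h, w = x.shape
        if h % 2**self.depth or w % 2**self.depth:
            raise SegmentationError(
                f"input {h}x{w} not divisible by {2**self.depth}"
            )
        y = self.stem(x)
        skips = []
        for enc, down in zip(self.enc_blocks, self.down_blocks):
            y = enc(y)
            skips.append(y)
            y = down(_nn.maxpool2(y))
        y = self.bottleneck(y)
        for dec, skip in zip(self.dec_blocks, reversed(skips)):
            y = _nn.concat_channels(_nn.upsample2(y), skip)
            y = dec(y)
        return self.head_conv(self.head_norm(y).relu())

    def predict_probs(self, images: np.ndarray) -> np.ndarray:
        """(N, H, W, 3) images in [0, 1] -> (N, H, W, 3) class probabilities."""
        x = Tensor(images.astype(np.float32).transpose(0, 3, 1, 2) - 0.5)
        p = _nn.softmax_channels(self.forward(x))
        return p.data.transpose(0, 2, 3, 1)


def build_segmenter(
    depth: int = 4,
    base_channels: int = 8,
    input_hw: tuple[int, int] = (96, 128),
    seed: int = 0,
    pretrained_weights: Optional[str | Path] = None,
) -> Segmenter:
    """Construct the model and check the input geometry contract.

    ``input_hw`` must be divisible by ``2**depth`` (e.g. 736 x 960 at depth
    4 gives a 46 x 60 bottleneck).  ``pretrained_weights`` optionally loads
    a locally supplied checkpoint; by default the network is randomly
    initialized — no download is ever attempted.
    """
    h, w = input_hw
    if h % 2**depth or w % 2**depth:
        raise SegmentationError(f"input dims {h}x{w} not divisible by {2**depth}")
    model = Segmenter(depth=depth, base_channels=base_channels, seed=seed)
    if pretrained_weights is not None:
        with np.load(pretrained_weights) as npz:
            model.load_state_arrays([npz[k] for k in npz.files])
    return model


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _batch_arrays(samples: Sequence[Sample]) -> tuple[np.ndarray, np.ndarray]:
    imgs = np.stack([s.image for s in samples]).astype(np.float32)
    masks = np.stack([s.mask for s in samples])
    onehot = np.eye(N_CLASSES, dtype=np.float32)[masks]  # N,H,W,C
    return imgs.transpose(0, 3, 1, 2) - 0.5, onehot.transpose(0, 3, 1, 2)


def _evaluate(model: Segmenter, samples: Sequence[Sample],
              config: TrainConfig) -> dict[str, float]:
    from .evaluation import overlap_scores

    accs, ious, f1s, losses = [], [], [], []
    for s in samples:
        probs = model.predict_probs(s.image[None])[0]
        pred = probs.argmax(axis=-1)
        truth = one_hot(s.mask)
        losses.append(
            config.loss_mix * dice_loss(probs, truth, config.class_weights)
            + (1 - config.loss_mix) * focal_loss(probs, truth, config.focal_gamma)
        )
        accs.append(float((pred == s.mask).mean()))
        iou_h, f1_h = overlap_scores(pred, s.mask, HEAD)
        iou_c, f1_c = overlap_scores(pred, s.mask, COIN)
        ious.append((iou_h + iou_c) / 2.0)
        f1s.append((f1_h + f1_c) / 2.0)
    return {
        "val_loss": float(np.mean(losses)),
        "val_accuracy": float(np.mean(accs)),
        "val_iou": float(np.mean(ious)),
        "val_f1": float(np.mean(f1s)),
    }


def train_segmenter(
    model: Segmenter,
    train_set: Sequence[Sample],
    val_set: Sequence[Sample],
    config: TrainConfig,
    log_path: Optional[str | Path] = None,
) -> tuple[Segmenter, list[dict[str, float]]]:
    """Adam training with per-epoch validation metrics.

    History records loss, pixel accuracy, mean head/coin IoU and F1 on the
    validation set after every epoch; the best-F1 epoch's weights are
    restored at the end.  Fully seeded: identical config and seed give an
    identical history on CPU.
    """
    if not train_set or not val_set:
        raise ValueError("train and validation sets must be nonempty")
    rng = np.random.default_rng(config.seed)
    opt = _nn.Adam(model.parameters(), lr=config.learning_rate)
    history: list[dict[str, float]] = []
    best_f1, best_state = -1.0, None
    for epoch in range(1, config.epochs + 1):
        if epoch in config.lr_milestones:
            opt.lr *= config.lr_decay
        order = rng.permutation(len(train_set))
        epoch_losses = []
        for start in range(0, len(order), config.batch_size):
            batch = [train_set[i] for i in order[start:start + config.batch_size]]
            x, t = _batch_arrays(batch)
            opt.zero_grad()
            p = _nn.softmax_channels(model.forward(Tensor(x, requires_grad=False)))
            loss = (
                _dice_loss_t(p, t, config.class_weights) * config.loss_mix
                + _focal_loss_t(p, t, config.focal_gamma) * (1.0 - config.loss_mix)
            )
            value = float(loss.data)
            if not math.isfinite(value):
                raise SegmentationError(
                    f"non-finite loss at epoch {epoch} (lr={config.learning_rate}); "
                    "reduce the learning rate or check the inputs"
                )
            loss.backward()
            opt.step()
            epoch_losses.append(value)
        record = {"epoch": epoch, "train_loss": float(np.mean(epoch_losses))}
        record.update(_evaluate(model, val_set, config))
        history.append(record)
        if record["val_f1"] > best_f1:
            best_f1 = record["val_f1"]
            best_state = [a.copy() for a in model.state_arrays()]
        if log_path is not None:
            _append_log(log_path, record)
    if best_state is not None:
        model.load_state_arrays(best_state)
    return model, history


def _append_log(path: str | Path, record: dict) -> None:
    path = Path(path)
    header = not path.exists()
    keys = ["epoch", "train_loss", "val_loss", "val_accuracy", "val_iou", "val_f1"]
    with path.open("a") as fh:
        if header:
            fh.write(",".join(keys) + "\n")
        fh.write(",".join(f"{record[k]}" for k in keys) + "\n")


# ---------------------------------------------------------------------------
# prediction post-processing
# ---------------------------------------------------------------------------

@dataclass
class Prediction:
    probability: np.ndarray      # H x W x 3, rows sum to 1
    mask: np.ndarray             # H x W uint8 after post-processing
    flags: list[str] = field(default_factory=list)


def _keep_largest(mask: np.ndarray, cls: int) -> np.ndarray:
    labels = skmeasure.label(mask == cls, connectivity=2)
    n = labels.max()
    if n <= 1:
        return mask
    sizes = np.bincount(labels.ravel())[1:]
    keep = 1 + int(np.argmax(sizes))
    out = mask.copy()
    out[(labels > 0) & (labels != keep)] = BACKGROUND
    return out


def predict_mask(model: Segmenter, image: np.ndarray) -> Prediction:
    """Segment one standardized image and tidy the label mask.

    Per-pixel argmax, then only the largest connected component is kept for
    the head and for the coin (stray fragments are returned to background —
    the typical failure is background clutter attached to the head).  A coin
    component that does not intersect the head's bounding box is flagged as
    suspect rather than silently accepted.
    """
    img = np.asarray(image)
    if img.dtype == np.uint8:
        img = img.astype(np.float32) / 255.0
    probs = model.predict_probs(img[None].astype(np.float32))[0]
    mask = probs.argmax(axis=-1).astype(np.uint8)
    for cls, name in ((HEAD, "head"), (COIN, "coin")):
        if not (mask == cls).any():
            raise SegmentationError(f"no {name} pixels predicted")
        mask = _keep_largest(mask, cls)
    flags = []
    rows, cols = np.nonzero(mask == HEAD)
    r0, r1, c0, c1 = rows.min(), rows.max(), cols.min(), cols.max()
    crow, ccol = np.nonzero(mask == COIN)
    if not ((crow >= r0) & (crow <= r1) & (ccol >= c0) & (ccol <= c1)).any():
        flags.append("coin_outside_head_bbox")
    return Prediction(probability=probs, mask=mask, flags=flags)


def soft_head_field(pred: Prediction, dilate: int = 2) -> np.ndarray:
    """Soft head-support field (head + coin probability) for subpixel contours.

    The probability plane is zeroed outside a small dilation of the cleaned
    head region, so stray responses elsewhere cannot re-introduce the
    components that post-processing removed.  Contouring this field at 0.5
    interpolates the boundary between pixels, which is substantially more
    accurate than the hard mask at coarse (desk-scale) resolution.
    """
    from scipy import ndimage as ndi

    support = pred.mask != BACKGROUND
    keep = ndi.binary_dilation(support, iterations=dilate)
    field = pred.probability[..., HEAD] + pred.probability[..., COIN]
    # argmax can win a pixel with probability < 0.5 (three-way splits);
    # floor the field inside the kept region so its 0.5 superlevel covers
    # the cleaned mask
    field = np.where(support, np.maximum(field, 0.501), field)
    field = np.where(keep, field, 0.0)
    # drop any superlevel blob not connected to the head itself (removed
    # clutter fragments adjacent to the head can survive the dilation ring)
    labels, _ = ndi.label(field >= 0.5, structure=np.ones((3, 3)))
    head_labels = np.unique(labels[support & (labels > 0)])
    connected = np.isin(labels, head_labels)
    return np.where(connected | (field < 0.5), field, 0.0).astype(float)


def soft_coin_area(pred: Prediction, dilate: int = 2) -> float:
    """Probability-weighted coin area in px^2 (expected pixel coverage).

    Summing the coin-class probability over the kept coin component (plus a
    small dilation) estimates the disc area with sub-pixel resolution, which
    matters because the coin spans only ~12 px at desk scale and calibration
    error propagates into every metric output.
    """
    from scipy import ndimage as ndi

    support = pred.mask == COIN
    keep = ndi.binary_dilation(support, iterations=dilate)
    return float(pred.probability[..., COIN][keep].sum())


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: Segmenter, path: str | Path,
                    config: Optional[TrainConfig] = None,
                    metrics: Optional[dict] = None) -> None:
    path = Path(path)
    arrays = {f"arr_{i:04d}": a for i, a in enumerate(model.state_arrays())}
    np.savez(path, **arrays)
    sidecar = {
        "depth": model.depth,
        "base_channels": model.base_channels,
        "in_channels": model.in_channels,
        "config_hash": config.content_hash() if config else None,
        "metrics": metrics or {},
    }
    real = path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")
    real.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_checkpoint(path: str | Path) -> tuple[Segmenter, dict]:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(path.suffix + ".npz")
    meta = json.loads(path.with_suffix(".json").read_text())
    model = Segmenter(depth=meta["depth"], base_channels=meta["base_channels"],
                      in_channels=meta["in_channels"])
    with np.load(path) as npz:
        model.load_state_arrays([npz[k] for k in sorted(npz.files)])
    return model, meta
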