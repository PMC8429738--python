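"""Input standardization and data augmentation for image-mask pairs.

Standardization reproduces the capture-to-network geometry: each dimension
is downscaled by a fixed factor (default 3.4, taking a typical 2448 x 3264
smartphone frame to 720 x 960) and zero-padded up to the next multiple of
32, the granularity required by a four-level encoder-decoder (2448 x 3264
thus becomes 736 x 960).

Augmentation follows a declarative schedule of (operation, parameters,
likelihood) entries applied independently per sample: horizontal flip
(p = 0.5), rotation uniform in [-90 deg, +90 deg] (p = 1.0), additive
Gaussian noise with std drawn from {0.01, 0.05} (p = 0.2), one of
{CLAHE, brightness, gamma, contrast} (p = 0.9), and HSV shifts of up to
(20, 30, 20) 8-bit units (p = 0.9).  Geometric operations are applied
identically to image and mask (mask warped nearest-neighbour so labels are
preserved); photometric operations never touch the mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml
from skimage import color as skcolor
from skimage import exposure as skexposure
from skimage import transform as sktransform

from .phantom import Phantom


@dataclass(frozen=True)
class StandardizationInfo:
    """Geometry bookkeeping so metric calibration can be propagated."""

    row_scale: float
    col_scale: float
    pad: tuple[int, int, int, int]  # top, bottom, left, right

    @property
    def scale(self) -> float:
        return (self.row_scale + self.col_scale) / 2.0


def _target_dims(h: int, w: int, factor: float) -> tuple[int, int]:
    return max(1, int(h / factor)), max(1, int(w / factor))


def standardize_input(
    image: np.ndarray, factor: float = 3.4, multiple: int = 32
) -> tuple[np.ndarray, StandardizationInfo]:
    """Downscale by ``factor`` (floor) and zero-pad to a multiple of ``multiple``.

    Padding is split evenly, with the odd pixel on the bottom/right.  Works
    for RGB images (bilinear) — use :func:`standardize_mask` for label masks.
    """
    if image.size == 0:
        raise ValueError("empty image")
    if factor < 1:
        raise ValueError("factor must be >= 1")
    h, w = image.shape[:2]
    nh, nw = _target_dims(h, w, factor)
    if nh < multiple or nw < multiple:
        warnings.warn(
            f"image {h}x{w} is smaller than {multiple} px after downscaling; "
            "padding only",
            stacklevel=2,
        )
    out = image
    if (nh, nw) != (h, w):
        out = sktransform.resize(
            image.astype(float), (nh, nw), order=1, anti_aliasing=True,
            preserve_range=True,
        )
        if np.issubdtype(image.dtype, np.integer):
            out = np.clip(np.round(out), 0, 255).astype(image.dtype)
    ph = (-nh) % multiple
    pw = (-nw) % multiple
    pad = (ph // 2, ph - ph // 2, pw // 2, pw - pw // 2)
    widths = [(pad[0], pad[1]), (pad[2], pad[3])] + [(0, 0)] * (out.ndim - 2)
    out = np.pad(out, widths)
    return out, StandardizationInfo(nh / h, nw / w, pad)


def standardize_mask(
    mask: np.ndarray, factor: float = 3.4, multiple: int = 32
) -> tuple[np.ndarray, StandardizationInfo]:
    """Label-mask variant: nearest-neighbour resampling, classes preserved."""
    if mask.size == 0:
        raise ValueError("empty mask")
    h, w = mask.shape[:2]
    nh, nw = _target_dims(h, w, factor)
    out = mask
    if (nh, nw) != (h, w):
        out = sktransform.resize(
            mask, (nh, nw), order=0, anti_aliasing=False, preserve_range=True
        ).astype(mask.dtype)
    ph = (-nh) % multiple
    pw = (-nw) % multiple
    pad = (ph // 2, ph - ph // 2, pw // 2, pw - pw // 2)
    out = np.pad(out, [(pad[0], pad[1]), (pad[2], pad[3])])
    return out, StandardizationInfo(nh / h, nw / w, pad)


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AugmentationOp:
    name: str
    params: dict
    likelihood: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.likelihood <= 1.0:
            raise ValueError("likelihood must lie in [0, 1]")


@dataclass
class AugmentationSpec:
    """Ordered augmentation schedule, serializable to/from YAML."""

    ops: list[AugmentationOp] = field(default_factory=list)

    @classmethod
    def from_yaml(cls, source: str | Path) -> "AugmentationSpec":
        text = str(source)
        if "\n" not in text and Path(text).exists():
            text = Path(text).read_text()
        raw = yaml.safe_load(text)
        ops = [
            AugmentationOp(o["name"], o.get("params", {}), float(o["likelihood"]))
            for o in raw["operations"]
        ]
        return cls(ops)

    def to_yaml(self, path: Optional[str | Path] = None) -> str:
        payload = {
            "operations": [
                {"name": o.name, "params": o.params, "likelihood": o.likelihood}
                for o in self.ops
            ]
        }
        text = yaml.safe_dump(payload, sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def default(cls) -> "AugmentationSpec":
        """The schedule bundled with the package (data/augmentation.yaml)."""
        text = (
            resources.files("craniometry").joinpath("data/augmentation.yaml").read_text()
        )
        return cls.from_yaml(text)


_GEOMETRIC = {"horizontal_flip", "rotate"}


def _apply_photometric(image: np.ndarray, choice: str, params: dict,
                       rng: np.random.Generator) -> np.ndarray:
    if choice == "clahe":
        kernel = params.get("kernel", [8, 8])
        ks = (max(1, image.shape[0] // kernel[0]), max(1, image.shape[1] // kernel[1]))
        return skexposure.equalize_adapthist(
            np.clip(image, 0, 1), kernel_size=ks,
            clip_limit=params.get("clip_limit", 0.04),
        )
    if choice == "brightness":
        lo, hi = params.get("limit", [-0.2, 0.2])
        return image + rng.uniform(lo, hi)
    if choice == "gamma":
        lo, hi = params.get("range", [0.8, 1.2])
        return np.power(np.clip(image, 0, 1), rng.uniform(lo, hi))
    if choice == "contrast":
        lo, hi = params.get("range", [0.8, 1.2])
        return (image - 0.5) * rng.uniform(lo, hi) + 0.5
    raise ValueError(f"unknown photometric choice '{choice}'")


def augment_sample(
    image: np.ndarray,
    mask: np.ndarray,
    spec: AugmentationSpec,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply the schedule to one image-mask pair.

    The image is handled in float [0, 1]; the mask keeps its integer labels.
    Rotation is counterclockwise in the displayed image (a feature in the
    left half of the frame moves to the bottom half under +90 deg).
    """
    if image.shape[:2] != mask.shape:
        raise ValueError("image and mask are not congruent")
    supported = sorted(_GEOMETRIC | {"gaussian_noise", "photometric_oneof", "hsv_shift"})
    rng = np.random.default_rng(seed)
    img = image.astype(float)
    if img.max() > 1.5:
        img = img / 255.0
    out_mask = mask.copy()
    for op in spec.ops:
        if op.name not in supported:
            raise ValueError(
                f"unknown augmentation '{op.name}'; supported: {supported}"
            )
        if rng.random() >= op.likelihood:
            continue
        if op.name == "horizontal_flip":
            img = img[:, ::-1].copy()
            out_mask = out_mask[:, ::-1].copy()
        elif op.name == "rotate":
            lo, hi = op.params.get("limit_deg", [-90.0, 90.0])
            angle = rng.uniform(lo, hi)
            img = sktransform.rotate(img, angle, order=1, mode="constant", cval=0.0)
            out_mask = sktransform.rotate(
                out_mask.astype(float), angle, order=0, mode="constant", cval=0.0
            ).astype(mask.dtype)
        elif op.name == "gaussian_noise":
            std = rng.choice(np.asarray(op.params.get("std_choices", [0.01, 0.05])))
            img = img + rng.normal(op.params.get("mean", 0.0), std, img.shape)
        elif op.name == "photometric_oneof":
            choices = op.params.get(
                "choices", ["clahe", "brightness", "gamma", "contrast"]
            )
            choice = choices[int(rng.integers(len(choices)))]
            img = _apply_photometric(img, choice, op.params.get(choice, {}), rng)
        elif op.name == "hsv_shift":
            hsv = skcolor.rgb2hsv(np.clip(img, 0, 1))
            # limits follow the 8-bit convention: H in [0,180), S/V in [0,256)
            h_lim = op.params.get("h_limit", 20) / 180.0
            s_lim = op.params.get("s_limit", 30) / 255.0
            v_lim = op.params.get("v_limit", 20) / 255.0
            hsv[..., 0] = (hsv[..., 0] + rng.uniform(-h_lim, h_lim)) % 1.0
            hsv[..., 1] = np.clip(hsv[..., 1] + rng.uniform(-s_lim, s_lim), 0, 1)
            hsv[..., 2] = np.clip(hsv[..., 2] + rng.uniform(-v_lim, v_lim), 0, 1)
            img = skcolor.hsv2rgb(hsv)
    return np.clip(img, 0.0, 1.0), out_mask


# ---------------------------------------------------------------------------
# training-set assembly
# ---------------------------------------------------------------------------

@dataclass
class Sample:
    image: np.ndarray   # H x W x 3 float32 in [0, 1]
    mask: np.ndarray    # H x W uint8
    phantom_index: int
    augmented: bool = False


def build_training_set(
    phantoms: Sequence[Phantom],
    spec: AugmentationSpec,
    copies: int = 2,
    split_ratio: tuple[int, int] = (2, 1),
    seed: int = 0,
    standardize_factor: float = 1.0,
) -> tuple[list[Sample], list[Sample]]:
    """Split phantoms train/validation and augment only the training side.

    The split is by phantom (no leakage).  Each training phantom contributes
    its standardized original plus ``copies`` augmented variants, so n train
    phantoms yield ``n * (copies + 1)`` samples; validation phantoms are
    standardized only.
    """
    if len(phantoms) < 3:
        raise ValueError("need at least 3 phantoms to split")
    a, b = split_ratio
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(phantoms))
    n_train = int(round(len(phantoms) * a / (a + b)))
    if n_train == 0 or n_train == len(phantoms):
        raise ValueError(f"split ratio {a}:{b} leaves one side empty")
    train_idx, val_idx = order[:n_train], order[n_train:]

    def _std(phantom: Phantom) -> tuple[np.ndarray, np.ndarray]:
        img, _ = standardize_input(phantom.image, factor=standardize_factor)
        msk, _ = standardize_mask(phantom.mask, factor=standardize_factor)
        return img.astype(np.float32) / 255.0, msk

    train: list[Sample] = []
    for i in train_idx:
        img, msk = _std(phantoms[i])
        train.append(Sample(img, msk, int(i)))
        for c in range(copies):
            aug_seed = int(rng.integers(2**31 - 1))
            aimg, amsk = augment_sample(img, msk, spec, aug_seed)
            train.append(Sample(aimg.astype(np.float32), amsk, int(i), augmented=True))
    val = []
    for i in val_idx:
        img, msk = _std(phantoms[i])
        val.append(Sample(img, msk, int(i)))
    return train, val
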