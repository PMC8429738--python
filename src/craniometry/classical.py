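"""Classical (non-learned) segmentation: Hough-circle coin detection and
threshold-based head extraction.

This is the fallback engine: blur, local thresholding, erosion to remove
outlier pixels, then a circular Hough transform over the candidate radius
range locates the reference coin; the head is the largest foreground
component containing the coin after global thresholding and morphological
cleanup.  It needs no training but is brittle against cluttered
backgrounds, which is what motivates the learned engine.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import color as skcolor
from skimage import filters as skfilters
from skimage import measure as skmeasure
from skimage import morphology as skmorph
from skimage import transform as sktransform

from .morphometry import BACKGROUND, COIN, HEAD


class ClassicalError(RuntimeError):
    pass


@dataclass(frozen=True)
class DetectedCircle:
    """A coin candidate from the Hough accumulator."""

    center: tuple[float, float]   # (row, col), subpixel
    radius: float                 # px
    score: float                  # normalized accumulator vote in [0, 1]

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ClassicalError("radius must be positive")


def _to_gray(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image)
    if img.ndim == 3:
        img = skcolor.rgb2gray(img)
    img = img.astype(float)
    if img.max() > 1.5:
        img = img / 255.0
    return img


def detect_coin_hct(
    image: np.ndarray,
    radius_range: tuple[int, int],
    blur_sigma: float = 1.0,
    threshold_block: int = 35,
    erosion_radius: int = 1,
    min_score: float = 0.3,
) -> DetectedCircle:
    """Locate the brightest disc in ``radius_range`` via the circular Hough
    transform.

    Pipeline: Gaussian blur -> local (adaptive) threshold -> binary erosion
    to delete outlier pixels -> edge map -> (center, radius) accumulator ->
    best-vote circle.  Raises :class:`ClassicalError` when no accumulator
    peak reaches ``min_score`` (no coin found).
    """
    gray = _to_gray(image)
    rmin, rmax = radius_range
    if rmin <= 0 or rmax <= rmin:
        raise ClassicalError("invalid radius range")
    if 2 * rmax > min(gray.shape):
        raise ClassicalError("radius range exceeds image dimensions")
    blurred = skfilters.gaussian(gray, sigma=blur_sigma)
    block = threshold_block if threshold_block % 2 else threshold_block + 1
    local = blurred > skfilters.threshold_local(blurred, block_size=block, offset=-0.02)
    # opening: erosion deletes outlier speckles, dilation restores the boundary
    opened = skmorph.dilation(
        skmorph.erosion(local, skmorph.disk(erosion_radius)),
        skmorph.disk(erosion_radius),
    )
    edges = opened ^ skmorph.erosion(opened, skmorph.disk(1))
    radii = np.arange(rmin, rmax + 1)
    accum = sktransform.hough_circle(edges, radii)
    scores, cols, rows, found = sktransform.hough_circle_peaks(
        accum, radii, total_num_peaks=1, normalize=False
    )
    if len(scores) == 0 or float(scores[0]) < min_score:
        best = float(scores[0]) if len(scores) else 0.0
        raise ClassicalError(f"no coin found: best accumulator vote {best:.3f} < {min_score}")
    center = (float(rows[0]), float(cols[0]))
    radius = float(found[0])
    refined = _refine_circle(gray, center, radius)
    if refined is not None:
        center, radius = refined
    return DetectedCircle(center=center, radius=radius, score=float(min(scores[0], 1.0)))


def _refine_circle(gray: np.ndarray, center: tuple[float, float],
                   radius: float) -> tuple[tuple[float, float], float] | None:
    """Subpixel refinement of the Hough circle.

    The accumulator radius is integer-quantized and biased ~1 px inward by
    the edge extraction.  Within a box around the detected centre, an Otsu
    split isolates the bright disc; its centroid and equivalent-area radius
    replace the quantized estimates when plausible.
    """
    h, w = gray.shape
    half = int(round(1.5 * radius))
    r0, r1 = max(0, int(center[0]) - half), min(h, int(center[0]) + half + 1)
    c0, c1 = max(0, int(center[1]) - half), min(w, int(center[1]) + half + 1)
    roi = gray[r0:r1, c0:c1]
    if roi.size < 16 or float(roi.max() - roi.min()) < 1e-6:
        return None
    bright = roi > skfilters.threshold_otsu(roi)
    labels = skmeasure.label(bright, connectivity=2)
    rr, cc = int(center[0]) - r0, int(center[1]) - c0
    lab = labels[min(max(rr, 0), labels.shape[0] - 1), min(max(cc, 0), labels.shape[1] - 1)]
    if lab == 0:
        return None
    blob = labels == lab
    area = float(blob.sum())
    r_eq = float(np.sqrt(area / np.pi))
    if not (0.6 * radius <= r_eq <= 1.6 * radius):
        return None
    rows_b, cols_b = np.nonzero(blob)
    return (float(rows_b.mean()) + r0, float(cols_b.mean()) + c0), r_eq


def segment_head_classical(
    image: np.ndarray,
    coin: DetectedCircle,
    closing_radius: int = 2,
    min_head_px: int = 64,
) -> np.ndarray:
    """Threshold-based head mask, anchored on the detected coin.

    Otsu foreground/background split, morphological closing and hole
    filling, then the connected component containing the coin centre
    becomes the head (class 1); the coin disc is relabelled class 2.  The
    output mask is interchangeable with the learned engine's.
    """
    gray = _to_gray(image)
    thresh = skfilters.threshold_otsu(gray)
    fg = gray > thresh
    fg = skmorph.closing(fg, skmorph.disk(closing_radius))
    fg = ndi.binary_fill_holes(fg)
    labels = skmeasure.label(fg, connectivity=2)
    r, c = int(round(coin.center[0])), int(round(coin.center[1]))
    if not (0 <= r < labels.shape[0] and 0 <= c < labels.shape[1]):
        raise ClassicalError("coin centre lies outside the image")
    lab = labels[r, c]
    if lab == 0:
        raise ClassicalError("no foreground component contains the coin centre")
    head = labels == lab
    if int(head.sum()) < min_head_px:
        raise ClassicalError("component containing the coin is too small to be a head")
    mask = np.full(gray.shape, BACKGROUND, dtype=np.uint8)
    mask[head] = HEAD
    rr, cc = np.ogrid[: gray.shape[0], : gray.shape[1]]
    disc = (rr - coin.center[0]) ** 2 + (cc - coin.center[1]) ** 2 <= coin.radius**2
    mask[disc & head] = COIN
    return mask
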