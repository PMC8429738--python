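"""Metric cranial morphometry from segmentation masks.

The measurement chain is: extract a subpixel head contour from the mask
(or from a soft class-probability field), calibrate millimetres-per-pixel
from the reference-coin component, then read five clinical parameters off
the contour geometry:

* ``length`` — caliper extent along the principal (anteroposterior) axis,
* ``width`` — caliper extent perpendicular to it,
* ``perimeter`` — contour arc length,
* ``diag_a`` / ``diag_b`` — transcranial diagonals: chords through the
  area centroid at +40 deg / -40 deg from the principal axis,

plus the two derived indices

* cranial index ``CI = 100 * width / length`` and
* cranial vault asymmetry index
  ``CVAI = 100 * |diag_a - diag_b| / max(diag_a, diag_b)``.

Conventions: contours are ``(N, 2)`` float arrays of ``(x, y)`` vertices
with the first vertex repeated at the end (explicitly closed).  For
image-derived contours ``x`` is the column and ``y`` the row coordinate,
origin at the top-left pixel centre.  Angles are degrees counterclockwise
from the +x axis in ``(x, y)`` coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from skimage import measure as skmeasure

#: Diameter of the 50-Eurocent reference coin (official specification), mm.
COIN_DIAMETER_MM = 24.25

#: Offset of the transcranial diagonals from the principal axis, degrees.
DIAGONAL_OFFSET_DEG = 40.0

BACKGROUND, HEAD, COIN = 0, 1, 2


class MorphometryError(ValueError):
    """Raised when a mask or contour cannot support a measurement."""


@dataclass(frozen=True)
class ScaleCalibration:
    """Pixel-to-metric scale derived from the reference coin.

    ``mm_per_px`` always equals ``COIN_DIAMETER_MM / coin_diameter_px``.
    """

    mm_per_px: float
    coin_diameter_px: float
    coin_center: tuple[float, float]  # (row, col)

    def __post_init__(self) -> None:
        if self.mm_per_px <= 0 or self.coin_diameter_px <= 0:
            raise MorphometryError("scale calibration must be positive")
        expected = COIN_DIAMETER_MM / self.coin_diameter_px
        if not math.isclose(self.mm_per_px, expected, rel_tol=1e-9):
            raise MorphometryError(
                f"mm_per_px {self.mm_per_px} inconsistent with coin diameter "
                f"{self.coin_diameter_px} px (expected {expected})"
            )


@dataclass(frozen=True)
class CranialMeasurements:
    """The five cranial parameters (cm) and the two derived indices (%)."""

    length_cm: float
    width_cm: float
    perimeter_cm: float
    diag_a_cm: float
    diag_b_cm: float
    ci_pct: float = field(default=float("nan"))
    cvai_pct: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        if math.isnan(self.ci_pct):
            object.__setattr__(self, "ci_pct", 100.0 * self.width_cm / self.length_cm)
        if math.isnan(self.cvai_pct):
            object.__setattr__(
                self,
                "cvai_pct",
                100.0
                * abs(self.diag_a_cm - self.diag_b_cm)
                / max(self.diag_a_cm, self.diag_b_cm),
            )
        for name in ("length_cm", "width_cm", "perimeter_cm", "diag_a_cm", "diag_b_cm"):
            if getattr(self, name) <= 0:
                raise MorphometryError(f"{name} must be positive")
        if self.width_cm > self.length_cm * (1 + 1e-9):
            raise MorphometryError("width_cm must not exceed length_cm")
        if not math.isclose(
            self.ci_pct, 100.0 * self.width_cm / self.length_cm, rel_tol=1e-9
        ):
            raise MorphometryError("ci_pct inconsistent with width/length")
        if self.cvai_pct < 0:
            raise MorphometryError("cvai_pct must be non-negative")

    def as_dict(self) -> dict[str, float]:
        return {
            "length_cm": self.length_cm,
            "width_cm": self.width_cm,
            "perimeter_cm": self.perimeter_cm,
            "diag_a_cm": self.diag_a_cm,
            "diag_b_cm": self.diag_b_cm,
            "ci_pct": self.ci_pct,
            "cvai_pct": self.cvai_pct,
        }


# ---------------------------------------------------------------------------
# polygon primitives
# ---------------------------------------------------------------------------

def ensure_closed(contour: np.ndarray) -> np.ndarray:
    """Return the contour with its first vertex repeated at the end."""
    contour = np.asarray(contour, dtype=float)
    if contour.ndim != 2 or contour.shape[1] != 2 or contour.shape[0] < 3:
        raise MorphometryError("contour must be an (N, 2) array with N >= 3")
    if not np.allclose(contour[0], contour[-1]):
        contour = np.vstack([contour, contour[0]])
    return contour


def _ring(contour: np.ndarray) -> np.ndarray:
    """Closed contour without the duplicated last vertex."""
    return ensure_closed(contour)[:-1]


def polygon_area(contour: np.ndarray) -> float:
    """Signed shoelace area; positive for counterclockwise orientation."""
    v = _ring(contour)
    x, y = v[:, 0], v[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    return 0.5 * float(np.sum(x * yn - xn * y))


def polygon_perimeter(contour: np.ndarray) -> float:
    v = ensure_closed(contour)
    return float(np.sum(np.hypot(*np.diff(v, axis=0).T)))


def polygon_centroid(contour: np.ndarray) -> np.ndarray:
    """Area centroid from the exact polygon integrals."""
    v = _ring(contour)
    x, y = v[:, 0], v[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    area = 0.5 * np.sum(cross)
    if abs(area) < 1e-12:
        raise MorphometryError("zero-area polygon has no centroid")
    cx = np.sum((x + xn) * cross) / (6.0 * area)
    cy = np.sum((y + yn) * cross) / (6.0 * area)
    return np.array([cx, cy])


def polygon_second_moments(contour: np.ndarray) -> tuple[float, float, float]:
    """Central second area moments (mu20, mu02, mu11) of the polygon."""
    v = _ring(contour)
    x, y = v[:, 0], v[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    area = 0.5 * np.sum(cross)
    if abs(area) < 1e-12:
        raise MorphometryError("zero-area polygon has no moments")
    cx = np.sum((x + xn) * cross) / (6.0 * area)
    cy = np.sum((y + yn) * cross) / (6.0 * area)
    ixx = np.sum((x * x + x * xn + xn * xn) * cross) / 12.0
    iyy = np.sum((y * y + y * yn + yn * yn) * cross) / 12.0
    ixy = np.sum((x * yn + 2 * x * y + 2 * xn * yn + xn * y) * cross) / 24.0
    mu20 = ixx - area * cx * cx
    mu02 = iyy - area * cy * cy
    mu11 = ixy - area * cx * cy
    if area < 0:  # clockwise ring: moments flip sign with the area element
        mu20, mu02, mu11 = -mu20, -mu02, -mu11
    return float(mu20), float(mu02), float(mu11)


def is_simple_polygon(contour: np.ndarray) -> bool:
    """True if no two non-adjacent edges intersect (O(N^2) sweep-free check)."""
    v = _ring(contour)
    n = len(v)
    a, b = v, np.roll(v, -1, axis=0)
    d = b - a
    for i in range(n):
        # vectorized segment-segment intersection of edge i against edges > i+1
        j = np.arange(i + 2, n if i > 0 else n - 1)
        if len(j) == 0:
            continue
        denom = d[i, 0] * d[j, 1] - d[i, 1] * d[j, 0]
        rel = a[j] - a[i]
        t = (rel[:, 0] * d[j, 1] - rel[:, 1] * d[j, 0])
        s = (rel[:, 0] * d[i, 1] - rel[:, 1] * d[i, 0])
        with np.errstate(divide="ignore", invalid="ignore"):
            t = t / denom
            s = s / denom
        hit = (denom != 0) & (t > 1e-12) & (t < 1 - 1e-12) & (s > 1e-12) & (s < 1 - 1e-12)
        if np.any(hit):
            return False
    return True


# ---------------------------------------------------------------------------
# contour extraction and calibration
# ---------------------------------------------------------------------------

def extract_contour(mask: np.ndarray, cls: int = HEAD) -> np.ndarray:
    """Subpixel closed contour of one class at the 0.5 iso-level.

    ``mask`` may be an integer label mask (the class indicator is contoured)
    or a float field in [0, 1] — e.g. a class-probability plane — which is
    contoured directly, giving genuinely subpixel boundaries.

    The class region must be a single connected component.  The returned
    polygon is counterclockwise in (x, y) with first vertex == last vertex.
    """
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise MorphometryError("mask must be 2-D")
    if np.issubdtype(mask.dtype, np.floating):
        indicator = np.clip(mask.astype(float), 0.0, 1.0)
    else:
        indicator = (mask == cls).astype(float)
    hard = indicator >= 0.5
    if not hard.any():
        raise MorphometryError(f"class {cls}: no pixels at or above the 0.5 level")
    n_components = int(skmeasure.label(hard, connectivity=2).max())
    if n_components != 1:
        raise MorphometryError(
            f"class {cls}: expected one connected component, found {n_components}"
        )
    padded = np.pad(indicator, 1, mode="constant")
    contours = skmeasure.find_contours(padded, 0.5)
    if not contours:
        raise MorphometryError(f"class {cls}: no iso-contour found")
    # outer boundary = contour enclosing the largest area
    best, best_area = None, -1.0
    for c in contours:
        xy = np.column_stack([c[:, 1] - 1.0, c[:, 0] - 1.0])
        area = abs(polygon_area(xy))
        if area > best_area:
            best, best_area = xy, area
    contour = ensure_closed(best)
    if polygon_area(contour) < 0:
        contour = contour[::-1].copy()
    return contour


def calibrate_scale(mask: np.ndarray) -> ScaleCalibration:
    """Metric calibration from the coin component.

    The coin diameter in pixels is the equivalent-area circle diameter
    ``2 * sqrt(area / pi)`` of the coin-labelled component — robust to
    partial occlusion of the rim, unlike a circle fit.
    """
    mask = np.asarray(mask)
    coin = mask == COIN
    npix = int(coin.sum())
    if npix == 0:
        raise MorphometryError("no coin pixels in mask: cannot calibrate scale")
    if npix < 20:
        raise MorphometryError(f"coin too small to calibrate ({npix} px < 20 px)")
    diameter_px = 2.0 * math.sqrt(npix / math.pi)
    rows, cols = np.nonzero(coin)
    center = (float(rows.mean()), float(cols.mean()))
    return ScaleCalibration(
        mm_per_px=COIN_DIAMETER_MM / diameter_px,
        coin_diameter_px=diameter_px,
        coin_center=center,
    )


# ---------------------------------------------------------------------------
# axes and chords
# ---------------------------------------------------------------------------

def principal_axis(contour: np.ndarray) -> float:
    """Major-axis orientation in degrees, from second central area moments.

    Returned in (-90, 90].  An isotropic contour (circle) has no preferred
    axis; the tie is broken by returning 0.
    """
    mu20, mu02, mu11 = polygon_second_moments(contour)
    area = abs(polygon_area(contour))
    scale = mu20 + mu02  # ~ area * r^2, sets the anisotropy tolerance
    if math.hypot(2 * mu11, mu20 - mu02) < 1e-9 * max(scale, 1e-30):
        return 0.0
    theta = 0.5 * math.atan2(2 * mu11, mu20 - mu02)
    deg = math.degrees(theta)
    if deg <= -90.0:
        deg += 180.0
    elif deg > 90.0:
        deg -= 180.0
    return deg


def point_in_polygon(contour: np.ndarray, point: np.ndarray) -> bool:
    """Even-odd rule with the half-open edge convention (robust at vertices)."""
    v = _ring(contour)
    px, py = float(point[0]), float(point[1])
    x1, y1 = v[:, 0], v[:, 1]
    x2, y2 = np.roll(x1, -1), np.roll(y1, -1)
    straddles = (y1 <= py) != (y2 <= py)
    with np.errstate(divide="ignore", invalid="ignore"):
        xcross = x1 + (py - y1) / (y2 - y1) * (x2 - x1)
    return bool(np.sum(straddles & (xcross > px)) % 2 == 1)


def chord_length(contour: np.ndarray, point: np.ndarray, angle_deg: float) -> float:
    """Length of the line through ``point`` at ``angle_deg`` clipped by the
    polygon, taken between the outermost pair of boundary crossings."""
    contour = ensure_closed(contour)
    point = np.asarray(point, dtype=float)
    if not point_in_polygon(contour, point):
        raise MorphometryError("point is outside the polygon")
    v = _ring(contour)
    u = np.array([math.cos(math.radians(angle_deg)), math.sin(math.radians(angle_deg))])
    a = v
    b = np.roll(v, -1, axis=0)
    d = b - a
    # solve point + t*u = a + s*d for each edge
    denom = u[0] * d[:, 1] - u[1] * d[:, 0]
    rel = a - point
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (rel[:, 0] * d[:, 1] - rel[:, 1] * d[:, 0]) / denom
        s = (rel[:, 0] * u[1] - rel[:, 1] * u[0]) / denom
    # epsilon overlap at the edge endpoints so a crossing exactly on a
    # vertex cannot fall between two half-open intervals; dedupe afterwards
    eps = 1e-9
    valid = (denom != 0) & (s >= -eps) & (s < 1.0 + eps)
    t = np.sort(t[valid])
    if t.size:
        scale = max(1.0, float(np.abs(t).max()))
        t = t[np.concatenate([[True], np.diff(t) > 1e-9 * scale])]
    if t.size < 2:
        raise MorphometryError("chord line does not cross the polygon boundary twice")
    return float(t.max() - t.min())


def _resample_arclength(contour: np.ndarray, n_samples: int) -> np.ndarray:
    v = ensure_closed(contour)
    seg = np.hypot(*np.diff(v, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        raise MorphometryError("degenerate contour")
    si = np.linspace(0.0, total, n_samples, endpoint=False)
    return np.column_stack([np.interp(si, s, v[:, 0]), np.interp(si, s, v[:, 1])])


def smooth_contour(
    contour: np.ndarray,
    n_samples: int = 720,
    harmonics: int = 40,
    robust: bool = False,
) -> np.ndarray:
    """Anti-alias a contour by arc-length resampling and Fourier truncation.

    Marching-squares contours of binary masks carry stair-step noise that
    biases arc length upward and perturbs chord endpoints.  Keeping only the
    lowest ``harmonics`` Fourier modes of the complex boundary signal removes
    the (high-frequency) rasterization noise while leaving the smooth head
    shapes measured here — ellipse plus low-order perturbations —
    essentially unchanged.

    With ``robust=True`` the truncation becomes an iteratively reweighted
    (Tukey bisquare) harmonic regression of the radial profile about the
    centroid.  Narrow dents or protrusions — the typical residue of
    segmentation errors where background clutter touches the head — are
    strongly down-weighted, so the fit recovers the underlying smooth
    outline instead of averaging the artifact in.  Requires the contour to
    be star-shaped about its centroid, which measured head outlines are.
    """
    pts = _resample_arclength(contour, n_samples)
    if not robust:
        z = pts[:, 0] + 1j * pts[:, 1]
        zf = np.fft.fft(z)
        k = np.fft.fftfreq(n_samples, d=1.0 / n_samples)
        zf[np.abs(k) > harmonics] = 0.0
        zs = np.fft.ifft(zf)
        return ensure_closed(np.column_stack([zs.real, zs.imag]))

    centroid = polygon_centroid(contour)
    rel = pts - centroid
    phi = np.arctan2(rel[:, 1], rel[:, 0])
    radius = np.hypot(rel[:, 0], rel[:, 1])
    korder = np.arange(1, harmonics + 1)
    design = np.column_stack(
        [np.ones_like(phi)]
        + [f(k * phi) for k in korder for f in (np.cos, np.sin)]
    )
    weights = np.ones_like(radius)
    coef = None
    for _ in range(5):
        wsqrt = np.sqrt(weights)[:, None]
        coef, *_ = np.linalg.lstsq(wsqrt * design, np.sqrt(weights) * radius, rcond=None)
        resid = radius - design @ coef
        mad = np.median(np.abs(resid - np.median(resid)))
        scale = max(1.4826 * mad, 1e-9)
        u = resid / (4.685 * scale)
        weights = np.where(np.abs(u) < 1.0, (1.0 - u * u) ** 2, 0.0)
    phi_out = np.linspace(-np.pi, np.pi, n_samples, endpoint=False)
    design_out = np.column_stack(
        [np.ones_like(phi_out)]
        + [f(k * phi_out) for k in korder for f in (np.cos, np.sin)]
    )
    r_out = design_out @ coef
    out = centroid + np.column_stack(
        [r_out * np.cos(phi_out), r_out * np.sin(phi_out)]
    )
    return ensure_closed(out)


def refine_contour(
    contour: np.ndarray,
    image: np.ndarray,
    reference_chroma: Optional[np.ndarray] = None,
    search_px: float = 8.0,
    n_steps: int = 33,
    n_samples: int = 720,
    harmonics: int = 16,
    sigma_prior_px: float = 4.0,
    sigma_chroma: float = 0.05,
) -> np.ndarray:
    """Refine a head contour against the native-resolution image.

    For each of ``n_samples`` boundary normals the intensity profile over
    ``±search_px`` is split by a two-region variance criterion (a 1-D Otsu
    over positions, summed across RGB): region statistics locate a boundary
    far more robustly than gradient maxima in cluttered scenes.  Candidate
    splits are scored by (i) their variance reduction, (ii) how closely the
    inner side's chromaticity matches ``reference_chroma`` — the cap colour
    estimated from the segmented head interior; chromaticity is invariant
    to the rim shading — and (iii) a Gaussian prior on displacement from
    the initial contour.  The per-normal boundary positions then enter a
    confidence-weighted, Tukey-reweighted harmonic regression of the radial
    profile (star-shaped heads), so low-contrast or outlying arcs are
    interpolated from the rest of the boundary.

    Returns a closed contour in the same (x, y) pixel coordinates.  Known
    limitation: clutter adjacent to the head whose colour and chromaticity
    both match the cap over a wide arc defeats the scoring and the
    harmonic fit alike — the same scenes that defeat segmentation.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim == 2:
        img = img[..., None].repeat(3, axis=-1)
    if img.max() > 1.5:
        img = img / 255.0
    from scipy import ndimage as ndi

    pts = _resample_arclength(contour, n_samples)
    centroid = polygon_centroid(contour)
    rel = pts - centroid
    r0 = np.hypot(rel[:, 0], rel[:, 1])
    if (r0 <= search_px).any():
        raise MorphometryError("contour too small for the requested search range")
    normal = rel / r0[:, None]
    ts = np.linspace(-search_px, search_px, n_steps)
    xs = pts[:, 0][:, None] + ts[None, :] * normal[:, 0][:, None]
    ys = pts[:, 1][:, None] + ts[None, :] * normal[:, 1][:, None]
    prof = np.stack(
        [
            ndi.map_coordinates(img[..., c], [ys.ravel(), xs.ravel()],
                                order=1, mode="nearest").reshape(n_samples, n_steps)
            for c in range(3)
        ],
        axis=-1,
    )
    csum = np.cumsum(prof, axis=1)
    total = csum[:, -1, :]
    n_in = np.arange(1, n_steps)
    mean_in = csum[:, :-1, :] / n_in[None, :, None]
    mean_out = (total[:, None, :] - csum[:, :-1, :]) / (n_steps - n_in)[None, :, None]
    between = (n_in * (n_steps - n_in))[None, :] * ((mean_in - mean_out) ** 2).sum(-1)
    contrast_all = np.linalg.norm(mean_in - mean_out, axis=2)
    if reference_chroma is not None:
        chroma_in = mean_in / np.maximum(mean_in.sum(-1, keepdims=True), 1e-9)
        capness = np.exp(
            -((chroma_in - reference_chroma) ** 2).sum(-1) / (2 * sigma_chroma**2)
        )
    else:
        capness = np.ones_like(contrast_all)
    mid = (ts[:-1] + ts[1:]) / 2.0
    prior = np.exp(-0.5 * (mid / sigma_prior_px) ** 2)
    score = (
        between / (between.max(axis=1, keepdims=True) + 1e-12)
        * capness
        * prior[None, :]
    )
    k = score.argmax(axis=1)
    idx = np.arange(n_samples)
    confidence = contrast_all[idx, k] * capness[idx, k]
    r_new = r0 + mid[k]

    phi = np.arctan2(rel[:, 1], rel[:, 0])
    orders = np.arange(1, harmonics + 1)
    design = np.column_stack(
        [np.ones_like(phi)] + [f(j * phi) for j in orders for f in (np.cos, np.sin)]
    )
    base_w = confidence**2 / (np.mean(confidence**2) + 1e-12)
    weights = base_w.copy()
    coef = np.zeros(design.shape[1])
    for _ in range(5):
        ws = np.sqrt(weights)[:, None]
        coef, *_ = np.linalg.lstsq(ws * design, np.sqrt(weights) * r_new, rcond=None)
        resid = r_new - design @ coef
        mad = np.median(np.abs(resid - np.median(resid)))
        scale = max(1.4826 * mad, 1e-9)
        u = resid / (4.685 * scale)
        weights = base_w * np.where(np.abs(u) < 1.0, (1.0 - u * u) ** 2, 0.0)
    phi_out = np.linspace(-np.pi, np.pi, n_samples, endpoint=False)
    design_out = np.column_stack(
        [np.ones_like(phi_out)]
        + [f(j * phi_out) for j in orders for f in (np.cos, np.sin)]
    )
    r_out = design_out @ coef
    refined = centroid + np.column_stack(
        [r_out * np.cos(phi_out), r_out * np.sin(phi_out)]
    )
    return ensure_closed(refined)


def measure_head(
    head: np.ndarray,
    scale: ScaleCalibration,
    diag_offset_deg: float = DIAGONAL_OFFSET_DEG,
    cvai_denominator: str = "longer",
    smooth: bool = True,
    smooth_harmonics: int = 16,
    robust: bool = False,
) -> CranialMeasurements:
    """Measure the five cranial parameters on a head contour in pixel units.

    Length and width are caliper extents along / perpendicular to the
    principal axis (robust to concavities of flattened heads); the
    transcranial diagonals are chords through the area centroid at
    ``+/- diag_offset_deg`` from that axis.  ``cvai_denominator`` selects the
    published CVAI variant ("longer" or "shorter" diagonal).
    """
    if cvai_denominator not in ("longer", "shorter"):
        raise MorphometryError("cvai_denominator must be 'longer' or 'shorter'")
    contour = ensure_closed(head)
    if smooth:
        contour = smooth_contour(contour, harmonics=smooth_harmonics, robust=robust)
    axis = principal_axis(contour)
    th = math.radians(axis)
    rot = np.array([[math.cos(th), math.sin(th)], [-math.sin(th), math.cos(th)]])
    aligned = _ring(contour) @ rot.T
    length_px = float(aligned[:, 0].max() - aligned[:, 0].min())
    width_px = float(aligned[:, 1].max() - aligned[:, 1].min())
    if width_px > length_px:  # moment axis and extent axis disagree: swap
        length_px, width_px = width_px, length_px
        axis += 90.0
    centroid = polygon_centroid(contour)
    diag_a_px = chord_length(contour, centroid, axis + diag_offset_deg)
    diag_b_px = chord_length(contour, centroid, axis - diag_offset_deg)
    perimeter_px = polygon_perimeter(contour)
    cm = scale.mm_per_px / 10.0
    diag_a, diag_b = diag_a_px * cm, diag_b_px * cm
    denom = max(diag_a, diag_b) if cvai_denominator == "longer" else min(diag_a, diag_b)
    return CranialMeasurements(
        length_cm=length_px * cm,
        width_cm=width_px * cm,
        perimeter_cm=perimeter_px * cm,
        diag_a_cm=diag_a,
        diag_b_cm=diag_b,
        cvai_pct=100.0 * abs(diag_a - diag_b) / denom,
    )


def measure_mask(
    mask: np.ndarray,
    head_field: Optional[np.ndarray] = None,
    **measure_kwargs,
) -> tuple[CranialMeasurements, ScaleCalibration]:
    """Convenience: calibrate from the coin and measure the head of one mask.

    ``head_field`` optionally supplies a soft head-probability plane for
    subpixel contouring; the label mask still provides the calibration.
    """
    scale = calibrate_scale(mask)
    source = head_field if head_field is not None else mask
    contour = extract_contour(source, HEAD)
    return measure_head(contour, scale, **measure_kwargs), scale
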