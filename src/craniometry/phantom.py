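"""Synthetic top-view head phantoms with analytic ground truth.

A phantom emulates the clinical capture protocol: an infant head seen from
directly above (wearing a tight textured cap), a 50-Eurocent coin resting on
the vertex as the metric reference, and a cluttered desk-like background.
Head outlines are smooth periodic radial curves — an ellipse modulated by
low-order harmonics plus a localized posterior flattening that mimics
deformational plagiocephaly — so every cranial parameter has an analytic
(polygon-exact) ground-truth value, computed here by an oracle that is
deliberately independent of the measurement pipeline (shapely geometry and
caliper search instead of moment/edge-intersection code).

Severity is parameterized by ``asymmetry`` in [0, 1]: 0 gives a perfectly
mirror-symmetric outline (CVAI = 0), 1 flattens one posterior diagonal
direction strongly enough to reach the top of the clinically observed CVAI
range (~2.6 %).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from PIL import Image
from shapely.geometry import LineString, Point, Polygon
from skimage import draw as skdraw
from skimage import transform as sktransform

from .morphometry import (
    COIN_DIAMETER_MM,
    DIAGONAL_OFFSET_DEG,
    BACKGROUND,
    COIN,
    HEAD,
    CranialMeasurements,
    ensure_closed,
)

#: Clinically observed caliper ranges used as phantom sampling bounds (cm / %).
CLINICAL_BOUNDS = {
    "perimeter_cm": (39.2, 51.0),   # head circumference
    "length_cm": (12.0, 17.0),
    "width_cm": (11.3, 14.5),
    "diag_a_cm": (12.1, 15.9),
    "diag_b_cm": (11.7, 16.9),
    "cvai_pct": (0.1, 2.6),
}

# Depth of the posterior radial flattening at asymmetry = 1, chosen so that
# the oracle CVAI spans roughly the clinical range [0.1, 2.6] as asymmetry
# sweeps [0, 1].
_FLATTEN_DEPTH_MAX = 0.15
# Angular position (deg, head frame; 0 = anterior) and concentration of the
# flattening bump: the posterior end of the +40 deg transcranial diagonal.
_FLATTEN_CENTER_DEG = 180.0 + DIAGONAL_OFFSET_DEG
_FLATTEN_KAPPA = 6.0
# Relative amplitude scale of the seeded even-harmonic shape perturbation.
_HARMONIC_SCALE = 0.015


class PhantomError(ValueError):
    """Raised for invalid phantom parameters or impossible geometry."""


@dataclass(frozen=True)
class HeadShapeParams:
    """Nominal head-outline parameters, sampled from the clinical ranges."""

    length_cm: float
    width_cm: float
    asymmetry: float = 0.0
    rotation_deg: float = 0.0
    n_vertices: int = 512

    def __post_init__(self) -> None:
        if self.length_cm <= 0 or self.width_cm <= 0:
            raise PhantomError("length_cm and width_cm must be positive")
        if self.width_cm > self.length_cm:
            raise PhantomError("width_cm must not exceed length_cm")
        if not 0.0 <= self.asymmetry <= 1.0:
            raise PhantomError("asymmetry must lie in [0, 1]")
        if self.n_vertices < 64:
            raise PhantomError(
                "n_vertices must be >= 64 for adequate subpixel geometry"
            )


@dataclass
class Phantom:
    """A rendered synthetic capture with ground truth."""

    image: np.ndarray          # H x W x 3 uint8
    mask: np.ndarray           # H x W uint8, values in {0, 1, 2}
    truth: CranialMeasurements
    px_per_mm: float
    seed: int
    contour_cm: np.ndarray = field(repr=False, default=None)
    params: Optional[HeadShapeParams] = None

    def validate(self) -> None:
        from skimage import measure as skmeasure

        if self.image.shape[:2] != self.mask.shape:
            raise PhantomError("image and mask are not congruent")
        if not np.isin(self.mask, [BACKGROUND, HEAD, COIN]).all():
            raise PhantomError("mask contains labels outside {0, 1, 2}")
        head = self.mask != BACKGROUND  # head region includes the coin on top
        if int(skmeasure.label(head, connectivity=2).max()) != 1:
            raise PhantomError("head region is not a single connected component")


# ---------------------------------------------------------------------------
# contour generation
# ---------------------------------------------------------------------------

def _radial_profile(phi: np.ndarray, a: float, b: float, asymmetry: float,
                    c2: float, c4: float) -> np.ndarray:
    """Head radius as a function of polar angle in the head frame.

    ``phi`` must be a uniform full-circle grid (FFT filtering below).  The
    flattening bump has its Fourier modes k <= 2 removed: those modes only
    resize, translate, or tilt the shape — they shift the area centroid and
    the moment principal axis in ways that cancel most of the intended
    diagonal asymmetry — while the k >= 3 residue changes the transcranial
    diagonals directly.  The filtered bump reads as a posterior flat spot
    with a mild contralateral bulge, the classic plagiocephalic pattern.
    """
    r = a * b / np.sqrt((b * np.cos(phi)) ** 2 + (a * np.sin(phi)) ** 2)
    # even cosine harmonics: mirror-symmetric about both head axes
    r = r * (1.0 + asymmetry * _HARMONIC_SCALE * (c2 * np.cos(2 * phi) + c4 * np.cos(4 * phi)))
    if asymmetry > 0:
        phi0 = math.radians(_FLATTEN_CENTER_DEG)
        bump = np.exp(_FLATTEN_KAPPA * (np.cos(phi - phi0) - 1.0))
        spec = np.fft.rfft(bump)
        spec[:3] = 0.0
        bump = np.fft.irfft(spec, len(phi))
        bump /= max(abs(bump.max()), abs(bump.min()))  # unit peak depth
        r = r * (1.0 - _FLATTEN_DEPTH_MAX * asymmetry * bump)
    return r


def make_head_contour(params: HeadShapeParams, seed: int = 0) -> np.ndarray:
    """Closed simple head outline in cm, centred at the origin.

    The principal axis lies at ``params.rotation_deg`` (counterclockwise
    from +x) and the axis-aligned caliper extents in the head frame equal
    ``length_cm`` and ``width_cm`` exactly (enforced by renormalization).
    ``asymmetry = 0`` yields an exact ellipse, hence a mirror-symmetric
    contour with CVAI identically zero.
    """
    rng = np.random.default_rng(seed)
    c2 = rng.uniform(-1.0, 1.0)
    c4 = rng.uniform(-1.0, 1.0)
    n = params.n_vertices
    phi = 2.0 * np.pi * np.arange(n) / n
    a, b = params.length_cm / 2.0, params.width_cm / 2.0
    r = _radial_profile(phi, a, b, params.asymmetry, c2, c4)
    x, y = r * np.cos(phi), r * np.sin(phi)
    # renormalize head-frame extents to the nominal length and width
    for _ in range(3):
        sx = params.length_cm / (x.max() - x.min())
        sy = params.width_cm / (y.max() - y.min())
        x, y = x * sx, y * sy
    x -= (x.max() + x.min()) / 2.0
    y -= (y.max() + y.min()) / 2.0
    th = math.radians(params.rotation_deg)
    xr = x * math.cos(th) - y * math.sin(th)
    yr = x * math.sin(th) + y * math.cos(th)
    return ensure_closed(np.column_stack([xr, yr]))


# ---------------------------------------------------------------------------
# analytic oracle
# ---------------------------------------------------------------------------

def _caliper_extent(verts: np.ndarray, theta_rad: float) -> float:
    proj = verts[:, 0] * math.cos(theta_rad) + verts[:, 1] * math.sin(theta_rad)
    return float(proj.max() - proj.min())


def _covariance_axis(verts: np.ndarray) -> float:
    """Principal-axis orientation (radians) from the exact area covariance.

    The covariance is assembled from signed origin-fan triangles (for a
    triangle with vertices ``0, P, Q``: ``int x x^T dA = A/12 * (P P^T +
    Q Q^T + (P+Q)(P+Q)^T)``) and diagonalized — an implementation route
    independent of the pipeline's Green's-theorem line integrals, though it
    evaluates the same mathematical object.
    """
    p = verts
    q = np.roll(verts, -1, axis=0)
    cross = p[:, 0] * q[:, 1] - q[:, 0] * p[:, 1]
    area = 0.5 * np.sum(cross)
    if abs(area) < 1e-12:
        raise PhantomError("zero-area polygon has no principal axis")
    centroid = np.sum((p + q) * cross[:, None], axis=0) / (6.0 * area)
    second = np.zeros((2, 2))
    for pi, qi, cr in zip(p, q, cross):
        s = pi + qi
        second += (cr / 2.0) / 12.0 * (
            np.outer(pi, pi) + np.outer(qi, qi) + np.outer(s, s)
        )
    cov = second - area * np.outer(centroid, centroid)
    cov /= area  # sign-normalizes clockwise rings too
    evals, evecs = np.linalg.eigh(cov)
    if (evals[1] - evals[0]) < 1e-12 * max(evals[1], 1e-30):
        return 0.0  # isotropic (circle): documented tie-break
    major = evecs[:, 1]
    return math.atan2(major[1], major[0]) % math.pi


def _shapely_chord(poly: Polygon, center: np.ndarray, theta_rad: float) -> float:
    u = np.array([math.cos(theta_rad), math.sin(theta_rad)])
    reach = 4.0 * math.sqrt(poly.area) + 10.0
    line = LineString([center - reach * u, center + reach * u])
    inter = line.intersection(poly)
    coords: list[tuple[float, float]] = []
    geoms = getattr(inter, "geoms", [inter])
    for g in geoms:
        coords.extend(g.coords)
    if not coords:
        raise PhantomError("chord line misses the polygon")
    proj = np.array([(cx - center[0]) * u[0] + (cy - center[1]) * u[1] for cx, cy in coords])
    return float(proj.max() - proj.min())


def oracle_measurements(contour: np.ndarray) -> CranialMeasurements:
    """Brute-force ground-truth measurements on a polygon, full precision.

    Shares the pipeline's definitions (moment principal axis, caliper
    extents, centroid chords at +/- 40 deg) but none of its implementation:
    the axis comes from fan-triangle covariance diagonalization, chords and
    perimeter from shapely geometry, with no rasterization anywhere.
    """
    contour = ensure_closed(contour)
    poly = Polygon(contour[:-1])
    if not (poly.is_valid and poly.is_simple):
        raise PhantomError("contour is not a simple polygon")
    verts = contour[:-1]
    axis = _covariance_axis(verts)
    if _caliper_extent(verts, axis) < _caliper_extent(verts, axis + math.pi / 2.0):
        axis += math.pi / 2.0
    length = _caliper_extent(verts, axis)
    width = _caliper_extent(verts, axis + math.pi / 2.0)
    centroid = np.array([poly.centroid.x, poly.centroid.y])
    off = math.radians(DIAGONAL_OFFSET_DEG)
    diag_a = _shapely_chord(poly, centroid, axis + off)
    diag_b = _shapely_chord(poly, centroid, axis - off)
    return CranialMeasurements(
        length_cm=length,
        width_cm=width,
        perimeter_cm=float(poly.exterior.length),
        diag_a_cm=diag_a,
        diag_b_cm=diag_b,
    )


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _value_noise(shape: tuple[int, int], rng: np.random.Generator,
                 scales=(8, 16, 32)) -> np.ndarray:
    """Multi-octave smooth value noise in [0, 1] (Perlin-like)."""
    h, w = shape
    out = np.zeros(shape)
    weight = 0.0
    for k, sc in enumerate(scales):
        coarse = rng.random((max(2, h // sc + 1), max(2, w // sc + 1)))
        up = sktransform.resize(coarse, shape, order=1, mode="reflect",
                                anti_aliasing=False)
        wgt = 1.0 / (k + 1)
        out += wgt * up
        weight += wgt
    out /= weight
    lo, hi = out.min(), out.max()
    return (out - lo) / (hi - lo + 1e-12)


def _background(shape: tuple[int, int], rng: np.random.Generator,
                cluttered: bool) -> np.ndarray:
    h, w = shape
    if not cluttered:
        return np.full((h, w, 3), 0.10)
    base = 0.20 + 0.55 * _value_noise(shape, rng)
    img = np.stack([base * s for s in (1.0, 0.96, 0.90)], axis=-1)
    for _ in range(8):
        rh = rng.integers(h // 10 + 1, max(h // 2, h // 10 + 2))
        rw = rng.integers(w // 10 + 1, max(w // 2, w // 10 + 2))
        r0 = rng.integers(0, max(1, h - rh))
        c0 = rng.integers(0, max(1, w - rw))
        color = rng.uniform(0.05, 0.9, size=3)
        img[r0:r0 + rh, c0:c0 + rw] = 0.35 * img[r0:r0 + rh, c0:c0 + rw] + 0.65 * color
    return img


def render_phantom(
    contour: np.ndarray,
    px_per_mm: float,
    coin_offset_mm: tuple[float, float] = (0.0, 0.0),
    noise_sd: float = 0.02,
    seed: int = 0,
    canvas_px: Optional[tuple[int, int]] = None,
    cluttered: bool = True,
) -> Phantom:
    """Rasterize a head contour into an RGB capture with ground-truth mask.

    The coin disc (24.25 mm) is placed at the head's area centroid plus
    ``coin_offset_mm`` (x, y in the contour frame) and must fit entirely
    inside the outline.  ``canvas_px`` fixes the output size (rows, cols);
    by default the canvas is the head bounding box plus a margin.  With
    ``noise_sd = 0`` and a fixed seed the output is bit-reproducible.
    """
    if px_per_mm <= 0:
        raise PhantomError("px_per_mm must be positive")
    contour = ensure_closed(contour)
    truth = oracle_measurements(contour)  # validates simplicity too
    s = 10.0 * px_per_mm  # px per cm
    verts_px = contour * s

    poly_cm = Polygon(contour[:-1])
    centroid_cm = np.array([poly_cm.centroid.x, poly_cm.centroid.y])
    coin_center_cm = centroid_cm + np.asarray(coin_offset_mm, dtype=float) / 10.0
    coin_r_cm = COIN_DIAMETER_MM / 20.0
    if not Point(coin_center_cm).buffer(coin_r_cm, 64).within(poly_cm):
        raise PhantomError("coin does not fit inside the head outline")

    xmin, ymin = verts_px[:-1].min(axis=0)
    xmax, ymax = verts_px[:-1].max(axis=0)
    if canvas_px is None:
        margin = max(8.0, 0.08 * max(xmax - xmin, ymax - ymin))
        wpx = int(math.ceil(xmax - xmin + 2 * margin))
        hpx = int(math.ceil(ymax - ymin + 2 * margin))
    else:
        hpx, wpx = canvas_px
        if (xmax - xmin) > wpx - 4 or (ymax - ymin) > hpx - 4:
            raise PhantomError("head does not fit on the requested canvas")
    # translate so the head bbox is centred on the canvas
    tx = (wpx - 1) / 2.0 - (xmax + xmin) / 2.0
    ty = (hpx - 1) / 2.0 - (ymax + ymin) / 2.0
    cols = verts_px[:, 0] + tx
    rows = verts_px[:, 1] + ty

    mask = np.zeros((hpx, wpx), dtype=np.uint8)
    head_mask = skdraw.polygon2mask((hpx, wpx), np.column_stack([rows, cols]))
    mask[head_mask] = HEAD
    coin_rc = (coin_center_cm[1] * s + ty, coin_center_cm[0] * s + tx)
    rr, cc = skdraw.disk(coin_rc, COIN_DIAMETER_MM * px_per_mm / 2.0, shape=(hpx, wpx))
    mask[rr, cc] = COIN

    rng = np.random.default_rng(seed)
    img = _background((hpx, wpx), rng, cluttered)
    # cap texture: brownish base with fine fabric-like noise and rim shading
    from scipy import ndimage as ndi

    cap_noise = _value_noise((hpx, wpx), rng, scales=(2, 5, 11))
    edt = ndi.distance_transform_edt(head_mask)
    rim = np.clip(edt / (edt.max() + 1e-9), 0.0, 1.0)
    cap_v = 0.38 + 0.12 * cap_noise + 0.18 * rim
    cap = np.stack([cap_v * t for t in (1.05, 0.85, 0.65)], axis=-1)
    img[head_mask] = cap[head_mask]
    # coin: bright metallic disc with a radial highlight
    coin_mask = mask == COIN
    if coin_mask.any():
        rgrid, cgrid = np.mgrid[0:hpx, 0:wpx]
        dist = np.hypot(rgrid - coin_rc[0], cgrid - coin_rc[1])
        rad = COIN_DIAMETER_MM * px_per_mm / 2.0
        highlight = np.clip(1.0 - dist / (rad + 1e-9), 0.0, 1.0)
        coin_v = 0.72 + 0.22 * highlight
        coin_img = np.stack([coin_v * t for t in (1.0, 0.92, 0.62)], axis=-1)
        img[coin_mask] = coin_img[coin_mask]
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, img.shape)
    image = (np.clip(img, 0.0, 1.0) * 255.0).round().astype(np.uint8)

    contour_canvas = np.column_stack([cols, rows]) / s  # cm, canvas frame
    ph = Phantom(
        image=image,
        mask=mask,
        truth=truth,
        px_per_mm=px_per_mm,
        seed=seed,
        contour_cm=contour_canvas,
    )
    ph.validate()
    return ph


# ---------------------------------------------------------------------------
# clinical-range sampling and dataset IO
# ---------------------------------------------------------------------------

def sample_params(
    rng: np.random.Generator,
    symmetric: bool = False,
    max_tries: int = 200,
) -> tuple[HeadShapeParams, np.ndarray]:
    """Draw head parameters whose oracle measurements fall inside the
    clinical caliper ranges, by rejection sampling.

    Returns the accepted parameters together with the generated contour.
    ``symmetric=True`` forces asymmetry 0 (the CVAI lower bound is then
    waived — a perfectly symmetric head has CVAI 0).
    """
    for _ in range(max_tries):
        length = rng.uniform(12.4, 17.0)
        width = rng.uniform(11.3, min(14.5, length - 0.05))
        asym = 0.0 if symmetric else rng.uniform(0.05, 1.0)
        rot = rng.uniform(-90.0, 90.0)
        params = HeadShapeParams(length, width, asymmetry=asym, rotation_deg=rot)
        contour = make_head_contour(params, seed=int(rng.integers(2**31 - 1)))
        m = oracle_measurements(contour)
        checks = dict(CLINICAL_BOUNDS)
        if symmetric:
            checks.pop("cvai_pct")
        vals = m.as_dict()
        if all(lo <= vals[k] <= hi for k, (lo, hi) in checks.items()):
            return params, contour
    raise PhantomError("rejection sampling failed to find in-range parameters")


_MASK_PALETTE = [0, 0, 0, 120, 200, 120, 255, 215, 0]


def save_phantom(ph: Phantom, directory: str | Path, stem: str) -> dict[str, str]:
    """Write image PNG, indexed mask PNG and a JSON truth sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    image_path = directory / f"{stem}.png"
    mask_path = directory / f"{stem}_mask.png"
    json_path = directory / f"{stem}.json"
    Image.fromarray(ph.image, mode="RGB").save(image_path)
    pal = Image.fromarray(ph.mask, mode="P")
    pal.putpalette(_MASK_PALETTE)
    pal.save(mask_path)
    payload = {
        "truth": ph.truth.as_dict(),
        "px_per_mm": ph.px_per_mm,
        "seed": ph.seed,
    }
    if ph.params is not None:
        payload["params"] = {
            "length_cm": ph.params.length_cm,
            "width_cm": ph.params.width_cm,
            "asymmetry": ph.params.asymmetry,
            "rotation_deg": ph.params.rotation_deg,
            "n_vertices": ph.params.n_vertices,
        }
    json_path.write_text(json.dumps(payload, indent=2))
    return {"image": str(image_path), "mask": str(mask_path), "truth": str(json_path)}


def load_mask(path: str | Path) -> np.ndarray:
    """Read an indexed-PNG label mask back as a {0,1,2} uint8 array."""
    return np.asarray(Image.open(path)).astype(np.uint8)


def load_image(path: str | Path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"))
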