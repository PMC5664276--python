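"""Myocardial ROI handling: contour rasterization, LV center, midline fraction.

Rasterization uses the even-odd rule evaluated at pixel centers, with
points on a polygon edge counted as inside; this keeps the mask exactly
reproducible by a per-pixel point-in-polygon oracle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from lvquant.io import ContourSet

_EDGE_TOL = 1e-9


@dataclass
class MyocardialMask:
    """Annular binary myocardium mask with the LV center.

    ``mask`` is True on myocardium; ``center`` is the subpixel (x, y)
    position of the LV cavity center used for sector and midline analysis.
    """

    mask: np.ndarray
    center: tuple[float, float]

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.n_pixels == 0:
            raise ValueError("myocardial mask is empty")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


def points_in_polygon(
    points: np.ndarray, polygon: np.ndarray, boundary: bool = True
) -> np.ndarray:
    """Even-odd point-in-polygon test for an array of (x, y) points.

    Points lying on a polygon edge are inside when ``boundary`` is True,
    outside otherwise.  The polygon is implicitly closed.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    poly = np.asarray(polygon, dtype=float)
    px, py = pts[:, 0], pts[:, 1]
    inside = np.zeros(len(pts), dtype=bool)
    on_edge = np.zeros(len(pts), dtype=bool)
    n = len(poly)
    for i in range(n):
        x1, y1 = poly[i]
        x2, y2 = poly[(i + 1) % n]
        # on-segment test: zero cross product and within the segment bbox
        cross = (x2 - x1) * (py - y1) - (y2 - y1) * (px - x1)
        seg_len = np.hypot(x2 - x1, y2 - y1)
        on_seg = (
            (np.abs(cross) <= _EDGE_TOL * max(seg_len, 1.0))
            & (px >= min(x1, x2) - _EDGE_TOL)
            & (px <= max(x1, x2) + _EDGE_TOL)
            & (py >= min(y1, y2) - _EDGE_TOL)
            & (py <= max(y1, y2) + _EDGE_TOL)
        )
        on_edge |= on_seg
        # even-odd crossing of the horizontal ray towards +x
        crosses = (y1 > py) != (y2 > py)
        with np.errstate(divide="ignore", invalid="ignore"):
            x_int = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
        inside ^= crosses & (px < x_int)
    return np.where(on_edge, boundary, inside)


def contours_to_mask(contours: ContourSet, image_shape: tuple[int, int]) -> MyocardialMask:
    """Rasterize epi/endo contours to the annular myocardium mask.

    mask = inside(epicardium) AND NOT inside(endocardium), with inclusion by
    the pixel-center even-odd test.  Pixels on the epicardial edge are
    myocardium; pixels on or inside the endocardial edge are cavity.
    """
    h, w = image_shape
    y, x = np.mgrid[0:h, 0:w]
    pts = np.column_stack([x.ravel(), y.ravel()]).astype(float)
    in_epi = points_in_polygon(pts, contours.epicardium, boundary=True)
    in_endo = points_in_polygon(pts, contours.endocardium, boundary=True)
    mask = (in_epi & ~in_endo).reshape(h, w)
    if not mask.any():
        raise ValueError("contours rasterize to an empty myocardium mask")
    return MyocardialMask(mask=mask, center=lv_center(contours))


def _polygon_centroid(poly: np.ndarray) -> tuple[float, float]:
    """Area-weighted centroid of a simple polygon (shoelace formula)."""
    x, y = poly[:, 0], poly[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    area = cross.sum() / 2.0
    if abs(area) < 1e-12:
        return float(x.mean()), float(y.mean())
    cx = ((x + xn) * cross).sum() / (6.0 * area)
    cy = ((y + yn) * cross).sum() / (6.0 * area)
    return float(cx), float(cy)


def lv_center(contours_or_mask: ContourSet | np.ndarray) -> tuple[float, float]:
    """Locate the LV cavity center.

    With contours: the centroid of the endocardial polygon.  With a binary
    mask: the centroid of the mask's hole (the cavity connected component);
    if no hole is detectable, falls back to the mask centroid with a warning.
    """
    if isinstance(contours_or_mask, ContourSet):
        return _polygon_centroid(contours_or_mask.endocardium)
    mask = np.asarray(contours_or_mask, dtype=bool)
    filled = ndimage.binary_fill_holes(mask)
    cavity = filled & ~mask
    if cavity.any():
        labels, n = ndimage.label(cavity)
        sizes = ndimage.sum_labels(cavity, labels, index=range(1, n + 1))
        cy, cx = ndimage.center_of_mass(labels == (1 + int(np.argmax(sizes))))
        return float(cx), float(cy)
    warnings.warn("no cavity detectable; falling back to mask centroid", stacklevel=2)
    cy, cx = ndimage.center_of_mass(mask)
    return float(cx), float(cy)


def midline_lesion_fraction(
    mask: MyocardialMask,
    lesion_mask: np.ndarray,
    center: tuple[float, float] | None = None,
    n_samples: int = 3600,
) -> float:
    """Lesion fraction along the mid-wall circumference, in percent.

    For each of ``n_samples`` angles the wall is probed along the ray from
    the LV center; the midline point sits at the midpoint radius between the
    innermost and outermost myocardial crossing.  The returned value is the
    percentage of midline samples landing in the lesion among those landing
    in myocardium — the mask-level analog of a histological length-based
    infarct measurement.
    """
    lesion_mask = np.asarray(lesion_mask, dtype=bool)
    if np.any(lesion_mask & ~mask.mask):
        raise ValueError("lesion_mask must be a subset of the myocardium mask")
    cx, cy = center if center is not None else mask.center
    h, w = mask.mask.shape
    my, mx = np.nonzero(mask.mask)
    r_max = float(np.hypot(mx - cx, my - cy).max()) + 1.0
    radii = np.arange(0.25, r_max, 0.25)

    angles = np.arange(n_samples) * (360.0 / n_samples)
    cos = np.cos(np.radians(angles))[:, None]
    sin = np.sin(np.radians(angles))[:, None]
    cols = np.round(cx + radii[None, :] * cos).astype(int)
    rows = np.round(cy + radii[None, :] * sin).astype(int)
    ok = (rows >= 0) & (rows < h) & (cols >= 0) & (cols < w)
    hit = np.zeros(cols.shape, dtype=bool)
    hit[ok] = mask.mask[rows[ok], cols[ok]]

    any_hit = hit.any(axis=1)
    n_undefined = int((~any_hit).sum())
    first = hit.argmax(axis=1)
    last = hit.shape[1] - 1 - hit[:, ::-1].argmax(axis=1)
    r_mid = (radii[first] + radii[last]) / 2.0
    mcol = np.round(cx + r_mid * cos[:, 0]).astype(int)
    mrow = np.round(cy + r_mid * sin[:, 0]).astype(int)
    in_img = (mrow >= 0) & (mrow < h) & (mcol >= 0) & (mcol < w)
    use = any_hit & in_img
    in_myo = np.zeros(n_samples, dtype=bool)
    in_myo[use] = mask.mask[mrow[use], mcol[use]]
    in_lesion = np.zeros(n_samples, dtype=bool)
    in_lesion[in_myo] = lesion_mask[mrow[in_myo], mcol[in_myo]]
    n_myo = int(in_myo.sum())
    n_lesion = int(in_lesion.sum())
    if n_undefined > 0.10 * n_samples:
        raise ValueError(
            f"wall radius undefined at {n_undefined}/{n_samples} angles; "
            "degenerate myocardium for midline analysis"
        )
    if n_myo == 0:
        raise ValueError("no midline samples landed in myocardium")
    return 100.0 * n_lesion / n_myo
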