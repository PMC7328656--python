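"""Construction of the three training-annotation regimes.

Herbarium scoring workflows often record each reproductive structure as a
single point marker.  This module turns such markers into trainable
masks:

* **point masks** — a 3×3-pixel square stamped at each marker (clipped at
  image borders);
* **partial masks** — Otsu foreground segmentation inside a 100×100-pixel
  window centered on each marker, restricted to the connected component
  the marker falls in;
* **full masks** — hand-drawn outlines, validated here for degenerate or
  duplicated geometry.

The Otsu threshold is computed from first principles (exhaustive
between-class-variance maximization over the 256 gray levels), since the
thresholding rule is itself part of the annotation protocol under test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .annotations import Category, MaskRegion, Provenance, SheetAnnotation

logger = logging.getLogger(__name__)

__all__ = [
    "PointMarker",
    "OtsuResult",
    "make_point_mask",
    "otsu_threshold",
    "make_partial_mask",
    "validate_full_masks",
    "rgb_to_gray",
]

#: side of the square stamped around each point marker, px
POINT_MASK_SIZE = 3
#: side of the Otsu window around each marker, px
DEFAULT_WINDOW = 100


@dataclass(frozen=True)
class PointMarker:
    """A scored point near the tip or center of one reproductive structure."""

    x: int
    y: int
    category: Category


@dataclass(frozen=True)
class OtsuResult:
    """Outcome of Otsu thresholding on one window.

    ``threshold`` is the gray level t maximizing the between-class
    variance ω₀(t)·ω₁(t)·(μ₀(t)−μ₁(t))², with class 0 = {levels ≤ t};
    ties broken toward the smallest t.  ``degenerate`` is set when the
    histogram occupies a single level (no split exists).
    """

    threshold: int
    between_class_variance: float
    degenerate: bool


def rgb_to_gray(image: np.ndarray) -> np.ndarray:
    """8-bit luminance (0.299 R + 0.587 G + 0.114 B), rounded."""
    img = np.asarray(image)
    if img.ndim == 2:
        return img.astype(np.uint8)
    gray = img[..., 0] * 0.299 + img[..., 1] * 0.587 + img[..., 2] * 0.114
    return np.clip(np.round(gray), 0, 255).astype(np.uint8)


def make_point_mask(marker: PointMarker, image_dims: tuple[int, int]) -> MaskRegion:
    """3×3-pixel square mask centered on ``marker``, clipped at borders.

    ``image_dims`` is ``(width, height)``.  A marker on an image corner
    yields a 2×2 mask, on an edge a 2×3 or 3×2 one.
    """
    width, height = image_dims
    if not (0 <= marker.x < width and 0 <= marker.y < height):
        raise ValueError(f"marker ({marker.x}, {marker.y}) outside "
                         f"{width}x{height} image")
    half = POINT_MASK_SIZE // 2
    x0 = max(marker.x - half, 0)
    y0 = max(marker.y - half, 0)
    x1 = min(marker.x + half + 1, width)
    y1 = min(marker.y + half + 1, height)
    raster = np.ones((y1 - y0, x1 - x0), dtype=bool)
    return MaskRegion.from_raster(raster, offset=(x0, y0))


def otsu_threshold(window: np.ndarray) -> OtsuResult:
    """Otsu's threshold of an 8-bit grayscale window.

    Evaluates the between-class variance at every candidate level
    t ∈ [0, 255] with class 0 = {pixels ≤ t} and returns the smallest
    maximizer.  Constant windows are flagged degenerate (variance 0,
    threshold at the occupied level).
    """
    window = np.asarray(window)
    if window.size == 0:
        raise ValueError("empty window")
    hist = np.bincount(window.ravel().astype(np.uint8), minlength=256).astype(float)
    n = hist.sum()
    occupied = np.flatnonzero(hist)
    if occupied.size == 1:
        return OtsuResult(threshold=int(occupied[0]),
                          between_class_variance=0.0, degenerate=True)

    levels = np.arange(256, dtype=float)
    w0 = np.cumsum(hist) / n                    # P(level <= t)
    sum0 = np.cumsum(hist * levels)             # sum of levels <= t
    total = sum0[-1]
    w1 = 1.0 - w0
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = sum0 / np.cumsum(hist)
        mu1 = (total - sum0) / (n - np.cumsum(hist))
    var_between = w0 * w1 * (mu0 - mu1) ** 2
    var_between = np.where((w0 > 0) & (w1 > 0), var_between, -np.inf)
    t = int(np.argmax(var_between))             # argmax takes smallest on ties
    return OtsuResult(threshold=t,
                      between_class_variance=float(var_between[t]),
                      degenerate=False)


def _window_bounds(marker: PointMarker, width: int, height: int,
                   window_size: int) -> tuple[int, int, int, int]:
    # even window: span [x-half, x+half), left/top biased
    half = window_size // 2
    x0 = max(marker.x - half, 0)
    y0 = max(marker.y - half, 0)
    x1 = min(marker.x - half + window_size, width)
    y1 = min(marker.y - half + window_size, height)
    return x0, y0, x1, y1


def make_partial_mask(image: np.ndarray, marker: PointMarker,
                      window_size: int = DEFAULT_WINDOW) -> MaskRegion:
    """Otsu foreground component around a marker, in full-image coordinates.

    The window of side ``window_size`` centered on the marker (clipped to
    the image) is thresholded with :func:`otsu_threshold` on luminance.
    The foreground is the Otsu class the marker pixel belongs to, unless
    that class is brighter than the other *and* does not contain the
    marker strictly — plant material is darker than mounting paper, so on
    boundary ambiguity the darker class wins.  Of the foreground's
    8-connected components, the one containing the marker is returned; if
    none does, the one whose centroid is nearest to the marker.

    Degenerate (single-level) windows fall back to a 3×3 point mask with
    a logged warning.
    """
    img = np.asarray(image)
    height, width = img.shape[:2]
    if not (0 <= marker.x < width and 0 <= marker.y < height):
        raise ValueError(f"marker ({marker.x}, {marker.y}) outside image")
    x0, y0, x1, y1 = _window_bounds(marker, width, height, window_size)
    gray = rgb_to_gray(img[y0:y1, x0:x1])
    res = otsu_threshold(gray)
    if res.degenerate:
        logger.warning("degenerate Otsu window at marker (%d, %d); "
                       "falling back to point mask", marker.x, marker.y)
        return make_point_mask(marker, (width, height))

    dark = gray <= res.threshold
    marker_dark = bool(dark[marker.y - y0, marker.x - x0])
    foreground = dark if marker_dark else ~dark
    # marker on the threshold boundary belongs to the dark class already
    # (<= semantics); no extra handling needed.

    labels, n_comp = ndimage.label(foreground, structure=np.ones((3, 3), dtype=int))
    marker_label = labels[marker.y - y0, marker.x - x0]
    if marker_label > 0:
        component = labels == marker_label
    else:
        centroids = ndimage.center_of_mass(foreground, labels, range(1, n_comp + 1))
        d2 = [(cy - (marker.y - y0)) ** 2 + (cx - (marker.x - x0)) ** 2
              for cy, cx in centroids]
        component = labels == (1 + int(np.argmin(d2)))
    return MaskRegion.from_raster(component, offset=(x0, y0))


def validate_full_masks(sheet: SheetAnnotation) -> list[str]:
    """Report geometry defects in a hand-annotated (full-mask) sheet.

    Returns human-readable violation strings; an empty list means the
    sheet is valid.  Checks: self-intersecting polygons, zero rasterized
    area, and duplicate geometry between instances.
    """
    import shapely

    if sheet.provenance is not Provenance.FULL:
        raise ValueError("full-mask validation applies to provenance=full sheets")
    violations: list[str] = []
    polys = []
    for idx, inst in enumerate(sheet.instances):
        verts = inst.mask.to_polygon()
        poly = shapely.polygons(np.asarray(verts, dtype=float))
        if not poly.is_valid:
            violations.append(f"instance {idx}: self-intersecting polygon")
        if inst.mask.area == 0:
            violations.append(f"instance {idx}: zero-area mask")
        polys.append(poly.buffer(0) if not poly.is_valid else poly)
    for i in range(len(polys)):
        for j in range(i + 1, len(polys)):
            if polys[i].equals(polys[j]):
                violations.append(f"instances {i} and {j}: duplicate geometry")
    return violations
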