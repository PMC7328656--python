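"""Domain types, coordinate conventions and COCO-dialect JSON I/O.

Coordinate conventions used throughout the package:

* pixel coordinates are 0-based, origin at the top-left corner, ``x``
  rightward and ``y`` downward;
* bounding boxes ``(x, y, w, h)`` are half-open: they cover the pixel
  columns ``[x, x + w)`` and rows ``[y, y + h)``, so ``w`` and ``h`` are
  pixel counts;
* a pixel ``(i, j)`` (row, column) belongs to a polygon mask iff its
  center ``(j + 0.5, i + 0.5)`` lies strictly inside the polygon.

Masks are stored as polygons in annotation files (the dialect written by
web annotation tools for instance segmentation) and rasterized lazily for
metric computation.
"""

from __future__ import annotations

import enum
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import shapely
from PIL import Image
from skimage import measure

logger = logging.getLogger(__name__)

__all__ = [
    "Category",
    "Provenance",
    "MaskRegion",
    "OrganInstance",
    "SheetAnnotation",
    "ScaleCalibration",
    "BUDS_FLOWERS",
    "FRUITS",
    "METACATEGORIES",
    "read_annotations",
    "write_annotations",
    "resize_image_and_annotations",
]


class Category(enum.IntEnum):
    """The four reproductive-structure types scored on a sheet.

    Integer values are the stable category ids used in annotation files.
    """

    BUD = 1
    FLOWER = 2
    IMMATURE_FRUIT = 3
    MATURE_FRUIT = 4

    @property
    def label(self) -> str:
        return self.name.lower()

    @classmethod
    def from_label(cls, label: str) -> "Category":
        try:
            return cls[label.upper()]
        except KeyError:
            raise ValueError(f"unknown category name: {label!r}") from None


#: Metacategories are derived groupings, never stored in files.
BUDS_FLOWERS: tuple[Category, ...] = (Category.BUD, Category.FLOWER)
FRUITS: tuple[Category, ...] = (Category.IMMATURE_FRUIT, Category.MATURE_FRUIT)
METACATEGORIES: dict[str, tuple[Category, ...]] = {
    "buds_flowers": BUDS_FLOWERS,
    "fruits": FRUITS,
}


class Provenance(str, enum.Enum):
    """How an annotation set was produced."""

    POINTS = "points"
    PARTIAL = "partial"
    FULL = "full"
    PREDICTED = "predicted"


def rasterize_polygon(vertices: np.ndarray, height: int, width: int,
                      x0: int = 0, y0: int = 0) -> np.ndarray:
    """Rasterize polygon ``vertices`` (N×2, (x, y)) onto a window.

    The window spans columns ``[x0, x0 + width)`` and rows
    ``[y0, y0 + height)`` of the image frame.  A pixel is set iff its
    center lies strictly inside the polygon.
    """
    poly = shapely.polygons(np.asarray(vertices, dtype=float))
    if not poly.is_valid:
        poly = poly.buffer(0)
    jj, ii = np.meshgrid(np.arange(width), np.arange(height))
    xs = jj.ravel() + x0 + 0.5
    ys = ii.ravel() + y0 + 0.5
    shapely.prepare(poly)
    inside = shapely.contains_xy(poly, xs, ys)
    return inside.reshape(height, width)


@dataclass
class MaskRegion:
    """A single organ mask: a polygon outline, a binary raster, or both.

    The raster is stored over a local window whose top-left corner in the
    image frame is ``offset = (x0, y0)``; polygons are in full-image
    coordinates.  Whichever representation is missing is derived lazily.
    """

    polygon: np.ndarray | None = None          # (N, 2) float, (x, y)
    _raster: np.ndarray | None = None          # bool array, local window
    _offset: tuple[int, int] = (0, 0)          # (x0, y0) of the raster

    # -- constructors --------------------------------------------------
    @classmethod
    def from_polygon(cls, vertices: Sequence[Sequence[float]]) -> "MaskRegion":
        verts = np.asarray(vertices, dtype=float)
        if verts.ndim != 2 or verts.shape[1] != 2 or verts.shape[0] < 3:
            raise ValueError("polygon needs at least 3 (x, y) vertices")
        return cls(polygon=verts)

    @classmethod
    def from_raster(cls, raster: np.ndarray,
                    offset: tuple[int, int] = (0, 0)) -> "MaskRegion":
        raster = np.asarray(raster, dtype=bool)
        if raster.ndim != 2:
            raise ValueError("raster must be 2-D")
        return cls(polygon=None, _raster=raster, _offset=(int(offset[0]), int(offset[1])))

    # -- raster access -------------------------------------------------
    def _ensure_raster(self) -> None:
        if self._raster is None:
            v = self.polygon
            x0 = int(math.floor(v[:, 0].min()))
            y0 = int(math.floor(v[:, 1].min()))
            x1 = int(math.ceil(v[:, 0].max()))
            y1 = int(math.ceil(v[:, 1].max()))
            w = max(x1 - x0, 1)
            h = max(y1 - y0, 1)
            self._raster = rasterize_polygon(v, h, w, x0, y0)
            self._offset = (x0, y0)

    @property
    def raster(self) -> np.ndarray:
        """Binary mask over the local window (see :attr:`offset`)."""
        self._ensure_raster()
        return self._raster

    @property
    def offset(self) -> tuple[int, int]:
        self._ensure_raster()
        return self._offset

    # -- derived quantities --------------------------------------------
    @property
    def area(self) -> int:
        """Pixel count of the rasterized mask."""
        return int(self.raster.sum())

    @property
    def bbox(self) -> tuple[int, int, int, int]:
        """Tight bounding box ``(x, y, w, h)`` of the rasterized mask."""
        r = self.raster
        rows = np.flatnonzero(r.any(axis=1))
        cols = np.flatnonzero(r.any(axis=0))
        if rows.size == 0:
            return (self.offset[0], self.offset[1], 0, 0)
        x0, y0 = self.offset
        return (x0 + int(cols[0]), y0 + int(rows[0]),
                int(cols[-1] - cols[0] + 1), int(rows[-1] - rows[0] + 1))

    @property
    def max_side(self) -> int:
        """max(bbox width, height) — the size used for size binning."""
        _, _, w, h = self.bbox
        return max(w, h)

    def diagonal_px(self) -> float:
        """Diagonal length of the bounding box, in pixels."""
        _, _, w, h = self.bbox
        return math.hypot(w, h)

    # -- conversions ---------------------------------------------------
    def to_polygon(self) -> np.ndarray:
        """Polygon outline in image coordinates.

        For raster-only masks a marching-squares contour of the largest
        connected region is traced halfway between foreground and
        background pixel centers, which reproduces the raster exactly
        under the center-containment rule.
        """
        if self.polygon is not None:
            return self.polygon
        padded = np.pad(self._raster.astype(float), 1)
        contours = measure.find_contours(padded, 0.5)
        if not contours:
            raise ValueError("empty mask has no outline")
        contour = max(contours, key=len)  # outer boundary of largest region
        x0, y0 = self._offset
        # (row, col) in padded index space -> (x, y) image coords.  A padded
        # index (r, c) corresponds to raster pixel (r-1, c-1) whose center is
        # at image (x0 + c - 1 + 0.5, y0 + r - 1 + 0.5).
        xs = contour[:, 1] - 1 + 0.5 + x0
        ys = contour[:, 0] - 1 + 0.5 + y0
        verts = np.column_stack([xs, ys])
        if np.allclose(verts[0], verts[-1]):
            verts = verts[:-1]
        return verts

    def window_raster(self, x0: int, y0: int, width: int, height: int) -> np.ndarray:
        """Raster of this mask over an arbitrary window of the image frame."""
        out = np.zeros((height, width), dtype=bool)
        r = self.raster
        rx0, ry0 = self.offset
        # overlap of [rx0, rx0+rw) with [x0, x0+width)
        ax0 = max(rx0, x0)
        ay0 = max(ry0, y0)
        ax1 = min(rx0 + r.shape[1], x0 + width)
        ay1 = min(ry0 + r.shape[0], y0 + height)
        if ax1 > ax0 and ay1 > ay0:
            out[ay0 - y0:ay1 - y0, ax0 - x0:ax1 - x0] = \
                r[ay0 - ry0:ay1 - ry0, ax0 - rx0:ax1 - rx0]
        return out

    def scaled(self, sx: float, sy: float) -> "MaskRegion":
        """Mask scaled by per-axis factors (used when resizing sheets)."""
        verts = self.to_polygon().astype(float).copy()
        verts[:, 0] *= sx
        verts[:, 1] *= sy
        return MaskRegion.from_polygon(verts)


@dataclass
class OrganInstance:
    """One reproductive structure: category, mask, optional confidence.

    Ground-truth instances carry no score; predictions always do.
    """

    category: Category
    mask: MaskRegion
    score: float | None = None

    def __post_init__(self) -> None:
        if self.score is not None and not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score must lie in [0, 1], got {self.score}")


@dataclass
class SheetAnnotation:
    """All annotated instances on one herbarium sheet image."""

    image_id: str
    width: int
    height: int
    instances: list[OrganInstance] = field(default_factory=list)
    provenance: Provenance = Provenance.FULL

    def counts(self) -> dict[Category, int]:
        out = {c: 0 for c in Category}
        for inst in self.instances:
            out[inst.category] += 1
        return out

    def validate(self) -> None:
        """Enforce the type invariants; raises ValueError on violation."""
        for inst in self.instances:
            x, y, w, h = inst.mask.bbox
            if x < 0 or y < 0 or x + w > self.width or y + h > self.height:
                raise ValueError(
                    f"mask bbox {(x, y, w, h)} escapes image bounds "
                    f"{self.width}x{self.height} on sheet {self.image_id}")
            if self.provenance is Provenance.PREDICTED and inst.score is None:
                raise ValueError("predicted instances must carry a score")
            if self.provenance is not Provenance.PREDICTED and inst.score is not None:
                raise ValueError("ground-truth instances must not carry a score")
            if self.provenance is Provenance.POINTS and not (w <= 3 and h <= 3):
                raise ValueError("points provenance requires 3x3 (or clipped) masks")


@dataclass(frozen=True)
class ScaleCalibration:
    """Links pixel measurements to physical size.

    The default follows the study's digitization scale at which 100 px
    corresponds to 0.84 cm on the sheet.
    """

    cm_per_pixel: float = 0.0084

    def __post_init__(self) -> None:
        if not self.cm_per_pixel > 0:
            raise ValueError("cm_per_pixel must be positive")

    def to_cm(self, pixels: float) -> float:
        return pixels * self.cm_per_pixel

    def to_px(self, cm: float) -> float:
        return cm / self.cm_per_pixel


# ---------------------------------------------------------------------------
# COCO-dialect JSON I/O
# ---------------------------------------------------------------------------

def _category_entries() -> list[dict]:
    return [{"id": int(c), "name": c.label} for c in Category]


def read_annotations(path: str | Path) -> list[SheetAnnotation]:
    """Read a COCO-dialect JSON file into per-sheet annotations.

    The dialect has top-level ``images``, ``annotations`` and
    ``categories`` arrays; masks are polygons (flat ``[x1, y1, x2, y2,
    ...]`` lists).  Unknown category ids are a hard error; polygons with
    fewer than 3 vertices are rejected with a logged warning and parsing
    continues.
    """
    path = Path(path)
    with open(path) as fh:
        doc = json.load(fh)

    id_to_cat: dict[int, Category] = {}
    for entry in doc.get("categories", _category_entries()):
        cid = int(entry["id"])
        try:
            cat = Category(cid)
        except ValueError:
            raise ValueError(f"unknown category id {cid} in {path}") from None
        name = entry.get("name")
        if name is not None and name != cat.label:
            raise ValueError(
                f"category id {cid} named {name!r}, expected {cat.label!r}")
        id_to_cat[cid] = cat

    provenance = Provenance(doc.get("provenance", "full"))
    sheets: dict[int, SheetAnnotation] = {}
    for img in doc["images"]:
        sheets[int(img["id"])] = SheetAnnotation(
            image_id=str(img.get("file_name", img["id"])),
            width=int(img["width"]),
            height=int(img["height"]),
            provenance=provenance,
        )

    for ann in doc.get("annotations", []):
        image_id = int(ann["image_id"])
        if image_id not in sheets:
            raise ValueError(f"annotation {ann.get('id')} references "
                             f"unknown image id {image_id}")
        cid = int(ann["category_id"])
        if cid not in id_to_cat:
            raise ValueError(f"unknown category id {cid} in {path}")
        seg = ann["segmentation"]
        ring = seg[0] if seg and isinstance(seg[0], (list, tuple)) else seg
        verts = np.asarray(ring, dtype=float).reshape(-1, 2)
        if verts.shape[0] < 3:
            logger.warning("annotation %s: polygon with %d vertices rejected",
                           ann.get("id"), verts.shape[0])
            continue
        score = ann.get("score")
        sheets[image_id].instances.append(OrganInstance(
            category=id_to_cat[cid],
            mask=MaskRegion.from_polygon(verts),
            score=float(score) if score is not None else None,
        ))

    return [sheets[k] for k in sorted(sheets)]


def write_annotations(sheets: Iterable[SheetAnnotation], path: str | Path) -> None:
    """Write sheets to a COCO-dialect JSON file (polygons only)."""
    sheets = list(sheets)
    provenances = {s.provenance for s in sheets}
    if len(provenances) > 1:
        raise ValueError("all sheets in one file must share a provenance")
    doc: dict = {
        "images": [],
        "annotations": [],
        "categories": _category_entries(),
        "provenance": (provenances.pop().value if provenances else "full"),
    }
    ann_id = 1
    for img_idx, sheet in enumerate(sheets, start=1):
        doc["images"].append({
            "id": img_idx,
            "file_name": sheet.image_id,
            "width": sheet.width,
            "height": sheet.height,
        })
        for inst in sheet.instances:
            verts = inst.mask.to_polygon()
            entry = {
                "id": ann_id,
                "image_id": img_idx,
                "category_id": int(inst.category),
                "segmentation": [np.round(verts, 4).ravel().tolist()],
                "area": inst.mask.area,
                "bbox": list(inst.mask.bbox),
            }
            if inst.score is not None:
                entry["score"] = round(float(inst.score), 6)
            doc["annotations"].append(entry)
            ann_id += 1
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(doc, fh)


# ---------------------------------------------------------------------------
# Resizing
# ---------------------------------------------------------------------------

def resize_image_and_annotations(
    image: np.ndarray,
    sheet: SheetAnnotation,
    target_long_edge: int = 2048,
) -> tuple[np.ndarray, SheetAnnotation]:
    """Resize a sheet so its longest edge equals ``target_long_edge``.

    Aspect ratio is preserved; all mask coordinates are scaled with the
    same per-axis factors as the raster, so relative areas are preserved
    up to resampling.  Returns the resized image and a new annotation.
    """
    img = np.asarray(image)
    if img.size == 0:
        raise ValueError("cannot resize an empty image")
    h, w = img.shape[:2]
    if max(h, w) == target_long_edge:
        return img, sheet
    s = target_long_edge / max(h, w)
    new_w = target_long_edge if w >= h else max(1, round(w * s))
    new_h = target_long_edge if h > w else max(1, round(h * s))
    resized = np.asarray(
        Image.fromarray(img).resize((new_w, new_h), Image.BILINEAR))
    sx, sy = new_w / w, new_h / h
    out = SheetAnnotation(
        image_id=sheet.image_id, width=new_w, height=new_h,
        provenance=sheet.provenance,
        instances=[OrganInstance(i.category, i.mask.scaled(sx, sy), i.score)
                   for i in sheet.instances],
    )
    return resized, out
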