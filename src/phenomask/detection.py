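"""Pluggable instance-segmentation contract and a classical baseline.

The evaluation pipeline only requires an object implementing
:class:`Segmenter`: given an 8-bit RGB sheet image it returns a
:class:`~phenomask.annotations.SheetAnnotation` of scored, in-bounds
instances, deterministically for a fixed input and seed.  Any external
detector (e.g. a trained mask R-CNN) can be plugged in by exporting its
results to COCO-dialect JSON and wrapping them with
:class:`CocoResultsSegmenter`; no neural network is trained or run here.

:class:`BaselineSegmenter` is a classical reference implementation:
Otsu foreground/background split on luminance, connected components,
then a rule table over per-component shape and color features
(elongation separates capsule fruits from compact organs; hue separates
green immature from brown mature fruits and purple flowers from green
buds; area separates buds from flowers).  Scores are rule margins mapped
to [0, 1].  It is tuned for the synthetic sheet generator's regime and
serves to exercise the pipeline end-to-end without GPU training.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Protocol, runtime_checkable

import numpy as np
from scipy import ndimage
from skimage import color as skcolor
from skimage import measure

from .annotations import (
    Category,
    MaskRegion,
    OrganInstance,
    Provenance,
    SheetAnnotation,
    read_annotations,
)
from .maskgen import otsu_threshold, rgb_to_gray

__all__ = [
    "Segmenter",
    "BaselineConfig",
    "BaselineSegmenter",
    "CocoResultsSegmenter",
]


@runtime_checkable
class Segmenter(Protocol):
    """Contract every detector backend must satisfy."""

    def segment(self, image: np.ndarray, image_id: str = "image",
                seed: int = 0) -> SheetAnnotation: ...


@dataclass(frozen=True)
class BaselineConfig:
    """Decision thresholds of the rule-based baseline.

    Defaults were tuned once on the synthetic suite and frozen.  Hue is
    in [0, 1) HSV units: green organs sit near 0.2–0.45, purple flowers
    near 0.7–0.95, brown mature fruits near 0.04–0.16.
    """

    min_area: int = 30              # px², drop speckle components
    fruit_elongation: float = 3.0   # major/minor axis ratio separating capsules
    bud_max_area: int = 1300        # px², bud vs flower split for compact organs
    green_hue: tuple[float, float] = (0.17, 0.5)
    purple_hue: tuple[float, float] = (0.6, 0.97)
    brown_hue: tuple[float, float] = (0.0, 0.17)


def _in_band(h: float, band: tuple[float, float]) -> bool:
    return band[0] <= h < band[1]


def _band_margin(h: float, band: tuple[float, float]) -> float:
    """Distance of hue to the band edges, normalized to [0, 1]."""
    lo, hi = band
    half = (hi - lo) / 2
    return max(0.0, 1.0 - abs(h - (lo + half)) / half)


@dataclass
class BaselineSegmenter:
    """Classical Otsu + connected components + shape-rule detector."""

    config: BaselineConfig = BaselineConfig()

    def segment(self, image: np.ndarray, image_id: str = "image",
                seed: int = 0) -> SheetAnnotation:
        img = np.asarray(image)
        if img.ndim != 3 or img.shape[2] != 3:
            raise ValueError("segment() expects an 8-bit RGB image")
        height, width = img.shape[:2]
        sheet = SheetAnnotation(image_id=image_id, width=width, height=height,
                                provenance=Provenance.PREDICTED)
        gray = rgb_to_gray(img)
        res = otsu_threshold(gray)
        if res.degenerate:
            return sheet
        dark = gray <= res.threshold
        # organs are darker than mounting paper; guard against inverted sheets
        foreground = dark if dark.mean() <= 0.5 else ~dark
        labels, n_comp = ndimage.label(foreground,
                                       structure=np.ones((3, 3), dtype=int))
        if n_comp == 0:
            return sheet
        hsv = skcolor.rgb2hsv(img.astype(float) / 255.0)
        for prop in measure.regionprops(labels):
            if prop.area < self.config.min_area:
                continue
            mask_local = prop.image
            y0, x0 = prop.bbox[0], prop.bbox[1]
            hue = float(np.mean(hsv[..., 0][labels == prop.label]))
            minor = max(prop.axis_minor_length, 1.0)
            elong = prop.axis_major_length / minor
            cat, margin = self._classify(prop.area, elong, hue)
            score = 0.5 + 0.5 * min(max(margin, 0.0), 1.0)
            sheet.instances.append(OrganInstance(
                category=cat,
                mask=MaskRegion.from_raster(mask_local, offset=(x0, y0)),
                score=score))
        return sheet

    def _classify(self, area: float, elong: float,
                  hue: float) -> tuple[Category, float]:
        cfg = self.config
        if elong >= cfg.fruit_elongation:
            elong_margin = min((elong - cfg.fruit_elongation)
                               / cfg.fruit_elongation, 1.0)
            if _in_band(hue, cfg.green_hue):
                return (Category.IMMATURE_FRUIT,
                        0.5 * elong_margin + 0.5 * _band_margin(hue, cfg.green_hue))
            return (Category.MATURE_FRUIT,
                    0.5 * elong_margin + 0.5 * _band_margin(hue, cfg.brown_hue))
        if _in_band(hue, cfg.purple_hue):
            return Category.FLOWER, _band_margin(hue, cfg.purple_hue)
        if _in_band(hue, cfg.green_hue):
            if area <= cfg.bud_max_area:
                return (Category.BUD,
                        0.5 + 0.5 * min(1.0, (cfg.bud_max_area - area)
                                        / cfg.bud_max_area))
            return Category.FLOWER, 0.25
        # hue outside all bands: fall back on size
        return (Category.BUD, 0.1) if area <= cfg.bud_max_area \
            else (Category.FLOWER, 0.1)


@dataclass
class CocoResultsSegmenter:
    """Adapter exposing a COCO-dialect results file through the contract.

    Wraps the exported predictions of any external detector (one file,
    possibly many sheets); ``segment`` looks the sheet up by image id and
    ignores the pixel data.
    """

    results_path: str | Path

    def __post_init__(self) -> None:
        sheets = read_annotations(self.results_path)
        self._by_id = {s.image_id: s for s in sheets}
        for s in sheets:
            s.provenance = Provenance.PREDICTED
            s.validate()

    def segment(self, image: np.ndarray, image_id: str = "image",
                seed: int = 0) -> SheetAnnotation:
        if image_id not in self._by_id:
            raise KeyError(f"no predictions for image id {image_id!r}")
        return self._by_id[image_id]
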