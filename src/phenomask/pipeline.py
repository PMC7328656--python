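"""End-to-end pipeline: synthesize → derive annotation regimes → detect → evaluate.

One :class:`RunConfig` drives a deterministic run; artifacts (images,
annotation files, metric reports, a manifest with the config hash) land
in an output directory, so a run can be referenced and reproduced by its
config alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from . import __version__
from .annotations import ScaleCalibration, SheetAnnotation, write_annotations
from .detection import BaselineSegmenter, CocoResultsSegmenter, Segmenter
from .evaluation import MetricsReport, evaluate_sheets
from .maskgen import PointMarker, make_partial_mask, make_point_mask
from .synthetic import PerturbationModel, SheetRecipe, generate_suite, perturb_predictions
from .annotations import OrganInstance, Provenance

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "derive_marker_regimes"]


@dataclass(frozen=True)
class RunConfig:
    """All knobs of a pipeline run (values the study keeps fixed).

    ``detector`` selects the prediction source: ``baseline`` (the
    classical detector), ``identity`` (unperturbed copies of the ground
    truth — useful as a pipeline self-check), or ``coco:<path>`` to wrap
    an external detector's results file.
    """

    out_dir: str = "phenomask_run"
    seed: int = 0
    n_sheets: int = 4
    iou_threshold: float = 0.5
    score_threshold: float = 0.5
    cm_per_pixel: float = 0.0084
    window_size: int = 100
    target_long_edge: int = 2048
    detector: str = "baseline"
    render_images: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.iou_threshold <= 1 and 0 < self.score_threshold <= 1):
            raise ValueError("thresholds must lie in (0, 1]")
        if min(self.n_sheets, self.window_size, self.target_long_edge) <= 0:
            raise ValueError("sizes must be positive")

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def derive_marker_regimes(images: list[np.ndarray],
                          gt_sheets: list[SheetAnnotation],
                          window_size: int = 100,
                          ) -> tuple[list[SheetAnnotation], list[SheetAnnotation]]:
    """Derive point- and partial-mask annotation sets from full masks.

    Emulates the manual scoring protocol: one marker per organ placed at
    the top of its mask (the scorer marks near the distal extremity),
    then 3×3 point masks and Otsu partial masks around those markers.
    """
    points_sheets, partial_sheets = [], []
    for img, gt in zip(images, gt_sheets):
        markers = []
        for inst in gt.instances:
            r = inst.mask.raster
            x0, y0 = inst.mask.offset
            rows = np.flatnonzero(r.any(axis=1))
            top = rows[0]
            cols = np.flatnonzero(r[top])
            markers.append(PointMarker(x=x0 + int(cols[len(cols) // 2]),
                                       y=y0 + int(top) + 1,
                                       category=inst.category))
        dims = (gt.width, gt.height)
        points_sheets.append(SheetAnnotation(
            image_id=gt.image_id, width=gt.width, height=gt.height,
            provenance=Provenance.POINTS,
            instances=[OrganInstance(m.category, make_point_mask(m, dims))
                       for m in markers]))
        partial_sheets.append(SheetAnnotation(
            image_id=gt.image_id, width=gt.width, height=gt.height,
            provenance=Provenance.PARTIAL,
            instances=[OrganInstance(m.category,
                                     make_partial_mask(img, m, window_size))
                       for m in markers]))
    return points_sheets, partial_sheets


def _make_detector(config: RunConfig) -> Segmenter | None:
    if config.detector == "baseline":
        return BaselineSegmenter()
    if config.detector == "identity":
        return None
    if config.detector.startswith("coco:"):
        return CocoResultsSegmenter(config.detector[5:])
    raise ValueError(f"unknown detector {config.detector!r}")


def run_pipeline(config: RunConfig) -> MetricsReport:
    """Run the full pipeline and write all artifacts under ``out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("pipeline run %s -> %s", config.digest(), out)

    try:
        images, gt_sheets = generate_suite(config.n_sheets, config.seed,
                                           render=True)
    except Exception as exc:
        raise RuntimeError(f"stage 'synth' failed: {exc}") from exc
    write_annotations(gt_sheets, out / "ground_truth.json")
    if config.render_images:
        for img, sheet in zip(images, gt_sheets):
            Image.fromarray(img).save(out / f"{sheet.image_id}.png")

    try:
        points, partial = derive_marker_regimes(images, gt_sheets,
                                                config.window_size)
    except Exception as exc:
        raise RuntimeError(f"stage 'maskgen' failed: {exc}") from exc
    write_annotations(points, out / "points_masks.json")
    write_annotations(partial, out / "partial_masks.json")

    try:
        detector = _make_detector(config)
        if detector is None:     # identity predictions
            model = PerturbationModel(seed=config.seed)
            pred_sheets = [perturb_predictions(g, model) for g in gt_sheets]
        else:
            pred_sheets = [detector.segment(img, image_id=s.image_id,
                                            seed=config.seed)
                           for img, s in zip(images, gt_sheets)]
    except Exception as exc:
        raise RuntimeError(f"stage 'detect' failed: {exc}") from exc
    write_annotations(pred_sheets, out / "predictions.json")

    try:
        report = evaluate_sheets(
            gt_sheets, pred_sheets,
            iou_threshold=config.iou_threshold,
            score_threshold=config.score_threshold,
            calibration=ScaleCalibration(config.cm_per_pixel))
    except Exception as exc:
        raise RuntimeError(f"stage 'evaluate' failed: {exc}") from exc

    report.to_json(out / "report.json")
    report.to_csv_dir(out / "tables")
    (out / "summary.txt").write_text(report.summary_text() + "\n")
    manifest = {"version": __version__, "seed": config.seed,
                "config_hash": config.digest(),
                "config": dataclasses.asdict(config)}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return report
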