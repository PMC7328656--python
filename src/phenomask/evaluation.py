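"""Evaluation metrics for organ detection, counting and measurement.

Implements the full metric suite used to judge an instance-segmentation
model on herbarium sheets:

* **IoU matching** — predictions claim ground-truth instances one-to-one
  when their mask intersection-over-union exceeds a threshold (default
  0.5).  Matching is *category-agnostic*: geometric correspondence is
  established first, label correctness is judged afterwards by AP and
  the confusion matrix (otherwise cross-category confusions could never
  be observed).
* **Average precision (AP)** — rank-weighted precision
  ``AP = Σ_k P(k)·δ(ŷ_k = y_k) / N_gt`` over predictions of a category
  sorted by decreasing confidence, where P(k) is the precision over the
  top-k results and δ is 1 when the matched ground-truth label agrees.
* **Size-wise AP** — the same AP pooled over all categories, with
  ground-truth instances partitioned by max bounding-box side into
  Small (1–64 px), Medium (65–128 px) and Large (>128 px) bins.
* **Counting precision (CP)** — 100 × detected / true count per sheet
  and category (plus the buds_flowers and fruits metacategories); values
  above 100% flag overestimated counts.  No IoU matching is involved;
  predictions count when their score clears a threshold.
* **Confusion matrix** — row i, column j: probability that a
  ground-truth organ of category i is matched by a prediction of
  category j; rows need not sum to 1, the deficit is the misdetection
  probability.
* **Measurement statistics / precision (MP)** — organ size is the
  diagonal of the mask's bounding box converted to cm; MP is
  100 × mean predicted size / mean true size per sheet and category.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .annotations import (
    METACATEGORIES,
    Category,
    MaskRegion,
    ScaleCalibration,
    SheetAnnotation,
)

__all__ = [
    "SIZE_BINS",
    "SizeBin",
    "MatchPair",
    "MatchSet",
    "MetricsReport",
    "iou",
    "match_instances",
    "average_precision",
    "sizewise_ap",
    "counting_precision",
    "confusion_matrix",
    "measurement_statistics",
    "measurement_precision",
    "evaluate_sheets",
]


@dataclass(frozen=True)
class SizeBin:
    """A size class over max(bbox width, height) in pixels."""

    name: str
    lo: int            # inclusive
    hi: int | None     # inclusive; None = unbounded

    def contains(self, max_side: int) -> bool:
        return max_side >= self.lo and (self.hi is None or max_side <= self.hi)

    def cm_bounds(self, calibration: ScaleCalibration) -> tuple[float, float | None]:
        hi = None if self.hi is None else round(calibration.to_cm(self.hi), 2)
        return round(calibration.to_cm(self.lo), 2), hi


SIZE_BINS: tuple[SizeBin, ...] = (
    SizeBin("small", 1, 64),
    SizeBin("medium", 65, 128),
    SizeBin("large", 129, None),
)


# ---------------------------------------------------------------------------
# IoU and matching
# ---------------------------------------------------------------------------

def iou(a: MaskRegion, b: MaskRegion) -> float:
    """|A∩B| / |A∪B| of two rasterized masks in the same image frame."""
    area_a, area_b = a.area, b.area
    if area_a == 0 or area_b == 0:
        raise ValueError("IoU is undefined for a zero-area mask")
    ax, ay, aw, ah = a.bbox
    bx, by, bw, bh = b.bbox
    ix0, iy0 = max(ax, bx), max(ay, by)
    ix1, iy1 = min(ax + aw, bx + bw), min(ay + ah, by + bh)
    if ix1 <= ix0 or iy1 <= iy0:
        return 0.0
    w, h = ix1 - ix0, iy1 - iy0
    ra = a.window_raster(ix0, iy0, w, h)
    rb = b.window_raster(ix0, iy0, w, h)
    inter = int(np.logical_and(ra, rb).sum())
    return inter / (area_a + area_b - inter)


@dataclass(frozen=True)
class MatchPair:
    pred_idx: int
    gt_idx: int
    iou: float


@dataclass
class MatchSet:
    """One-to-one IoU-thresholded matching between predictions and ground truth.

    Predictions are processed in decreasing score order (ties: input
    order); each claims the still-unclaimed ground-truth instance with
    the highest IoU above the threshold (ties: lower ground-truth
    index).  Claims are category-agnostic.
    """

    pred: SheetAnnotation
    gt: SheetAnnotation
    iou_threshold: float = 0.5
    pairs: list[MatchPair] = field(default_factory=list)
    unmatched_pred: list[int] = field(default_factory=list)
    unmatched_gt: list[int] = field(default_factory=list)

    def gt_match(self, gt_idx: int) -> MatchPair | None:
        for p in self.pairs:
            if p.gt_idx == gt_idx:
                return p
        return None

    def pred_match(self, pred_idx: int) -> MatchPair | None:
        for p in self.pairs:
            if p.pred_idx == pred_idx:
                return p
        return None


def match_instances(pred: SheetAnnotation, gt: SheetAnnotation,
                    iou_threshold: float = 0.5) -> MatchSet:
    """Greedily match scored predictions to ground truth on one sheet."""
    if pred.image_id != gt.image_id:
        raise ValueError(f"image id mismatch: {pred.image_id!r} vs {gt.image_id!r}")
    ms = MatchSet(pred=pred, gt=gt, iou_threshold=iou_threshold)
    order = sorted(range(len(pred.instances)),
                   key=lambda i: (-(pred.instances[i].score or 0.0), i))
    claimed: set[int] = set()
    for pi in order:
        pmask = pred.instances[pi].mask
        px, py, pw, ph = pmask.bbox
        best_iou, best_gt = 0.0, -1
        for gi, ginst in enumerate(gt.instances):
            if gi in claimed:
                continue
            gx, gy, gw, gh = ginst.mask.bbox
            if px >= gx + gw or gx >= px + pw or py >= gy + gh or gy >= py + ph:
                continue
            v = iou(pmask, ginst.mask)
            if v > best_iou + 1e-12 or (v > 0 and math.isclose(v, best_iou)
                                        and gi < best_gt):
                best_iou, best_gt = v, gi
        if best_gt >= 0 and best_iou > iou_threshold:
            ms.pairs.append(MatchPair(pi, best_gt, best_iou))
            claimed.add(best_gt)
        else:
            ms.unmatched_pred.append(pi)
    ms.unmatched_gt = [gi for gi in range(len(gt.instances)) if gi not in claimed]
    return ms


def _as_matchsets(matches: MatchSet | Iterable[MatchSet]) -> list[MatchSet]:
    return [matches] if isinstance(matches, MatchSet) else list(matches)


# ---------------------------------------------------------------------------
# Average precision
# ---------------------------------------------------------------------------

def _ap_from_ranked(correct: Sequence[bool], n_gt: int) -> float:
    """AP = Σ_k P(k)·δ_k / N_gt over a ranked correctness sequence."""
    total, n_correct = 0.0, 0
    for k, ok in enumerate(correct, start=1):
        if ok:
            n_correct += 1
            total += n_correct / k
    return total / n_gt


def average_precision(matches: MatchSet | Iterable[MatchSet],
                      category: Category) -> float | None:
    """AP of one category at the match set's IoU threshold.

    Predictions of the category (across all sheets) are ranked by
    decreasing score; a rank is correct when the prediction geometrically
    matched a ground-truth instance of the same category.  Returns None
    when the category has no ground-truth instances.
    """
    matchsets = _as_matchsets(matches)
    n_gt = sum(1 for ms in matchsets for inst in ms.gt.instances
               if inst.category is category)
    if n_gt == 0:
        return None
    ranked: list[tuple[float, int, bool]] = []
    for si, ms in enumerate(matchsets):
        for pi, pinst in enumerate(ms.pred.instances):
            if pinst.category is not category:
                continue
            pair = ms.pred_match(pi)
            ok = (pair is not None
                  and ms.gt.instances[pair.gt_idx].category is category)
            ranked.append((-(pinst.score or 0.0), si * 10 ** 6 + pi, ok))
    ranked.sort()
    return _ap_from_ranked([ok for _, _, ok in ranked], n_gt)


def sizewise_ap(matches: MatchSet | Iterable[MatchSet],
                bins: Sequence[SizeBin] = SIZE_BINS) -> dict[str, float | None]:
    """AP per size bin, all categories pooled.

    Ground-truth instances are binned by max bounding-box side.  A
    prediction is ranked in the bin of its matched ground-truth instance
    when matched, else in the bin of its own size; a rank is correct
    when matched with agreeing category.  Bins without ground truth get
    None.
    """
    matchsets = _as_matchsets(matches)
    out: dict[str, float | None] = {}
    for b in bins:
        n_gt = sum(1 for ms in matchsets for inst in ms.gt.instances
                   if b.contains(inst.mask.max_side))
        if n_gt == 0:
            out[b.name] = None
            continue
        ranked: list[tuple[float, int, bool]] = []
        for si, ms in enumerate(matchsets):
            for pi, pinst in enumerate(ms.pred.instances):
                pair = ms.pred_match(pi)
                if pair is not None:
                    ginst = ms.gt.instances[pair.gt_idx]
                    if not b.contains(ginst.mask.max_side):
                        continue
                    ok = ginst.category is pinst.category
                else:
                    if not b.contains(pinst.mask.max_side):
                        continue
                    ok = False
                ranked.append((-(pinst.score or 0.0), si * 10 ** 6 + pi, ok))
        ranked.sort()
        out[b.name] = _ap_from_ranked([ok for _, _, ok in ranked], n_gt)
    return out


# ---------------------------------------------------------------------------
# Counting precision
# ---------------------------------------------------------------------------

def counting_precision(pred_count: int, true_count: int) -> float | None:
    """CP = 100 × detected / true; >100% means the count is overestimated.

    Returns None when there is nothing to count (true_count = 0).
    """
    if true_count < 0 or pred_count < 0:
        raise ValueError("counts must be non-negative")
    if true_count == 0:
        return None
    return 100.0 * pred_count / true_count


def _counts_table(pred: SheetAnnotation, gt: SheetAnnotation,
                  score_threshold: float) -> dict[str, tuple[int, int]]:
    """(detected, true) counts per category and metacategory on one sheet."""
    gc = gt.counts()
    pc = {c: 0 for c in Category}
    for inst in pred.instances:
        if inst.score is None or inst.score >= score_threshold:
            pc[inst.category] += 1
    out = {c.label: (pc[c], gc[c]) for c in Category}
    for name, cats in METACATEGORIES.items():
        out[name] = (sum(pc[c] for c in cats), sum(gc[c] for c in cats))
    out["all"] = (sum(pc.values()), sum(gc.values()))
    return out


# ---------------------------------------------------------------------------
# Confusion matrix
# ---------------------------------------------------------------------------

def confusion_matrix(matches: MatchSet | Iterable[MatchSet]) -> pd.DataFrame:
    """Detection/confusion probabilities with a misdetection column.

    Entry (i, j): fraction of ground-truth instances of category i whose
    matched prediction carries category j (with one-to-one matching each
    ground-truth instance has at most one — its best-scoring — match).
    Rows sum to ≤ 1; the deficit is the misdetection probability,
    reported in the ``misdetection`` column.  Categories without ground
    truth get a NaN row.
    """
    matchsets = _as_matchsets(matches)
    labels = [c.label for c in Category]
    counts = pd.DataFrame(0.0, index=labels, columns=labels)
    n_gt = {c: 0 for c in Category}
    for ms in matchsets:
        for gi, ginst in enumerate(ms.gt.instances):
            n_gt[ginst.category] += 1
            pair = ms.gt_match(gi)
            if pair is not None:
                pcat = ms.pred.instances[pair.pred_idx].category
                counts.loc[ginst.category.label, pcat.label] += 1
    for c in Category:
        if n_gt[c] == 0:
            counts.loc[c.label] = np.nan
        else:
            counts.loc[c.label] /= n_gt[c]
    counts["misdetection"] = 1.0 - counts[labels].sum(axis=1)
    counts.loc[[c.label for c in Category if n_gt[c] == 0], "misdetection"] = np.nan
    return counts


# ---------------------------------------------------------------------------
# Size measurement
# ---------------------------------------------------------------------------

def instance_size_cm(mask: MaskRegion, calibration: ScaleCalibration) -> float:
    """Organ size: diagonal of the mask's bounding box, in cm."""
    return calibration.to_cm(mask.diagonal_px())


def measurement_statistics(
    gt_sheets: Sequence[SheetAnnotation],
    pred_sheets: Sequence[SheetAnnotation],
    calibration: ScaleCalibration = ScaleCalibration(),
) -> pd.DataFrame:
    """Quartile summaries of organ sizes (cm), ground truth vs predictions.

    One row per (category, source) with n, min, q1, median, q3, max and
    mean of the bounding-box-diagonal sizes.
    """
    rows = []
    for source, sheets in (("ground_truth", gt_sheets), ("predicted", pred_sheets)):
        sizes: dict[Category, list[float]] = {c: [] for c in Category}
        for sheet in sheets:
            for inst in sheet.instances:
                sizes[inst.category].append(instance_size_cm(inst.mask, calibration))
        for c in Category:
            vals = np.asarray(sizes[c])
            if vals.size:
                q1, med, q3 = np.percentile(vals, [25, 50, 75])
                rows.append({"category": c.label, "source": source,
                             "n": vals.size, "min": vals.min(), "q1": q1,
                             "median": med, "q3": q3, "max": vals.max(),
                             "mean": vals.mean()})
            else:
                rows.append({"category": c.label, "source": source, "n": 0,
                             "min": np.nan, "q1": np.nan, "median": np.nan,
                             "q3": np.nan, "max": np.nan, "mean": np.nan})
    return pd.DataFrame(rows)


def measurement_precision(gt_sizes: Sequence[float],
                          pred_sizes: Sequence[float]) -> float | None:
    """MP = 100 × mean predicted size / mean true size.

    >100% means the true average size is overestimated.  Returns None
    when either list is empty.
    """
    if len(gt_sizes) == 0 or len(pred_sizes) == 0:
        return None
    return 100.0 * float(np.mean(pred_sizes)) / float(np.mean(gt_sizes))


# ---------------------------------------------------------------------------
# Full report
# ---------------------------------------------------------------------------

@dataclass
class MetricsReport:
    """All evaluation metrics over a sheet set.

    ``counting`` and ``mp`` are per-sheet tables (rows: sheets, columns:
    categories/metacategories, values: percent or NaN); ``ap`` and
    ``sizewise`` are per-category / per-bin AP values; ``confusion`` is
    the 4×4 probability matrix plus misdetection column; ``size_stats``
    summarizes size distributions in cm.
    """

    counting: pd.DataFrame
    ap: dict[str, float | None]
    sizewise: dict[str, float | None]
    confusion: pd.DataFrame
    size_stats: pd.DataFrame
    mp: pd.DataFrame
    iou_threshold: float = 0.5
    score_threshold: float = 0.5
    calibration: ScaleCalibration = ScaleCalibration()

    def mean_cp(self, column: str = "all") -> float:
        return float(self.counting[column].dropna().mean())

    def mean_mp(self, column: str = "all") -> float:
        return float(self.mp[column].dropna().mean())

    def to_dict(self) -> dict:
        return {
            "iou_threshold": self.iou_threshold,
            "score_threshold": self.score_threshold,
            "cm_per_pixel": self.calibration.cm_per_pixel,
            "counting_precision": json_safe(self.counting.to_dict()),
            "average_precision": json_safe(self.ap),
            "sizewise_ap": json_safe(self.sizewise),
            "confusion_matrix": json_safe(self.confusion.to_dict()),
            "measurement_statistics": json_safe(
                self.size_stats.to_dict(orient="records")),
            "measurement_precision": json_safe(self.mp.to_dict()),
        }

    def to_json(self, path) -> None:
        import json
        from pathlib import Path
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def to_csv_dir(self, directory) -> None:
        from pathlib import Path
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.counting.to_csv(d / "counting_precision.csv")
        pd.Series(self.ap, name="ap").to_csv(d / "average_precision.csv")
        pd.Series(self.sizewise, name="ap").to_csv(d / "sizewise_ap.csv")
        self.confusion.to_csv(d / "confusion_matrix.csv")
        self.size_stats.to_csv(d / "measurement_statistics.csv", index=False)
        self.mp.to_csv(d / "measurement_precision.csv")

    def summary_text(self) -> str:
        lines = [
            f"Evaluation summary (IoU > {self.iou_threshold:.0%}, "
            f"score >= {self.score_threshold}, "
            f"{self.calibration.cm_per_pixel} cm/px)",
            "",
            "Counting precision, mean over sheets (100% = exact count):",
        ]
        for col in self.counting.columns:
            vals = self.counting[col].dropna()
            if len(vals):
                lines.append(f"  {col:16s} {vals.mean():6.1f}%")
        lines.append("")
        lines.append("Average precision (AP at IoU > 50%):")
        for k, v in self.ap.items():
            lines.append(f"  {k:16s} {'  n/a' if v is None else f'{v:5.3f}'}")
        lines.append("")
        lines.append("Size-wise AP (max bbox side: small 1-64 px, "
                     "medium 65-128 px, large >128 px):")
        for k, v in self.sizewise.items():
            lines.append(f"  {k:16s} {'  n/a' if v is None else f'{v:5.3f}'}")
        lines.append("")
        lines.append("Measurement precision, mean over sheets "
                     "(100% = exact mean size):")
        for col in self.mp.columns:
            vals = self.mp[col].dropna()
            if len(vals):
                lines.append(f"  {col:16s} {vals.mean():6.1f}%")
        return "\n".join(lines)


def json_safe(obj):
    """Recursively convert NaN to None and numpy scalars to Python ones."""
    if isinstance(obj, dict):
        return {str(k): json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [json_safe(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (float, np.floating)):
        f = float(obj)
        return None if math.isnan(f) else f
    return obj


def evaluate_sheets(
    gt_sheets: Sequence[SheetAnnotation],
    pred_sheets: Sequence[SheetAnnotation],
    iou_threshold: float = 0.5,
    score_threshold: float = 0.5,
    calibration: ScaleCalibration = ScaleCalibration(),
) -> MetricsReport:
    """Run the full metric suite on paired ground-truth/prediction sheets.

    Sheets are paired by ``image_id``; every ground-truth sheet must have
    a prediction sheet (possibly empty).
    """
    preds = {s.image_id: s for s in pred_sheets}
    missing = [s.image_id for s in gt_sheets if s.image_id not in preds]
    if missing:
        raise ValueError(f"no predictions for sheets: {missing}")

    matchsets = [match_instances(preds[g.image_id], g, iou_threshold)
                 for g in gt_sheets]

    # counting precision per sheet
    cp_rows, mp_rows = {}, {}
    for g in gt_sheets:
        table = _counts_table(preds[g.image_id], g, score_threshold)
        cp_rows[g.image_id] = {k: counting_precision(p, t)
                               for k, (p, t) in table.items()}
    counting = pd.DataFrame.from_dict(cp_rows, orient="index").astype(float)

    # measurement precision per sheet
    for g in gt_sheets:
        p = preds[g.image_id]
        row = {}
        groups = {c.label: (c,) for c in Category} | METACATEGORIES
        groups["all"] = tuple(Category)
        for name, cats in groups.items():
            gt_sizes = [instance_size_cm(i.mask, calibration)
                        for i in g.instances if i.category in cats]
            pr_sizes = [instance_size_cm(i.mask, calibration)
                        for i in p.instances if i.category in cats
                        and (i.score is None or i.score >= score_threshold)]
            row[name] = measurement_precision(gt_sizes, pr_sizes)
        mp_rows[g.image_id] = row
    mp = pd.DataFrame.from_dict(mp_rows, orient="index").astype(float)

    ap = {c.label: average_precision(matchsets, c) for c in Category}
    sw = sizewise_ap(matchsets)
    conf = confusion_matrix(matchsets)
    stats = measurement_statistics(gt_sheets, [preds[g.image_id] for g in gt_sheets],
                                   calibration)
    return MetricsReport(counting=counting, ap=ap, sizewise=sw, confusion=conf,
                         size_stats=stats, mp=mp, iou_threshold=iou_threshold,
                         score_threshold=score_threshold, calibration=calibration)
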