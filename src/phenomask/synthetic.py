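"""Synthetic herbarium sheets with exact ground-truth masks.

Real annotated herbarium material is scarce, so this module renders
sheet-like images whose ground truth is known by construction: procedural
organ shapes (ellipse buds, lobed-disc flowers, curved thin capsules for
immature fruits, broader capsules for mature fruits) placed on a
paper-colored background.  Shapes are not photorealistic — the evaluation
layer only needs masks with controllable geometry, category, size and
color — but their size ranges deliberately span the Small/Medium/Large
detection bins and their elongation/hue separate the four categories the
way real organs do (fruits long and thin; buds small and compact;
flowers mid-sized and differently colored).

A :class:`PerturbationModel` turns ground truth into synthetic
"predictions" with analytically known miss rate, false-alarm rate,
label-swap matrix and mask jitter, so every evaluation metric can be
checked against closed-form expectations.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence`` spawning, making every fixture
byte-reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .annotations import (
    Category,
    MaskRegion,
    OrganInstance,
    Provenance,
    SheetAnnotation,
    write_annotations,
)

__all__ = [
    "SheetRecipe",
    "PerturbationModel",
    "CATEGORY_COLORS",
    "TABLE1_TRAIN_COUNTS",
    "TABLE1_TEST_COUNTS",
    "generate_sheet",
    "generate_suite",
    "generate_fixture_table1",
    "perturb_predictions",
]

#: Base RGB color per category; buds and immature fruits share the green
#: family (separated by elongation), flowers are purple, mature fruits brown.
CATEGORY_COLORS: dict[Category, tuple[int, int, int]] = {
    Category.BUD: (58, 104, 48),
    Category.FLOWER: (150, 62, 158),
    Category.IMMATURE_FRUIT: (92, 138, 58),
    Category.MATURE_FRUIT: (132, 92, 40),
}

PAPER_COLOR = (235, 228, 210)

#: Per-category totals of the study's training and test annotation sets.
TABLE1_TRAIN_COUNTS: dict[Category, int] = {
    Category.BUD: 279, Category.FLOWER: 349,
    Category.IMMATURE_FRUIT: 196, Category.MATURE_FRUIT: 212,
}
TABLE1_TEST_COUNTS: dict[Category, int] = {
    Category.BUD: 168, Category.FLOWER: 299,
    Category.IMMATURE_FRUIT: 110, Category.MATURE_FRUIT: 101,
}
TABLE1_TRAIN_SHEETS = 21
TABLE1_TEST_SHEETS = 10


@dataclass(frozen=True)
class SheetRecipe:
    """Parameters of one synthetic sheet.

    Default counts follow the per-category proportions of the study's
    training set scaled to a typical sheet (~50 structures).  Shape
    parameter ranges (px): bud ellipse axes 10–40 with elongation ≤ 2;
    flower disc+petals 30–90 overall; immature fruit capsule length
    60–250, width 6–14; mature fruit capsule length 120–360, width 8–18.
    ``min_gap`` keeps rendered organs separated so ground-truth masks
    never overlap (pairwise IoU 0).
    """

    width: int = 1024
    height: int = 2048
    counts: dict[Category, int] = field(default_factory=lambda: {
        Category.BUD: 13, Category.FLOWER: 17,
        Category.IMMATURE_FRUIT: 9, Category.MATURE_FRUIT: 10,
    })
    min_gap: int = 8
    seed: int = 0
    image_id: str = "sheet_0"


@dataclass(frozen=True)
class PerturbationModel:
    """Stochastic corruption of ground truth into synthetic predictions.

    ``miss`` — per-category probability of dropping an instance;
    ``false_alarm_rate`` — expected number of spurious detections per
    sheet (Poisson); ``swap`` — 4×4 row-stochastic label-confusion
    matrix indexed by (true, predicted) category order; ``jitter_radius``
    — disk radius (px) by which surviving masks are dilated, plus
    ``boundary_noise`` probability of flipping boundary pixels.

    Scores: surviving detections draw from a beta variate mapped into
    [0.55, 1] (concentrated near 1), false alarms from one mapped into
    [0.5, 0.7) (concentrated near 0.5), so every prediction clears the
    default 0.5 counting threshold while detections still outrank false
    alarms in expectation.  With the identity settings (no miss, no
    false alarms, identity swap, zero jitter) the perturbation is the
    identity map on geometry and labels, modulo scores.
    """

    miss: dict[Category, float] = field(
        default_factory=lambda: {c: 0.0 for c in Category})
    false_alarm_rate: float = 0.0
    swap: np.ndarray = field(default_factory=lambda: np.eye(4))
    jitter_radius: int = 0
    boundary_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        sw = np.asarray(self.swap, dtype=float)
        if sw.shape != (4, 4) or not np.allclose(sw.sum(axis=1), 1.0):
            raise ValueError("swap must be a 4x4 row-stochastic matrix")
        object.__setattr__(self, "swap", sw)
        for c, p in self.miss.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"miss probability for {c} out of [0,1]")


# ---------------------------------------------------------------------------
# Procedural organ shapes (local boolean masks)
# ---------------------------------------------------------------------------

def _ellipse_mask(a: float, b: float, theta: float) -> np.ndarray:
    """Filled rotated ellipse with semi-axes a, b (local window)."""
    r = int(np.ceil(max(a, b))) + 1
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1].astype(float)
    ct, st = np.cos(theta), np.sin(theta)
    u = xx * ct + yy * st
    v = -xx * st + yy * ct
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _disc_stamp(mask: np.ndarray, cy: float, cx: float, radius: float) -> None:
    r = int(np.ceil(radius))
    y0, y1 = int(np.floor(cy)) - r, int(np.floor(cy)) + r + 1
    x0, x1 = int(np.floor(cx)) - r, int(np.floor(cx)) + r + 1
    y0c, x0c = max(y0, 0), max(x0, 0)
    y1c, x1c = min(y1, mask.shape[0]), min(x1, mask.shape[1])
    if y1c <= y0c or x1c <= x0c:
        return
    yy, xx = np.mgrid[y0c:y1c, x0c:x1c].astype(float)
    mask[y0c:y1c, x0c:x1c] |= (yy - cy) ** 2 + (xx - cx) ** 2 <= radius ** 2


def _bud_mask(rng: np.random.Generator) -> np.ndarray:
    a = rng.uniform(5, 20)                     # semi-axes -> 10-40 px extent
    b = rng.uniform(max(5.0, a / 2), a)        # elongation <= 2
    return _trim(_ellipse_mask(a, b, rng.uniform(0, np.pi)))


def _flower_mask(rng: np.random.Generator) -> np.ndarray:
    overall = rng.uniform(30, 90)              # target overall extent, px
    r_disc = overall * rng.uniform(0.18, 0.25)
    n_petals = rng.integers(4, 7)
    petal_r = overall / 2 - r_disc
    size = int(np.ceil(overall)) + 3
    mask = np.zeros((size, size), dtype=bool)
    c = size / 2
    _disc_stamp(mask, c, c, r_disc)
    phase = rng.uniform(0, 2 * np.pi)
    for k in range(n_petals):
        ang = phase + 2 * np.pi * k / n_petals
        dist = r_disc + petal_r * 0.55
        _disc_stamp(mask, c + dist * np.sin(ang), c + dist * np.cos(ang),
                    petal_r * 0.55)
    return _trim(mask)


def _capsule_mask(rng: np.random.Generator, length: float,
                  width: float) -> np.ndarray:
    """Thin curved capsule: discs stamped along a quadratic arc."""
    sag = length * rng.uniform(0.02, 0.12)     # arc height (curvature)
    theta = rng.uniform(0, np.pi)
    n = max(int(length), 8)
    t = np.linspace(-0.5, 0.5, n)
    xs = t * length
    ys = sag * (1 - (2 * t) ** 2) - sag / 2
    ct, st = np.cos(theta), np.sin(theta)
    xr = xs * ct - ys * st
    yr = xs * st + ys * ct
    pad = width + 2
    size_y = int(np.ceil(yr.max() - yr.min() + 2 * pad))
    size_x = int(np.ceil(xr.max() - xr.min() + 2 * pad))
    mask = np.zeros((size_y, size_x), dtype=bool)
    for px, py in zip(xr - xr.min() + pad, yr - yr.min() + pad):
        _disc_stamp(mask, py, px, width / 2)
    return _trim(mask)


def _immature_fruit_mask(rng: np.random.Generator) -> np.ndarray:
    return _capsule_mask(rng, rng.uniform(60, 250), rng.uniform(6, 14))


def _mature_fruit_mask(rng: np.random.Generator) -> np.ndarray:
    return _capsule_mask(rng, rng.uniform(120, 360), rng.uniform(8, 18))


_SHAPE_BUILDERS = {
    Category.BUD: _bud_mask,
    Category.FLOWER: _flower_mask,
    Category.IMMATURE_FRUIT: _immature_fruit_mask,
    Category.MATURE_FRUIT: _mature_fruit_mask,
}


def _trim(mask: np.ndarray) -> np.ndarray:
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    return mask[rows[0]:rows[-1] + 1, cols[0]:cols[-1] + 1]


def random_organ_mask(rng: np.random.Generator,
                      category: Category) -> np.ndarray:
    """Local boolean mask of one procedurally generated organ."""
    return _SHAPE_BUILDERS[category](rng)


# ---------------------------------------------------------------------------
# Sheet assembly
# ---------------------------------------------------------------------------

def _place_instances(rng: np.random.Generator, recipe: SheetRecipe,
                     ) -> list[OrganInstance]:
    """Sample shapes and non-overlapping placements for one sheet."""
    shapes: list[tuple[Category, np.ndarray]] = []
    for cat, n in recipe.counts.items():
        if n < 0:
            raise ValueError("counts must be non-negative")
        for _ in range(n):
            shapes.append((cat, random_organ_mask(rng, cat)))
    order = rng.permutation(len(shapes))       # interleave categories
    shapes = [shapes[i] for i in order]
    # place large shapes first: greatly improves packing feasibility
    shapes.sort(key=lambda s: -max(s[1].shape))

    occupied: list[tuple[int, int, int, int]] = []   # (x0, y0, x1, y1) + gap
    instances: list[OrganInstance] = []
    gap = recipe.min_gap
    for cat, m in shapes:
        h, w = m.shape
        if w >= recipe.width or h >= recipe.height:
            raise ValueError(
                f"organ of size {w}x{h} cannot fit on a "
                f"{recipe.width}x{recipe.height} sheet")
        placed = False
        for _ in range(400):
            x0 = int(rng.integers(0, recipe.width - w))
            y0 = int(rng.integers(0, recipe.height - h))
            box = (x0 - gap, y0 - gap, x0 + w + gap, y0 + h + gap)
            if all(box[2] <= ox0 or ox2 <= box[0] or box[3] <= oy0 or oy3 <= box[1]
                   for ox0, oy0, ox2, oy3 in occupied):
                occupied.append(box)
                instances.append(OrganInstance(
                    category=cat,
                    mask=MaskRegion.from_raster(m, offset=(x0, y0))))
                placed = True
                break
        if not placed:
            raise ValueError(
                f"infeasible packing: could not place a {w}x{h} {cat.label} "
                f"after 400 attempts on a {recipe.width}x{recipe.height} sheet "
                f"holding {len(instances)} organs")
    return instances


def generate_sheet(recipe: SheetRecipe, render: bool = True,
                   ) -> tuple[np.ndarray | None, SheetAnnotation]:
    """Generate one sheet: RGB image (optional) plus exact ground truth.

    Deterministic for a fixed recipe (including its seed).  With
    ``render=False`` only the annotation is produced, which is much
    faster for metric-only studies.
    """
    if recipe.width < 256 or recipe.height < 256:
        raise ValueError("sheet dimensions must be at least 256 px")
    rng = np.random.default_rng(np.random.SeedSequence(recipe.seed))
    instances = _place_instances(rng, recipe)
    sheet = SheetAnnotation(image_id=recipe.image_id, width=recipe.width,
                            height=recipe.height, instances=instances,
                            provenance=Provenance.FULL)
    if not render:
        return None, sheet

    img = np.empty((recipe.height, recipe.width, 3), dtype=float)
    img[:] = PAPER_COLOR
    img += rng.normal(0, 3, size=img.shape)
    for inst in instances:
        color = np.asarray(CATEGORY_COLORS[inst.category], dtype=float)
        color = color + rng.normal(0, 6, size=3)          # per-instance tint
        m = inst.mask.raster
        x0, y0 = inst.mask.offset
        region = img[y0:y0 + m.shape[0], x0:x0 + m.shape[1]]
        noise = rng.normal(0, 4, size=(int(m.sum()), 3))
        region[m] = color + noise
    return np.clip(np.round(img), 0, 255).astype(np.uint8), sheet


def generate_suite(n_sheets: int, seed: int, recipe: SheetRecipe = SheetRecipe(),
                   render: bool = True,
                   ) -> tuple[list[np.ndarray | None], list[SheetAnnotation]]:
    """Generate a suite of sheets with per-sheet seeds spawned from ``seed``."""
    seeds = np.random.SeedSequence(seed).generate_state(n_sheets) % (2 ** 31)
    images, sheets = [], []
    for i in range(n_sheets):
        r = replace(recipe, seed=int(seeds[i]), image_id=f"sheet_{i}")
        img, sheet = generate_sheet(r, render=render)
        images.append(img)
        sheets.append(sheet)
    return images, sheets


# ---------------------------------------------------------------------------
# Table-1-shaped fixtures
# ---------------------------------------------------------------------------

def _allocate(rng: np.random.Generator, total: int, n_sheets: int) -> np.ndarray:
    """Random seeded split of ``total`` instances over ``n_sheets`` sheets."""
    return rng.multinomial(total, np.full(n_sheets, 1.0 / n_sheets))


def _fixture_sheets(rng: np.random.Generator, totals: dict[Category, int],
                    n_sheets: int, prefix: str) -> list[SheetAnnotation]:
    alloc = {c: _allocate(rng, n, n_sheets) for c, n in totals.items()}
    sheets = []
    for i in range(n_sheets):
        counts = {c: int(alloc[c][i]) for c in totals}
        recipe = SheetRecipe(counts=counts,
                             seed=int(rng.integers(0, 2 ** 31)),
                             image_id=f"{prefix}_{i}")
        _, sheet = generate_sheet(recipe, render=False)
        sheets.append(sheet)
    return sheets


def generate_fixture_table1(out_dir: str | Path | None = None, seed: int = 0,
                            ) -> tuple[list[SheetAnnotation], list[SheetAnnotation]]:
    """Annotation fixtures matching the study's data-set composition.

    Training fixture: per-category totals (279, 349, 196, 212) spread
    over 21 sheets; test fixture: (168, 299, 110, 101) over 10 sheets.
    The per-sheet allocation is random but seeded.  When ``out_dir`` is
    given, writes ``table1_train.json`` and ``table1_test.json`` there.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x7AB1]))
    train = _fixture_sheets(rng, TABLE1_TRAIN_COUNTS, TABLE1_TRAIN_SHEETS, "train")
    test = _fixture_sheets(rng, TABLE1_TEST_COUNTS, TABLE1_TEST_SHEETS, "test")
    if out_dir is not None:
        out = Path(out_dir)
        write_annotations(train, out / "table1_train.json")
        write_annotations(test, out / "table1_test.json")
    return train, test


# ---------------------------------------------------------------------------
# Perturbation into synthetic predictions
# ---------------------------------------------------------------------------

def _detection_score(rng: np.random.Generator) -> float:
    return float(1.0 - 0.45 * rng.beta(2, 5))          # in (0.55, 1]


def _false_alarm_score(rng: np.random.Generator) -> float:
    return float(0.5 + 0.2 * rng.beta(2, 5))           # in [0.5, 0.7)


def _jitter_mask(rng: np.random.Generator, mask: MaskRegion,
                 radius: int, boundary_noise: float,
                 width: int, height: int) -> MaskRegion:
    """Dilate a mask by a disk of ``radius`` px and add boundary noise."""
    if radius <= 0 and boundary_noise <= 0:
        return mask
    r = mask.raster
    x0, y0 = mask.offset
    pad = radius + 1
    grown = np.pad(r, pad)
    if radius > 0:
        yy, xx = np.mgrid[-radius:radius + 1, -radius:radius + 1]
        disk = xx ** 2 + yy ** 2 <= radius ** 2
        grown = ndimage.binary_dilation(grown, structure=disk)
    if boundary_noise > 0:
        boundary = grown & ~ndimage.binary_erosion(grown)
        flips = boundary & (rng.random(grown.shape) < boundary_noise)
        core = ndimage.binary_erosion(grown)
        grown = (grown & ~flips) | core
    out = MaskRegion.from_raster(grown, offset=(x0 - pad, y0 - pad))
    # clip to image bounds
    clipped = out.window_raster(0, 0, width, height)
    return MaskRegion.from_raster(clipped, offset=(0, 0))


def perturb_predictions(gt: SheetAnnotation,
                        model: PerturbationModel) -> SheetAnnotation:
    """Corrupt ground truth into scored predictions with known statistics.

    Each ground-truth instance is independently dropped with its
    category's miss probability; survivors keep their geometry (jittered
    when configured), draw a new label from the swap matrix row of their
    true category, and get a detection score.  False alarms — random
    organ shapes of uniform random category with low scores — are added
    at a Poisson rate per sheet.
    """
    rng = np.random.default_rng(np.random.SeedSequence(
        [model.seed, zlib.crc32(gt.image_id.encode()) % (2 ** 31)]))
    cats = list(Category)
    preds: list[OrganInstance] = []
    for inst in gt.instances:
        if rng.random() < model.miss.get(inst.category, 0.0):
            continue
        row = model.swap[cats.index(inst.category)]
        new_cat = cats[int(rng.choice(4, p=row))]
        mask = _jitter_mask(rng, inst.mask, model.jitter_radius,
                            model.boundary_noise, gt.width, gt.height)
        preds.append(OrganInstance(category=new_cat, mask=mask,
                                   score=_detection_score(rng)))
    n_fa = int(rng.poisson(model.false_alarm_rate))
    for _ in range(n_fa):
        cat = cats[int(rng.integers(0, 4))]
        m = random_organ_mask(rng, cat)
        h, w = m.shape
        if w >= gt.width or h >= gt.height:
            continue
        x0 = int(rng.integers(0, gt.width - w))
        y0 = int(rng.integers(0, gt.height - h))
        preds.append(OrganInstance(
            category=cat, mask=MaskRegion.from_raster(m, offset=(x0, y0)),
            score=_false_alarm_score(rng)))
    return SheetAnnotation(image_id=gt.image_id, width=gt.width,
                           height=gt.height, instances=preds,
                           provenance=Provenance.PREDICTED)
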