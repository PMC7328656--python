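# phenomask

Tools for the fine-grained detection, counting and measurement of plant
reproductive structures — flower buds, flowers, immature fruits and
mature fruits — on digitized herbarium sheets.

Herbarium collections hold centuries of pressed specimens whose
reproductive state encodes phenology: when and how intensely a species
flowered and fruited. Scoring that state by hand (counting every bud,
flower and fruit on a sheet) does not scale to millions of digitized
specimens, so instance-segmentation models are trained to do it. This
package implements everything *around* such a model:

* **Annotation regimes.** Manual scoring workflows record one point
  marker per organ. `phenomask` turns markers into the three training
  regimes used in practice: 3×3-pixel *point masks*; *partial masks*
  obtained by Otsu thresholding inside a 100×100-pixel window around
  each marker (at the working scale of 0.0084 cm/px, 100 px ≈ 0.84 cm);
  and validated hand-drawn *full masks*. Sheets are resized so the
  longest edge is 2048 px, and annotations are read and written in a
  COCO-dialect JSON (polygon masks, categories `bud`, `flower`,
  `immature_fruit`, `mature_fruit`).
* **A pluggable segmentation contract.** Any detector that outputs
  scored masks can be evaluated — wrap an external model's COCO results
  file with `CocoResultsSegmenter`, or use the built-in classical
  baseline (Otsu foreground split → connected components → shape/color
  rules) to run the pipeline end to end without a GPU.
* **The evaluation metric suite.** For predictions *vs* ground truth:
  - **Counting precision** CP = 100 × detected/true per sheet and
    category (plus the `buds_flowers` and `fruits` metacategories);
    CP > 100% flags overcounting.
  - **Average precision** at IoU > 50%,
    `AP = Σₖ P(k)·δ(ŷₖ = yₖ) / N_gt`, where predictions of a category
    are ranked by decreasing confidence, P(k) is the precision over the
    top-k, δ marks label agreement with the matched ground-truth
    instance, and N_gt is the number of true instances.
  - **Size-wise AP** with instances binned by maximum bounding-box side:
    Small 1–64 px (≤ 0.54 cm), Medium 65–128 px (≤ 1.08 cm), Large
    > 128 px.
  - **Detection/confusion matrix**: P(true category i detected as
    category j); rows sum to ≤ 1, the deficit is the misdetection
    probability.
  - **Measurement statistics and precision**: organ size is the
    bounding-box diagonal in cm; MP = 100 × mean predicted size / mean
    true size.
* **A synthetic sheet generator** producing herbarium-like images with
  exact ground truth, Table-style dataset fixtures (1036 training + 678
  test instances over 21 + 10 sheets), and a perturbation model (miss
  rate, false alarms, label swaps, mask jitter) whose metric
  expectations are known in closed form — the basis of the test suite.

## Worked example

Generate a sheet, corrupt its ground truth with known parameters and
read them back (condensed from `examples/04_evaluate_metrics.py`):

```python
import numpy as np
from phenomask import (Category, PerturbationModel, SheetRecipe,
                       evaluate_sheets, generate_sheet, perturb_predictions)

sheets = [generate_sheet(SheetRecipe(seed=s, image_id=f"s{s}"),
                         render=False)[1] for s in range(6)]
swap = np.eye(4); swap[1, 1], swap[1, 0] = 0.8, 0.2   # flower -> bud, 20%
model = PerturbationModel(miss={c: 0.2 for c in Category}, swap=swap, seed=1)
report = evaluate_sheets(sheets, [perturb_predictions(s, model) for s in sheets])
print(report.summary_text())
```

prints (excerpt):

```
Counting precision, mean over sheets (100% = exact count):
  bud               101.3%
  flower             68.6%
  ...
  all                81.6%
```

The overall CP of 81.6% reflects the 20% miss rate (each organ survives
with probability 0.8); flower CP falls further because one in five
detected flowers is relabeled as a bud, which in turn pushes bud CP
above 100%. The confusion matrix shows the swap directly: entry
(flower, bud) ≈ 0.16 = 0.8 × 0.2.

The `examples/` directory has one short script per capability:
sheet generation, annotation regimes, baseline detection, metric
evaluation and the one-call pipeline.

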