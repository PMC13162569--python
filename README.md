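# colposeg

Dataset engineering and evaluation toolkit for multi-class semantic
segmentation of colposcopy images.

Colposcopy triages positive cervical-cancer screening results by magnified
inspection of the cervix across staining stages (saline, acetic acid,
Lugol's solution). Training per-class segmentation models on annotated
colposcopy archives raises a set of data-engineering problems that have
nothing to do with the network architecture and everything to do with the
annotations: brush masks arrive run-length encoded in two dialects (CVAT
XML and COCO JSON); squamous epithelium forms annular "donut" masks whose
interior hole a naive polygon export destroys; findings scatter over
disconnected components; tiny fragments pollute label files; image quality
tags, mixed resolutions, and per-class background images all shape the
training set; and evaluation must aggregate per-image pixel metrics and
instance-level detection quality into comparable summaries. `colposeg`
implements that pipeline as a reusable, fully tested library, with the
neural models themselves treated as pluggable external predictors.

## What it computes

**Pixel metrics** per image and class, from confusion counts TP/FP/FN over
pixels, with ε = 1e-8 added to denominators so empty masks score 0:

    Dice      = 2TP / (2TP + FP + FN)        IoU    = TP / (TP + FP + FN)
    Precision = TP / (TP + FP)               Recall = TP / (TP + FN)

Class summaries report **mean (median) ± SD** (sample SD) over per-image
records, the convention used in clinical segmentation tables.

**Instance metrics**: mask mAP50-95 (greedy confidence-ordered matching,
101-point interpolated AP, IoU thresholds 0.50…0.95), instance F1 at
IoU 0.5 and the best confidence cutoff, and the composite tuning objective

    0.7 × F1 + 0.3 × mAP50-95

used to drive hyperparameter search for one-class segmentation models.

**Geometry**: hierarchical contour extraction from binary masks,
Douglas–Peucker simplification, discarding of contours below 30 px of
enclosed area, donut-shape merging via a zero-width connector bridge
between nearest vertex pairs, connected-component splitting, and
normalization of polygon vertices to [0, 1] — plus the even-odd
pixel-center rasterizer that inverts all of it.

**Curation**: quality-tag and two-most-common-resolution filtering,
general/extended class variants with seeded general and "difficult"
background injection, 70/20/10 train/val/test splits at image or patient
granularity, and export to YOLO-seg label files and per-subset COCO JSON.

## Worked example

Vectorizing an annular epithelium mask without losing its hole
(`examples/vectorize_donut.py`):

```python
import numpy as np
from colposeg import BinaryMask, mask_to_instances, rasterize

mask = np.zeros((100, 100), dtype=bool)
mask[20:60, 20:60] = True      # 40x40 epithelium ring ...
mask[35:45, 35:45] = False     # ... with a 10x10 empty interior
poly = mask_to_instances(BinaryMask(mask), "Squamous epithelium")[0]
back = rasterize(poly, 100, 100)
```

prints

```
ring foreground:        1500 px (1600 outer - 100 hole)
polygon vertices:       10 (normalized to [0, 1])
rasterized foreground:  1500 px
hole pixels re-filled:  0
```

All 1500 ring pixels survive the round trip and the hole stays empty: the
connector bridge joining outer boundary and hole has zero area under the
even-odd fill rule. The other scripts in `examples/` walk through dataset
curation (`build_dataset.py`), evaluation of imperfect predictions
(`evaluate_predictions.py`) and CVAT↔COCO conversion
(`annotation_roundtrip.py`).

A thin CLI wraps the same functions: `colposeg synth | convert | build |
evaluate` (see `colposeg --help`).

## Scope

The toolkit handles annotations and evaluation only: no model training or
inference, no hyperparameter search loop (only its objective function), no
image augmentation, and no photorealistic image synthesis — fixture scenes
are flat-shaded shapes with exactly known ground truth.
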