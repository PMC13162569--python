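"""Curate a per-class dataset from synthetic scenes and export it.

Filters out unusable images, keeps the squamous-epithelium class in its
extended (metaplastic-only) variant with difficult backgrounds, splits
70/20/10 and writes YOLO-seg label files plus per-subset COCO JSON.
"""

import tempfile
from collections import Counter
from pathlib import Path

from colposeg import (
    FilterPolicy,
    VariantSpec,
    build_class_dataset,
    export_coco,
    export_yolo_labels,
    filter_images,
    split,
)
from colposeg.fixtures import SceneSpec, StructureSpec, generate_scenes

specs = [
    SceneSpec(
        seed=i,
        structures=(
            StructureSpec("ellipse-cervix"),
            StructureSpec(
                "ring-epithelium",
                attributes={"epithelium type": "metaplastic" if i % 3 else "original"},
            ),
        ),
        tags=("High quality image",) if i != 5 else ("Unusable image",),
        patient_id=f"P{i % 4}",
    )
    for i in range(20)
]
_, annotations = generate_scenes(specs)

usable = filter_images(annotations, FilterPolicy())
print(f"images after quality/resolution filtering: {len(usable.images)} of 20")

spec = VariantSpec(
    "Squamous epithelium",
    variant="extended",
    attribute_key="epithelium type",
    attribute_value="metaplastic",
    background_count_difficult=2,
)
dataset = build_class_dataset(usable, spec, seed=7)
positives = sum(1 for im in dataset.images if im.shapes)
print(f"class dataset: {positives} positives + "
      f"{len(dataset.images) - positives} difficult backgrounds")

manifest = split(dataset, seed=7, group_key="patient")
print(f"patient-level split: {dict(Counter(manifest.assignment.values()))}")

out = Path(tempfile.mkdtemp()) / "epithelium_metaplastic"
export_yolo_labels(dataset, manifest, None, out)
export_coco(dataset, manifest, out)
n_labels = len(list(out.rglob("*.txt")))
print(f"exported {n_labels} label files under {out}")
# Background images get empty label files on purpose: they teach a
# one-class model what the class does NOT look like.
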