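"""COCO 1.0 JSON dialect: reader and writer.

Segmentations are accepted as polygon lists, uncompressed RLE (``counts`` as
a list) or compressed RLE (``counts`` as a string); polygons are rasterized
with the toolkit's even-odd pixel-center rule.  The writer emits
uncompressed RLE and is deterministic (images ordered by id, annotations by
image then shape order, sorted JSON keys), so repeated calls are
byte-identical.

Whole-image tags and patient ids have no native COCO slot; they travel in
the toolkit's ``tags`` / ``patient_id`` image fields, and class attributes
in the annotation-level ``attributes`` dict (as CVAT's own COCO export
does).
"""

from __future__ import annotations

import json
from typing import Optional

import numpy as np

from . import geometry, rle
from .model import (
    AnnotationSet,
    BinaryMask,
    ColposegError,
    ImageRecord,
    LabelEntry,
    LabelVocabulary,
    MaskShape,
    RlePayload,
    TagRecord,
)


class ReferentialError(ColposegError):
    """An annotation references a missing image or category id."""


def _decode_segmentation(seg, width: int, height: int) -> BinaryMask:
    """Any COCO segmentation form -> BinaryMask."""
    if isinstance(seg, dict):
        counts = seg["counts"]
        h, w = seg["size"]
        if isinstance(counts, str):
            runs = rle.decompress_counts(counts)
        else:
            runs = tuple(int(c) for c in counts)
        return rle.decode(RlePayload(runs, None, "coco-uncompressed"), w, h)
    if isinstance(seg, list):  # list of flat polygons, absolute pixel coords
        arr = np.zeros((height, width), dtype=bool)
        for flat in seg:
            pts = np.asarray(flat, dtype=float).reshape(-1, 2)
            arr ^= geometry.rasterize_path(pts, width, height)
        return BinaryMask(arr)
    raise ColposegError(f"unsupported segmentation form: {type(seg).__name__}")


def parse_coco(document: str, vocabulary: Optional[LabelVocabulary] = None) -> AnnotationSet:
    """Parse a COCO 1.0 JSON document into an :class:`AnnotationSet`.

    All segmentations are normalized to whole-frame uncompressed RLE, so two
    documents describing the same pixel sets parse to equivalent sets.
    """
    data = json.loads(document)
    if vocabulary is None:
        entries = []
        for cat in sorted(data.get("categories", []), key=lambda c: c["id"]):
            attrs = {
                k: tuple(v) for k, v in (cat.get("attributes") or {}).items()
            }
            entries.append(
                LabelEntry(cat.get("supercategory") or "findings", cat["name"], attrs)
            )
        vocabulary = LabelVocabulary(entries) if entries else LabelVocabulary.default()
    cat_names = {c["id"]: c["name"] for c in data.get("categories", [])}

    images: dict[int, ImageRecord] = {}
    for im in sorted(data.get("images", []), key=lambda i: i["id"]):
        tags = [TagRecord(t["category"], t["value"]) for t in im.get("tags", [])]
        images[im["id"]] = ImageRecord(
            image_id=im["id"],
            file_name=im.get("file_name", f"{im['id']}.png"),
            width_px=im["width"],
            height_px=im["height"],
            tags=tags,
            patient_id=im.get("patient_id"),
        )
    for ann in data.get("annotations", []):
        if ann["image_id"] not in images:
            raise ReferentialError(f"annotation references missing image id {ann['image_id']}")
        if ann["category_id"] not in cat_names:
            raise ReferentialError(
                f"annotation references missing category id {ann['category_id']}"
            )
        record = images[ann["image_id"]]
        mask = _decode_segmentation(
            ann["segmentation"], record.width_px, record.height_px
        )
        payload = rle.encode(mask, "coco-uncompressed")
        record.shapes.append(
            MaskShape(
                class_name=cat_names[ann["category_id"]],
                payload=payload,
                attributes=dict(ann.get("attributes") or {}),
                image_id=record.image_id,
            )
        )
    return AnnotationSet(vocabulary, list(images.values()))


def write_coco(aset: AnnotationSet) -> str:
    """Emit COCO 1.0 JSON; deterministic inverse of :func:`parse_coco`."""
    categories = []
    cat_ids: dict[str, int] = {}
    for i, entry in enumerate(aset.vocabulary, start=1):
        cat_ids[entry.class_name] = i
        cat = {"id": i, "name": entry.class_name, "supercategory": entry.category}
        if entry.attributes:
            cat["attributes"] = {k: list(v) for k, v in entry.attributes.items()}
        categories.append(cat)

    images = []
    annotations = []
    ann_id = 1
    for im in sorted(aset.images, key=lambda i: i.image_id):
        rec = {
            "id": im.image_id,
            "file_name": im.file_name,
            "width": im.width_px,
            "height": im.height_px,
        }
        if im.tags:
            rec["tags"] = [{"category": t.category, "value": t.value} for t in im.tags]
        if im.patient_id is not None:
            rec["patient_id"] = im.patient_id
        images.append(rec)
        for shape in im.shapes:
            mask = rle.decode(shape.payload, im.width_px, im.height_px)
            payload = rle.encode(mask, "coco-uncompressed")
            rows, cols = np.nonzero(mask.membership)
            bbox = (
                [float(cols.min()), float(rows.min()),
                 float(cols.max() - cols.min() + 1), float(rows.max() - rows.min() + 1)]
                if rows.size
                else [0.0, 0.0, 0.0, 0.0]
            )
            ann = {
                "id": ann_id,
                "image_id": im.image_id,
                "category_id": cat_ids[shape.class_name],
                "segmentation": {
                    "size": [im.height_px, im.width_px],
                    "counts": list(payload.runs),
                },
                "area": mask.foreground_count,
                "bbox": bbox,
                "iscrowd": 0,
            }
            if shape.attributes:
                ann["attributes"] = dict(shape.attributes)
            annotations.append(ann)
            ann_id += 1
    doc = {
        "info": {"description": "colposeg export", "version": "1.0"},
        "licenses": [],
        "images": images,
        "categories": categories,
        "annotations": annotations,
    }
    return json.dumps(doc, sort_keys=True, indent=1)
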