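"""CVAT-for-Images 1.1 XML dialect: reader and writer.

The reader preserves every image, tag, brush-mask shape and attribute.  Mask
payloads are kept run-length encoded exactly as exported (comma-separated
runs anchored at the shape's bounding box, background run first).  The
label vocabulary is read from ``meta/task/labels`` when present, otherwise
the default colposcopy taxonomy applies; unknown labels warn (default) or
fail depending on ``on_unknown``.
"""

from __future__ import annotations

import logging
from typing import Optional

from lxml import etree

from .model import (
    AnnotationSet,
    ColposegError,
    ImageRecord,
    LabelEntry,
    LabelVocabulary,
    MaskShape,
    RlePayload,
    TagRecord,
    VocabularyError,
)
from . import taxonomy

logger = logging.getLogger(__name__)


class AnnotationParseError(ColposegError):
    """The document is not a well-formed annotation export."""


def _default_category(class_name: str) -> str:
    for cat, name, _ in taxonomy.default_vocabulary_entries():
        if name == class_name:
            return cat
    return "findings"


def _register_unknown(
    vocab: LabelVocabulary, class_name: str, on_unknown: str
) -> LabelVocabulary:
    if on_unknown == "fail":
        raise VocabularyError(f"mask references unknown label: {class_name!r}")
    logger.warning("unknown label %r added to vocabulary", class_name)
    return LabelVocabulary(
        list(vocab.entries) + [LabelEntry(_default_category(class_name), class_name)]
    )


def parse_cvat_xml(
    document: str,
    vocabulary: Optional[LabelVocabulary] = None,
    on_unknown: str = "warn",
) -> AnnotationSet:
    """Parse a CVAT-for-Images 1.1 export into an :class:`AnnotationSet`."""
    try:
        root = etree.fromstring(document.encode("utf-8"))
    except etree.XMLSyntaxError as exc:
        raise AnnotationParseError(
            f"malformed XML at line {exc.lineno}: {exc.msg}"
        ) from exc

    vocab = vocabulary
    label_nodes = root.findall("meta/task/labels/label")
    if vocab is None:
        if label_nodes:
            entries = []
            for node in label_nodes:
                name = node.findtext("name", "").strip()
                category = node.findtext("category", "").strip() or _default_category(name)
                attrs = {}
                for attr in node.findall("attributes/attribute"):
                    values = tuple(
                        v for v in (attr.findtext("values") or "").splitlines() if v
                    )
                    attrs[attr.findtext("name", "").strip()] = values
                entries.append(LabelEntry(category, name, attrs))
            vocab = LabelVocabulary(entries)
        else:
            vocab = LabelVocabulary.default()

    images: list[ImageRecord] = []
    for node in root.iter("image"):
        image_id = int(node.get("id"))
        width = int(node.get("width"))
        height = int(node.get("height"))
        tags = []
        shapes = []
        for child in node:
            if child.tag == "tag":
                value = child.get("label", "")
                try:
                    tags.append(TagRecord.from_value(value))
                except VocabularyError:
                    logger.warning("unknown tag %r ignored", value)
            elif child.tag == "mask":
                label = child.get("label", "")
                if label not in vocab:
                    vocab = _register_unknown(vocab, label, on_unknown)
                runs = tuple(
                    int(tok) for tok in (child.get("rle") or "").replace(" ", "").split(",") if tok
                )
                box = (
                    int(child.get("left")),
                    int(child.get("top")),
                    int(child.get("width")),
                    int(child.get("height")),
                )
                attributes = {
                    a.get("name"): (a.text or "") for a in child.findall("attribute")
                }
                shapes.append(
                    MaskShape(
                        class_name=label,
                        payload=RlePayload(runs, box, "cvat-bbox"),
                        attributes=attributes,
                        image_id=image_id,
                    )
                )
            elif child.tag not in ("box", "polygon", "polyline", "points"):
                logger.warning("unknown element %r ignored", child.tag)
        images.append(
            ImageRecord(
                image_id=image_id,
                file_name=node.get("name", f"{image_id}.png"),
                width_px=width,
                height_px=height,
                tags=tags,
                shapes=shapes,
                patient_id=node.get("patient_id"),
            )
        )
    return AnnotationSet(vocab, images)


def write_cvat(aset: AnnotationSet) -> str:
    """Emit a CVAT-for-Images 1.1 document; inverse of :func:`parse_cvat_xml`."""
    root = etree.Element("annotations")
    etree.SubElement(root, "version").text = "1.1"
    labels = etree.SubElement(
        etree.SubElement(etree.SubElement(root, "meta"), "task"), "labels"
    )
    for entry in aset.vocabulary:
        label = etree.SubElement(labels, "label")
        etree.SubElement(label, "name").text = entry.class_name
        etree.SubElement(label, "category").text = entry.category
        if entry.attributes:
            attrs = etree.SubElement(label, "attributes")
            for key, values in entry.attributes.items():
                attr = etree.SubElement(attrs, "attribute")
                etree.SubElement(attr, "name").text = key
                etree.SubElement(attr, "values").text = "\n".join(values)
    for im in sorted(aset.images, key=lambda i: i.image_id):
        node = etree.SubElement(
            root,
            "image",
            id=str(im.image_id),
            name=im.file_name,
            width=str(im.width_px),
            height=str(im.height_px),
        )
        if im.patient_id is not None:
            node.set("patient_id", im.patient_id)
        for tag in im.tags:
            etree.SubElement(node, "tag", label=tag.value, source="manual")
        for shape in im.shapes:
            if shape.payload.dialect != "cvat-bbox":
                raise ColposegError(
                    "CVAT export requires cvat-bbox payloads; re-encode first"
                )
            left, top, w, h = shape.payload.anchor_box
            mask = etree.SubElement(
                node,
                "mask",
                label=shape.class_name,
                source="manual",
                occluded="0",
                rle=", ".join(str(r) for r in shape.payload.runs),
                left=str(left),
                top=str(top),
                width=str(w),
                height=str(h),
                z_order="0",
            )
            for key, value in shape.attributes.items():
                attr = etree.SubElement(mask, "attribute", name=key)
                attr.text = value
    return etree.tostring(
        root, pretty_print=True, xml_declaration=True, encoding="utf-8"
    ).decode("utf-8")
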