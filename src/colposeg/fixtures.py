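"""Seeded synthetic scenes with the structures the pipeline must survive.

Real colposcopy data cannot be shared, so every capability is exercised on
generated scenes carrying the same structural hazards: a large elliptical
cervix, a ring of squamous epithelium with an empty interior (the
"donut-shape" that breaks naive polygon export), thin small medical
instruments, and findings scattered over several disconnected components.
Rasters are flat-shaded — the toolkit tests geometry and metrics, not
perception.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from skimage import draw as skdraw
from skimage import morphology

from . import rle
from .cvat import write_cvat  # re-export: fixture emitter for CVAT roundtrips
from .metrics import InstancePrediction
from .model import AnnotationSet, BinaryMask, ImageRecord, LabelVocabulary, MaskShape, TagRecord

__all__ = [
    "SceneSpec",
    "StructureSpec",
    "PerturbSpec",
    "generate_scene",
    "generate_scenes",
    "perturb_predictions",
    "write_cvat",
]

STRUCTURE_KINDS = ("ellipse-cervix", "ring-epithelium", "small-instrument", "multi-blob-lesion")

_DEFAULT_CLASS = {
    "ellipse-cervix": "Cervix",
    "ring-epithelium": "Squamous epithelium",
    "small-instrument": "Medical instruments",
    "multi-blob-lesion": "Erythroplakia",
}

_COLOR = {
    "ellipse-cervix": (205, 120, 120),
    "ring-epithelium": (235, 200, 190),
    "small-instrument": (160, 160, 170),
    "multi-blob-lesion": (180, 60, 60),
}


@dataclass(frozen=True)
class StructureSpec:
    kind: str
    class_name: Optional[str] = None
    attributes: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in STRUCTURE_KINDS:
            raise ValueError(f"unknown structure kind {self.kind!r}")

    @property
    def label(self) -> str:
        return self.class_name or _DEFAULT_CLASS[self.kind]


@dataclass(frozen=True)
class SceneSpec:
    seed: int = 0
    width_px: int = 160
    height_px: int = 120
    structures: tuple[StructureSpec, ...] = ()
    tags: tuple[str, ...] = ()
    patient_id: Optional[str] = None


@dataclass(frozen=True)
class PerturbSpec:
    seed: int = 0
    dilate_px: int = 0
    erode_px: int = 0
    shift: tuple[int, int] = (0, 0)  # (dx, dy) px
    drop_probability: float = 0.0
    confidence_base: float = 1.0
    confidence_jitter: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.drop_probability <= 1.0:
            raise ValueError("drop_probability must be in [0, 1]")


# ---------------------------------------------------------------------------
# drawing


def _draw_structure(spec: StructureSpec, shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    h, w = shape
    mask = np.zeros(shape, dtype=bool)
    p = spec.params
    if spec.kind == "ellipse-cervix":
        r = p.get("center_row", h // 2)
        c = p.get("center_col", w // 2)
        rr, cc = skdraw.ellipse(
            r, c, p.get("radius_row", h // 3), p.get("radius_col", w // 3), shape=shape
        )
        mask[rr, cc] = True
    elif spec.kind == "ring-epithelium":
        # axis-aligned rectangles give exact pixel-count arithmetic
        top = p.get("top", h // 4)
        left = p.get("left", w // 4)
        ow, oh = p.get("outer", (min(40, w // 2), min(40, h // 2)))
        hw, hh = p.get("hole", (max(ow // 4, 1), max(oh // 4, 1)))
        mask[top : top + oh, left : left + ow] = True
        ht = top + (oh - hh) // 2
        hl = left + (ow - hw) // 2
        mask[ht : ht + hh, hl : hl + hw] = False
    elif spec.kind == "small-instrument":
        top = p.get("top", int(rng.integers(0, max(h - 40, 1))))
        left = p.get("left", int(rng.integers(0, max(w - 6, 1))))
        length = p.get("length", 40)
        thickness = p.get("thickness", 3)
        mask[top : top + length, left : left + thickness] = True
    elif spec.kind == "multi-blob-lesion":
        n = p.get("n_blobs", 3)
        radius = p.get("radius", 6)
        for _ in range(n):
            r = int(rng.integers(radius, h - radius))
            c = int(rng.integers(radius, w - radius))
            rr, cc = skdraw.disk((r, c), radius, shape=shape)
            mask[rr, cc] = True
    return mask


def generate_scene(spec: SceneSpec) -> tuple[np.ndarray, AnnotationSet]:
    """Draw one scene; deterministic given the spec's seed.

    Returns the flat-shaded RGB raster and an AnnotationSet whose mask pixel
    sets exactly match the drawn structures (overlaps resolved by draw
    order, later structures on top).
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height_px, spec.width_px
    image = np.full((h, w, 3), 40, dtype=np.uint8)
    vocab = LabelVocabulary.default()
    drawn: list[np.ndarray] = []
    for sspec in spec.structures:
        m = _draw_structure(sspec, (h, w), rng)
        for prev in drawn:
            prev &= ~m  # later structures occlude earlier ones
        drawn.append(m)
        image[m] = _COLOR[sspec.kind]
    # encode only after every occlusion has been applied
    shapes = [
        MaskShape(
            class_name=sspec.label,
            payload=rle.encode(BinaryMask(m), "cvat-bbox"),
            attributes=dict(sspec.attributes),
            image_id=0,
        )
        for sspec, m in zip(spec.structures, drawn)
        if m.any()
    ]
    record = ImageRecord(
        image_id=0,
        file_name=f"scene_{spec.seed}.png",
        width_px=w,
        height_px=h,
        tags=[TagRecord.from_value(t) for t in spec.tags],
        shapes=shapes,
        patient_id=spec.patient_id,
    )
    return image, AnnotationSet(vocab, [record])


def generate_scenes(specs: Sequence[SceneSpec]) -> tuple[list[np.ndarray], AnnotationSet]:
    """Generate several scenes into one AnnotationSet (image ids 0..n-1)."""
    images, records = [], []
    vocab = LabelVocabulary.default()
    for i, spec in enumerate(specs):
        raster, aset = generate_scene(spec)
        rec = aset.images[0]
        rec.image_id = i
        rec.file_name = f"scene_{i:04d}.png"
        for s in rec.shapes:
            s.image_id = i
        images.append(raster)
        records.append(rec)
    return images, AnnotationSet(vocab, records)


# ---------------------------------------------------------------------------
# prediction perturbation


def _shift(mask: np.ndarray, dx: int, dy: int) -> np.ndarray:
    out = np.zeros_like(mask)
    h, w = mask.shape
    src = mask[
        max(0, -dy) : h - max(0, dy),
        max(0, -dx) : w - max(0, dx),
    ]
    out[max(0, dy) : max(0, dy) + src.shape[0], max(0, dx) : max(0, dx) + src.shape[1]] = src
    return out


def perturb_predictions(gt: AnnotationSet, spec: PerturbSpec) -> list[InstancePrediction]:
    """Derive predictions from ground truth by seeded shift/dilate/erode/drop.

    Zero perturbation returns pixel-exact copies at confidence 1.0.
    """
    rng = np.random.default_rng(spec.seed)
    preds: list[InstancePrediction] = []
    for im in gt.images:
        for shape in im.shapes:
            if rng.random() < spec.drop_probability:
                continue
            arr = rle.decode(shape.payload, im.width_px, im.height_px).membership
            if spec.shift != (0, 0):
                arr = _shift(arr, *spec.shift)
            if spec.dilate_px:
                arr = morphology.binary_dilation(
                    arr, morphology.footprint_rectangle((2 * spec.dilate_px + 1,) * 2)
                )
            if spec.erode_px:
                arr = morphology.binary_erosion(
                    arr, morphology.footprint_rectangle((2 * spec.erode_px + 1,) * 2)
                )
            conf = spec.confidence_base
            if spec.confidence_jitter:
                conf += float(rng.uniform(-spec.confidence_jitter, spec.confidence_jitter))
            preds.append(
                InstancePrediction(
                    image_id=im.image_id,
                    class_name=shape.class_name,
                    mask=BinaryMask(arr),
                    confidence=float(np.clip(conf, 0.0, 1.0)),
                )
            )
    return preds
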