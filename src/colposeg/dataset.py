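"""Per-class dataset curation: filtering, variants, splits, export.

The curation workflow mirrors how single-class segmentation models are
trained on multi-stage colposcopy archives: unusable and low-quality images
are rejected, the two most common resolutions are kept, annotation-free
images are dropped; each class yields a *general* dataset (attributes
collapsed) or an *extended* one (a single attribute value as the label),
optionally padded with seeded background images — images without the class
("general" backgrounds) or with the class under a different attribute value
("difficult" backgrounds).  Datasets split 70/20/10 into train/val/test at
image or patient granularity, and export as YOLO-seg polygon label files
plus per-subset COCO JSON.
"""

from __future__ import annotations

import dataclasses
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from . import coco as coco_io
from . import geometry, rle
from .model import AnnotationSet, ColposegError, ImageRecord

DEFAULT_PROPORTIONS = (0.70, 0.20, 0.10)
SUBSETS = ("train", "val", "test")


class SplitError(ColposegError):
    """The requested split cannot be formed (e.g. missing patient ids)."""


@dataclass(frozen=True)
class FilterPolicy:
    rejected_quality_tags: frozenset[str] = frozenset({"Unusable image", "Low quality image"})
    allowed_stage_tags: Optional[frozenset[str]] = None
    resolution_policy: str = "keep-two-most-common"  # | "keep-all" | "explicit"
    explicit_resolutions: tuple[tuple[int, int], ...] = ()
    drop_unannotated: bool = True


@dataclass(frozen=True)
class VariantSpec:
    class_name: str
    variant: str = "general"  # | "extended"
    attribute_key: Optional[str] = None
    attribute_value: Optional[str] = None
    background_count_general: int = 0
    background_count_difficult: int = 0

    def __post_init__(self) -> None:
        if self.variant not in ("general", "extended"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.variant == "extended" and (self.attribute_key is None or self.attribute_value is None):
            raise ValueError("extended variant requires attribute_key and attribute_value")
        if self.variant == "general" and self.background_count_difficult:
            raise ValueError("difficult backgrounds exist only in the extended variant")


@dataclass
class SplitManifest:
    assignment: dict[int, str]  # image_id -> subset
    proportions: tuple[float, float, float]
    seed: int
    group_key: str = "image"

    def ids(self, subset: str) -> list[int]:
        return [i for i, s in self.assignment.items() if s == subset]

    def to_yaml(self) -> str:
        return yaml.safe_dump(
            {
                "seed": self.seed,
                "group_key": self.group_key,
                "proportions": list(self.proportions),
                "assignment": {int(k): v for k, v in sorted(self.assignment.items())},
            },
            sort_keys=True,
        )


@dataclass
class ExportBundle:
    root: Path
    label_files: dict[str, list[Path]] = field(default_factory=dict)
    coco_files: dict[str, Path] = field(default_factory=dict)
    manifest_file: Optional[Path] = None


# ---------------------------------------------------------------------------
# filtering


def _resolution_rank(item: tuple[tuple[int, int], int]) -> tuple:
    (w, h), count = item
    # count desc, then pixel area desc, then lexicographic
    return (-count, -(w * h), (w, h))


def filter_images(aset: AnnotationSet, policy: FilterPolicy = FilterPolicy()) -> AnnotationSet:
    """Pure selection of images passing the policy; survivors untouched."""
    survivors = list(aset.images)
    survivors = [
        im
        for im in survivors
        if not any(t.value in policy.rejected_quality_tags for t in im.tags)
    ]
    if policy.allowed_stage_tags is not None:
        survivors = [
            im
            for im in survivors
            if any(
                t.category == "procedural stage" and t.value in policy.allowed_stage_tags
                for t in im.tags
            )
        ]
    if policy.drop_unannotated:
        survivors = [im for im in survivors if im.shapes]
    if policy.resolution_policy == "keep-two-most-common":
        counts = Counter((im.width_px, im.height_px) for im in survivors)
        keep = {res for res, _ in sorted(counts.items(), key=_resolution_rank)[:2]}
        survivors = [im for im in survivors if (im.width_px, im.height_px) in keep]
    elif policy.resolution_policy == "explicit":
        keep = set(policy.explicit_resolutions)
        survivors = [im for im in survivors if (im.width_px, im.height_px) in keep]
    elif policy.resolution_policy != "keep-all":
        raise ValueError(f"unknown resolution policy {policy.resolution_policy!r}")
    if aset.images and not survivors:
        warnings.warn("filter removed every image; dataset is empty", stacklevel=2)
    return AnnotationSet(aset.vocabulary, survivors)


# ---------------------------------------------------------------------------
# class variants with background injection


def _is_target(shape, spec: VariantSpec) -> bool:
    if shape.class_name != spec.class_name:
        return False
    if spec.variant == "general":
        return True
    return shape.attributes.get(spec.attribute_key) == spec.attribute_value


def build_class_dataset(aset: AnnotationSet, spec: VariantSpec, seed: int = 0) -> AnnotationSet:
    """Positives for the (class, variant) plus seeded background images.

    Non-target shapes are dropped from every retained image, so background
    images come out shape-free (their label files will be empty).
    """
    if spec.class_name not in aset.vocabulary:
        raise ColposegError(f"class {spec.class_name!r} not in vocabulary")
    if spec.variant == "extended":
        entry = aset.vocabulary.get(spec.class_name)
        allowed = entry.attributes.get(spec.attribute_key)
        if allowed is None or spec.attribute_value not in allowed:
            raise ColposegError(
                f"{spec.attribute_key!r}={spec.attribute_value!r} is not a legal "
                f"attribute of {spec.class_name!r}"
            )

    positives, general_pool, difficult_pool = [], [], []
    for im in aset.images:
        if any(_is_target(s, spec) for s in im.shapes):
            positives.append(im)
        elif spec.variant == "extended" and any(
            s.class_name == spec.class_name for s in im.shapes
        ):
            difficult_pool.append(im)
        elif not any(s.class_name == spec.class_name for s in im.shapes):
            general_pool.append(im)

    rng = np.random.default_rng(seed)

    def sample(pool: list[ImageRecord], count: int, kind: str) -> list[ImageRecord]:
        if count > len(pool):
            warnings.warn(
                f"requested {count} {kind} backgrounds, only {len(pool)} available",
                stacklevel=3,
            )
            count = len(pool)
        idx = rng.choice(len(pool), size=count, replace=False) if count else []
        return [pool[i] for i in sorted(idx)]

    chosen = (
        positives
        + sample(general_pool, spec.background_count_general, "general")
        + sample(difficult_pool, spec.background_count_difficult, "difficult")
    )
    out = [
        dataclasses.replace(im, shapes=[s for s in im.shapes if _is_target(s, spec)])
        for im in chosen
    ]
    return AnnotationSet(aset.vocabulary, out)


# ---------------------------------------------------------------------------
# splitting


def split(
    aset: AnnotationSet,
    proportions: Sequence[float] = DEFAULT_PROPORTIONS,
    seed: int = 0,
    group_key: str = "image",
) -> SplitManifest:
    """Seeded train/val/test partition of images or patient groups.

    Unit counts are floor(n * p) per subset with the remainder handed to
    train, then val, then test; with ``group_key='patient'`` no patient
    spans two subsets.
    """
    proportions = tuple(float(p) for p in proportions)
    if len(proportions) != 3 or any(p <= 0 for p in proportions):
        raise ValueError("need three positive proportions")
    if abs(sum(proportions) - 1.0) > 1e-9:
        raise ValueError("proportions must sum to 1")

    if group_key == "image":
        units: list[tuple] = [(im.image_id,) for im in aset.images]
    elif group_key == "patient":
        missing = [im.image_id for im in aset.images if im.patient_id is None]
        if missing:
            raise SplitError(f"images missing patient_id: {missing}")
        groups: dict[str, list[int]] = {}
        for im in aset.images:
            groups.setdefault(im.patient_id, []).append(im.image_id)
        units = [tuple(groups[p]) for p in sorted(groups)]
    else:
        raise ValueError(f"unknown group key {group_key!r}")

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(units))
    n = len(units)
    # +1e-9 so floor sees the mathematical product, not float dust below it
    counts = [int(np.floor(n * p + 1e-9)) for p in proportions]
    for i in range(n - sum(counts)):  # remainder: train, then val, then test
        counts[i % 3] += 1
    assignment: dict[int, str] = {}
    pos = 0
    for subset, count in zip(SUBSETS, counts):
        for k in order[pos : pos + count]:
            for image_id in units[k]:
                assignment[image_id] = subset
        pos += count
    return SplitManifest(assignment, proportions, seed, group_key)


# ---------------------------------------------------------------------------
# export


def export_yolo_labels(
    aset: AnnotationSet,
    manifest: SplitManifest,
    class_index_map: Optional[dict[str, int]],
    out_dir: Path,
    simplify_tolerance_px: float = 0.5,
) -> ExportBundle:
    """Write YOLO-seg polygon label files under ``<out>/<subset>/labels/``.

    Each line is ``<class_idx> x1 y1 x2 y2 ...`` with 6-decimal normalized
    coordinates; background images get empty label files.
    """
    out_dir = Path(out_dir)
    if class_index_map is None:
        class_index_map = {
            name: i for i, name in enumerate(sorted({s.class_name for im in aset.images for s in im.shapes}))
        }
    bundle = ExportBundle(root=out_dir, label_files={s: [] for s in SUBSETS})
    for im in aset.images:
        subset = manifest.assignment.get(im.image_id)
        if subset is None:
            continue
        lines = []
        for shape in im.shapes:
            if shape.class_name not in class_index_map:
                raise ColposegError(f"class {shape.class_name!r} missing from index map")
            mask = rle.decode(shape.payload, im.width_px, im.height_px)
            for poly in geometry.mask_to_instances(
                mask,
                shape.class_name,
                shape.attributes,
                simplify_tolerance_px=simplify_tolerance_px,
            ):
                coords = " ".join(f"{v:.6f}" for v in poly.vertices_norm.ravel())
                lines.append(f"{class_index_map[shape.class_name]} {coords}")
        label_dir = out_dir / subset / "labels"
        label_dir.mkdir(parents=True, exist_ok=True)
        path = label_dir / (Path(im.file_name).stem + ".txt")
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
        bundle.label_files[subset].append(path)
    manifest_path = out_dir / "manifest.yaml"
    manifest_path.write_text(manifest.to_yaml())
    bundle.manifest_file = manifest_path
    return bundle


def parse_yolo_label_line(line: str, width_px: int, height_px: int):
    """Inverse of one exported line -> (class index, PolygonInstance)."""
    fields = line.split()
    cls = int(fields[0])
    coords = np.asarray([float(x) for x in fields[1:]], dtype=float).reshape(-1, 2)
    return cls, geometry.PolygonInstance(str(cls), coords)


def export_coco(aset: AnnotationSet, manifest: SplitManifest, out_dir: Path) -> ExportBundle:
    """Write one COCO 1.0 JSON per subset (category ids stable across subsets)."""
    out_dir = Path(out_dir)
    bundle = ExportBundle(root=out_dir)
    for subset in SUBSETS:
        sub = aset.subset(manifest.ids(subset))
        path = out_dir / subset / "annotations.json"
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(coco_io.write_coco(sub))
        bundle.coco_files[subset] = path
    manifest_path = out_dir / "manifest.yaml"
    manifest_path.write_text(manifest.to_yaml())
    bundle.manifest_file = manifest_path
    return bundle
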