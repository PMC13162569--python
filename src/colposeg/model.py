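"""Core annotation domain types.

The common currency of the toolkit is the :class:`BinaryMask` — a 2-D boolean
pixel-membership grid with the origin at the top-left pixel.  Annotation
containers (:class:`AnnotationSet`, :class:`ImageRecord`, :class:`MaskShape`)
hold masks in run-length-encoded form (:class:`RlePayload`) exactly as the
CVAT and COCO annotation dialects store them; decoding is done lazily by
:mod:`colposeg.rle`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Optional, Sequence

import numpy as np

from . import taxonomy


class ColposegError(Exception):
    """Base class for toolkit errors."""


class VocabularyError(ColposegError):
    """A class, tag or attribute is not legal under the active vocabulary."""


class PayloadError(ColposegError):
    """An RLE payload is inconsistent with its declared geometry."""


RLE_DIALECTS = ("cvat-bbox", "coco-uncompressed", "coco-compressed")


@dataclass(frozen=True)
class TagRecord:
    """Whole-image classification tag (procedural stage, quality, ...)."""

    category: str
    value: str

    def __post_init__(self) -> None:
        if self.category not in taxonomy.TAG_CATEGORIES:
            raise VocabularyError(f"unknown tag category: {self.category!r}")

    @classmethod
    def from_value(cls, value: str) -> "TagRecord":
        """Build a record by looking the value up in the default taxonomy."""
        try:
            return cls(taxonomy.TAG_VALUES[value], value)
        except KeyError:
            raise VocabularyError(f"unknown tag value: {value!r}") from None


@dataclass(frozen=True)
class LabelEntry:
    category: str
    class_name: str
    attributes: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.category not in taxonomy.MASK_CATEGORIES:
            raise VocabularyError(f"unknown mask category: {self.category!r}")
        for key, values in self.attributes.items():
            if not values:
                raise VocabularyError(
                    f"attribute {key!r} of class {self.class_name!r} has no allowed values"
                )


class LabelVocabulary:
    """Hierarchical class vocabulary: category -> class -> attribute values."""

    def __init__(self, entries: Sequence[LabelEntry]):
        names = [e.class_name for e in entries]
        if len(set(names)) != len(names):
            raise VocabularyError("duplicate class names in vocabulary")
        self.entries = tuple(entries)
        self._by_name = {e.class_name: e for e in entries}

    @classmethod
    def default(cls) -> "LabelVocabulary":
        return cls(
            [LabelEntry(cat, name, attrs) for cat, name, attrs in taxonomy.default_vocabulary_entries()]
        )

    @classmethod
    def from_yaml(cls, text: str) -> "LabelVocabulary":
        return cls(
            [LabelEntry(cat, name, attrs) for cat, name, attrs in taxonomy.vocabulary_entries_from_yaml(text)]
        )

    def to_yaml(self) -> str:
        return taxonomy.vocabulary_to_yaml(
            [(e.category, e.class_name, e.attributes) for e in self.entries]
        )

    def __contains__(self, class_name: str) -> bool:
        return class_name in self._by_name

    def __iter__(self) -> Iterator[LabelEntry]:
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, LabelVocabulary) and self.entries == other.entries

    def get(self, class_name: str) -> LabelEntry:
        try:
            return self._by_name[class_name]
        except KeyError:
            raise VocabularyError(f"unknown class: {class_name!r}") from None

    def class_names(self) -> list[str]:
        return [e.class_name for e in self.entries]

    def check_shape(self, class_name: str, attributes: Mapping[str, str]) -> None:
        """Raise VocabularyError if the class or any attribute is illegal."""
        entry = self.get(class_name)
        for key, value in attributes.items():
            allowed = entry.attributes.get(key)
            if allowed is None:
                raise VocabularyError(
                    f"class {class_name!r} has no attribute {key!r}"
                )
            if value not in allowed:
                raise VocabularyError(
                    f"value {value!r} not allowed for attribute {key!r} of {class_name!r}"
                )


class BinaryMask:
    """2-D boolean pixel membership grid, row-major, origin top-left."""

    __slots__ = ("membership",)

    def __init__(self, membership: np.ndarray):
        arr = np.asarray(membership)
        if arr.ndim != 2:
            raise ValueError("mask must be 2-D")
        self.membership = arr.astype(bool, copy=False)

    @classmethod
    def zeros(cls, height_px: int, width_px: int) -> "BinaryMask":
        return cls(np.zeros((height_px, width_px), dtype=bool))

    @property
    def height_px(self) -> int:
        return self.membership.shape[0]

    @property
    def width_px(self) -> int:
        return self.membership.shape[1]

    @property
    def foreground_count(self) -> int:
        return int(self.membership.sum())

    def __eq__(self, other: object) -> bool:
        return isinstance(other, BinaryMask) and np.array_equal(self.membership, other.membership)

    def __repr__(self) -> str:  # pragma: no cover
        return f"BinaryMask({self.height_px}x{self.width_px}, fg={self.foreground_count})"


@dataclass(frozen=True)
class RlePayload:
    """Run-length-encoded mask.

    ``runs`` alternate background/foreground starting with background.
    ``anchor_box`` is ``(left, top, width, height)`` for the ``cvat-bbox``
    dialect (runs are row-major within the box) or ``None`` for whole-frame
    COCO dialects (runs are column-major over the full image).
    """

    runs: tuple[int, ...]
    anchor_box: Optional[tuple[int, int, int, int]]
    dialect: str

    def __post_init__(self) -> None:
        if self.dialect not in RLE_DIALECTS:
            raise PayloadError(f"unknown RLE dialect: {self.dialect!r}")
        if any(r < 0 for r in self.runs):
            raise PayloadError("negative run length")
        if self.dialect == "cvat-bbox" and self.anchor_box is None:
            raise PayloadError("cvat-bbox payload requires an anchor box")

    @property
    def foreground_total(self) -> int:
        return sum(self.runs[1::2])


@dataclass
class MaskShape:
    """One labeled mask instance on an image."""

    class_name: str
    payload: RlePayload
    attributes: dict[str, str] = field(default_factory=dict)
    image_id: Optional[int] = None


@dataclass
class ImageRecord:
    image_id: int
    file_name: str
    width_px: int
    height_px: int
    tags: list[TagRecord] = field(default_factory=list)
    shapes: list[MaskShape] = field(default_factory=list)
    patient_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.width_px < 1 or self.height_px < 1:
            raise ValueError("image dimensions must be >= 1 px")

    def has_tag(self, value: str) -> bool:
        return any(t.value == value for t in self.tags)

    def class_names(self) -> set[str]:
        return {s.class_name for s in self.shapes}


@dataclass
class AnnotationSet:
    vocabulary: LabelVocabulary
    images: list[ImageRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [im.image_id for im in self.images]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate image ids")

    def validate(self) -> None:
        """Check every shape's class and attributes against the vocabulary."""
        for im in self.images:
            for shape in im.shapes:
                self.vocabulary.check_shape(shape.class_name, shape.attributes)

    def image_by_id(self, image_id: int) -> ImageRecord:
        for im in self.images:
            if im.image_id == image_id:
                return im
        raise KeyError(image_id)

    def subset(self, image_ids: Sequence[int]) -> "AnnotationSet":
        wanted = set(image_ids)
        return AnnotationSet(self.vocabulary, [im for im in self.images if im.image_id in wanted])

    def map_images(self, fn) -> "AnnotationSet":
        return AnnotationSet(self.vocabulary, [fn(dataclasses.replace(im)) for im in self.images])
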