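"""Default label and tag taxonomy for colposcopy image annotation.

The vocabulary mirrors the annotation scheme used in multi-stage colposcopy
studies: classification *tags* describe whole-image properties (procedural
stage, clinical assessment, image quality, technical parameters), while
*mask* classes fall into three categories — physiological/anatomical
structures, colposcopic findings, and obstacles/artifacts.  Attributes refine
selected classes (e.g. squamous epithelium is either ``original`` or
``metaplastic``).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import yaml

# tag value -> tag category
TAG_VALUES: dict[str, str] = {
    "Stage 0—before rinsing": "procedural stage",
    "Stage 1—after saline application": "procedural stage",
    "Stage 2—after application of acetic acid": "procedural stage",
    "Stage 3—after application of Lugol's solution": "procedural stage",
    "Normal colposcopic findings": "clinical assessment",
    "Abnormal colposcopic findings": "clinical assessment",
    "High quality image": "image quality",
    "Low quality image": "image quality",
    "Unusable image": "image quality",
    "Green filter": "technical",
}

TAG_CATEGORIES = ("procedural stage", "clinical assessment", "image quality", "technical")

MASK_CATEGORIES = ("physiological-anatomical", "findings", "obstacles-artifacts")

_ANATOMICAL = [
    "Cervix",
    "Squamous epithelium",
    "External os",
    "Columnar epithelium",
    "nSCJ",
    "Transformation zone",
]

_FINDINGS = [
    "Acetowhite epithelium",
    "Erythroplakia",
    "Iodine-negative zone",
    "Rimmed glandular openings",
    "Endometriosis",
    "Mosaicism",
    "Polyp",
    "Punctation",
    "Atypical vessels",
    "Inflammatory changes",
    "Atrophy",
    "Exophytic changes",
    "Glandular ectopy",
    "Irregular surface",
    "Papilloma",
    "Leukoplakia",
    "Erosion",
    "Decidual changes (in pregnancy)",
    "Condyloma",
]

_OBSTACLES = ["Mucus", "Blood", "Medical instruments"]

# class attributes: class name -> {attribute name: allowed values}
CLASS_ATTRIBUTES: dict[str, dict[str, tuple[str, ...]]] = {
    "Squamous epithelium": {"epithelium type": ("original", "metaplastic")},
}


def default_vocabulary_entries() -> list[tuple[str, str, dict[str, tuple[str, ...]]]]:
    """Return (category, class_name, attributes) triples of the default taxonomy."""
    entries = []
    for cat, names in (
        ("physiological-anatomical", _ANATOMICAL),
        ("findings", _FINDINGS),
        ("obstacles-artifacts", _OBSTACLES),
    ):
        for name in names:
            entries.append((cat, name, dict(CLASS_ATTRIBUTES.get(name, {}))))
    return entries


def vocabulary_entries_from_yaml(text: str) -> list[tuple[str, str, dict[str, tuple[str, ...]]]]:
    """Parse a vocabulary config.

    Expected layout::

        classes:
          - name: Squamous epithelium
            category: physiological-anatomical
            attributes:
              epithelium type: [original, metaplastic]
    """
    data = yaml.safe_load(text) or {}
    entries = []
    for item in data.get("classes", []):
        attrs = {k: tuple(str(v) for v in vals) for k, vals in (item.get("attributes") or {}).items()}
        entries.append((str(item["category"]), str(item["name"]), attrs))
    return entries


def vocabulary_to_yaml(entries: Sequence[tuple[str, str, Mapping[str, Sequence[str]]]]) -> str:
    data = {
        "classes": [
            {
                "name": name,
                "category": cat,
                **({"attributes": {k: list(v) for k, v in attrs.items()}} if attrs else {}),
            }
            for cat, name, attrs in entries
        ]
    }
    return yaml.safe_dump(data, sort_keys=False, allow_unicode=True)
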