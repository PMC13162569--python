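"""Binary-mask vectorization: contours, holes, and model-ready polygons.

Annular structures (squamous epithelium rings) must be encoded as a single
simple polygon for polygon-based segmentation trainers; this module detects
hierarchical contours, discards tiny fragments, merges each hole into its
outer boundary through a zero-width connector bridge between the nearest
vertex pair, normalizes vertices to [0, 1], and provides the inverse
rasterization used as a test oracle.

Coordinate convention
---------------------
Continuous frame coordinates span ``[0, W] x [0, H]`` with the center of
pixel ``(row r, col c)`` at ``(c + 0.5, r + 0.5)``.  A pixel is inside a
polygon iff its *center* is, under the even-odd rule — so a connector bridge
traversed once in each direction contributes nothing and holes stay empty.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from skimage import measure

from .model import BinaryMask, ColposegError


class TopologyError(ColposegError):
    """A hole is not strictly inside its outer contour."""


MIN_CONTOUR_AREA_PX = 30  # fragments below this pixel area are discarded


@dataclass
class Contour:
    """Closed boundary in continuous frame coordinates (x, y), not repeated."""

    vertices: np.ndarray  # (n, 2) float
    role: str = "outer"  # "outer" | "hole"
    parent_index: Optional[int] = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2 or len(self.vertices) < 3:
            raise ValueError("contour needs >= 3 (x, y) vertices")
        if self.role == "hole" and self.parent_index is None:
            raise ValueError("hole contour needs a parent")

    @property
    def signed_area(self) -> float:
        x, y = self.vertices[:, 0], self.vertices[:, 1]
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


@dataclass
class PolygonInstance:
    """One class instance as a simple polygon with [0, 1]-normalized vertices."""

    class_name: str
    vertices_norm: np.ndarray  # (n, 2) float in [0, 1]
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices_norm = np.asarray(self.vertices_norm, dtype=float)
        v = self.vertices_norm
        if v.ndim != 2 or v.shape[1] != 2 or len(v) < 3:
            raise ValueError("polygon needs >= 3 vertices")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("normalized vertices must lie in [0, 1]")


# ---------------------------------------------------------------------------
# even-odd scanline rasterization


def rasterize_path(vertices: np.ndarray, width_px: int, height_px: int) -> np.ndarray:
    """Even-odd fill of a closed path over pixel centers; returns bool grid."""
    out = np.zeros((height_px, width_px), dtype=bool)
    v = np.asarray(vertices, dtype=float)
    if len(v) < 3:
        return out
    x1, y1 = v[:, 0], v[:, 1]
    x2, y2 = np.roll(x1, -1), np.roll(y1, -1)
    keep = y1 != y2  # horizontal edges never cross a scanline
    x1, y1, x2, y2 = x1[keep], y1[keep], x2[keep], y2[keep]
    if x1.size == 0:
        return out
    ymin = np.minimum(y1, y2)
    ymax = np.maximum(y1, y2)
    slope = (x2 - x1) / (y2 - y1)
    r_lo = max(0, int(np.floor(ymin.min() - 0.5)))
    r_hi = min(height_px, int(np.ceil(ymax.max())) + 1)
    for r in range(r_lo, r_hi):
        yc = r + 0.5
        hit = (ymin <= yc) & (yc < ymax)  # half-open: vertex on scanline counted once
        if not hit.any():
            continue
        # +1e-9 is a symbolic perturbation: a center exactly on an edge (a
        # connector bridge can run along a half-integer column) is assigned
        # to one side consistently instead of falling out of both spans
        xs = np.sort(x1[hit] + (yc - y1[hit]) * slope[hit]) + 1e-9
        for a, b in zip(xs[0::2], xs[1::2]):
            c0 = max(0, int(np.floor(a - 0.5)) + 1)  # first center with c+0.5 > a
            c1 = min(width_px - 1, int(np.ceil(b - 0.5)) - 1)  # last center with c+0.5 < b
            if c1 >= c0:
                out[r, c0 : c1 + 1] ^= True  # XOR keeps even-odd exact for overlapping spans
    return out


def point_in_path(point: Sequence[float], vertices: np.ndarray) -> bool:
    """Even-odd containment of a single point (crossing number)."""
    px, py = float(point[0]), float(point[1])
    v = np.asarray(vertices, dtype=float)
    x1, y1 = v[:, 0], v[:, 1]
    x2, y2 = np.roll(x1, -1), np.roll(y1, -1)
    keep = y1 != y2
    x1, y1, x2, y2 = x1[keep], y1[keep], x2[keep], y2[keep]
    hit = (np.minimum(y1, y2) <= py) & (py < np.maximum(y1, y2))
    if not hit.any():
        return False
    xi = x1[hit] + (py - y1[hit]) * (x2[hit] - x1[hit]) / (y2[hit] - y1[hit])
    return bool(np.count_nonzero(xi + 1e-9 > px) % 2)


def contour_pixel_area(contour: Contour) -> int:
    """Number of pixel centers enclosed by the contour (its own ring only)."""
    v = contour.vertices
    left = int(np.floor(v[:, 0].min()))
    top = int(np.floor(v[:, 1].min()))
    right = int(np.ceil(v[:, 0].max()))
    bottom = int(np.ceil(v[:, 1].max()))
    shifted = v - [left, top]
    return int(rasterize_path(shifted, max(right - left, 1), max(bottom - top, 1)).sum())


# ---------------------------------------------------------------------------
# contour extraction


def extract_contours(mask: BinaryMask) -> list[Contour]:
    """Hierarchical boundary contours of the mask foreground.

    Foreground is 8-connected.  Returned outer contours carry no parent;
    every hole's ``parent_index`` points at its enclosing outer within the
    returned list.  Rasterizing (outer minus holes) recovers the mask.
    """
    arr = mask.membership
    if not arr.any():
        return []
    padded = np.pad(arr, 1).astype(float)
    raw = measure.find_contours(padded, 0.5, fully_connected="high")
    paths = []
    for rc in raw:
        if np.allclose(rc[0], rc[-1]):
            rc = rc[:-1]
        if len(rc) < 3:
            continue
        # (row, col) in padded index space -> frame (x, y)
        paths.append(np.column_stack([rc[:, 1] - 0.5, rc[:, 0] - 0.5]))
    # nesting depth by even-odd containment of a representative vertex
    depths = []
    for i, p in enumerate(paths):
        depth = sum(
            1 for j, q in enumerate(paths) if j != i and point_in_path(p[0], q)
        )
        depths.append(depth)
    contours: list[Contour] = []
    index_map: dict[int, int] = {}
    order = sorted(range(len(paths)), key=lambda i: (depths[i], i))
    for i in order:
        if depths[i] % 2 == 0:
            index_map[i] = len(contours)
            contours.append(Contour(paths[i], "outer"))
    for i in order:
        if depths[i] % 2 == 1:
            # immediate parent: smallest enclosing outer one level up
            candidates = [
                j
                for j in range(len(paths))
                if j != i and depths[j] == depths[i] - 1 and point_in_path(paths[i][0], paths[j])
            ]
            parent_raw = min(
                candidates, key=lambda j: abs(Contour(paths[j]).signed_area)
            )
            contours.append(Contour(paths[i], "hole", index_map[parent_raw]))
    return contours


# ---------------------------------------------------------------------------
# simplification (Douglas-Peucker on a closed ring)


def _dp(points: np.ndarray, tol: float) -> np.ndarray:
    """Douglas-Peucker on an open chain; endpoints always kept."""
    if len(points) <= 2:
        return points
    a, b = points[0], points[-1]
    ab = b - a
    norm = np.hypot(*ab)
    mid = points[1:-1]
    if norm == 0.0:
        dists = np.hypot(*(mid - a).T)
    else:
        dists = np.abs(ab[0] * (mid[:, 1] - a[1]) - ab[1] * (mid[:, 0] - a[0])) / norm
    idx = int(np.argmax(dists))
    if dists[idx] > tol:
        left = _dp(points[: idx + 2], tol)
        right = _dp(points[idx + 1 :], tol)
        return np.vstack([left[:-1], right])
    return np.vstack([a, b])


def simplify_contour(contour: Contour, tolerance_px: float = 0.5) -> Contour:
    """Reduce vertex count; removed vertices stay within ``tolerance_px`` of
    the simplified path.  Tolerance 0 removes exactly collinear vertices."""
    if tolerance_px < 0:
        raise ValueError("tolerance must be >= 0")
    v = contour.vertices
    if len(v) <= 3:
        return contour
    # split the ring at its two mutually farthest vertices so DP endpoints
    # are guaranteed survivors of any sensible simplification
    a = int(np.argmax(np.hypot(*(v - v[0]).T)))
    b = int(np.argmax(np.hypot(*(v - v[a]).T)))
    i, j = sorted((a, b))
    chain1 = v[i : j + 1]
    chain2 = np.vstack([v[j:], v[: i + 1]])
    s1 = _dp(chain1, tolerance_px)
    s2 = _dp(chain2, tolerance_px)
    merged = np.vstack([s1[:-1], s2[:-1]])
    if len(merged) < 3:
        return contour
    return replace(contour, vertices=merged)


# ---------------------------------------------------------------------------
# size filtering


def filter_small(
    contours: Sequence[Contour], min_area_px: int = MIN_CONTOUR_AREA_PX
) -> list[Contour]:
    """Drop contours enclosing fewer than ``min_area_px`` pixels.

    A contour of area exactly ``min_area_px`` is retained; holes of a
    discarded outer are discarded with it.  Order is preserved and parent
    links are re-indexed.
    """
    keep = [contour_pixel_area(c) >= min_area_px for c in contours]
    for i, c in enumerate(contours):
        if c.role == "hole" and not keep[c.parent_index]:
            keep[i] = False
    new_index: dict[int, int] = {}
    out: list[Contour] = []
    for i, (c, k) in enumerate(zip(contours, keep)):
        if not k:
            continue
        new_index[i] = len(out)
        parent = new_index[c.parent_index] if c.role == "hole" else None
        out.append(replace(c, parent_index=parent))
    return out


# ---------------------------------------------------------------------------
# donut merging


def merge_donut(outer: Contour, holes: Sequence[Contour]) -> Contour:
    """Merge holes into the outer boundary via zero-width connector bridges.

    Each hole is spliced at the vertex pair (merged path vertex, hole
    vertex) with minimal Euclidean distance; ties break on the lowest vertex
    index.  Holes are processed in decreasing area order and traversed
    opposite to the outer's orientation, so even-odd rasterization leaves
    the hole interiors empty.
    """
    merged = outer.vertices.copy()
    outer_ccw = outer.signed_area > 0
    for hole in sorted(holes, key=lambda h: -abs(h.signed_area)):
        if not point_in_path(hole.vertices[0], outer.vertices):
            raise TopologyError("hole is not inside the outer contour")
        hv = hole.vertices.copy()
        if (hole.signed_area > 0) == outer_ccw:
            hv = hv[::-1]
        d = np.linalg.norm(merged[:, None, :] - hv[None, :, :], axis=2)
        i, j = np.unravel_index(int(np.argmin(d)), d.shape)  # lowest index on ties
        merged = np.vstack(
            [merged[: i + 1], hv[j:], hv[: j + 1], merged[i:]]
        )
    return Contour(merged, "outer")


# ---------------------------------------------------------------------------
# component splitting


def split_components(mask: BinaryMask) -> list[BinaryMask]:
    """Split the foreground into 8-connected components.

    Components are ordered by their first foreground pixel in row-major
    scan order (top-most, then left-most); outputs are pairwise disjoint and
    union exactly to the input.
    """
    labels = measure.label(mask.membership, connectivity=2)
    n = labels.max()
    if n == 0:
        return []
    flat = labels.ravel()
    first_seen = {}
    for pos in np.flatnonzero(flat):
        lab = flat[pos]
        if lab not in first_seen:
            first_seen[lab] = pos
            if len(first_seen) == n:
                break
    order = sorted(first_seen, key=first_seen.get)
    return [BinaryMask(labels == lab) for lab in order]


# ---------------------------------------------------------------------------
# normalization / rasterization


def normalize_polygon(
    contour: Contour,
    width_px: int,
    height_px: int,
    class_name: str = "",
    attributes: Optional[dict[str, str]] = None,
) -> PolygonInstance:
    """Scale vertices to [0, 1] relative to the frame (clamped)."""
    if width_px <= 0 or height_px <= 0:
        raise ValueError("frame dimensions must be positive")
    norm = np.clip(contour.vertices / [width_px, height_px], 0.0, 1.0)
    return PolygonInstance(class_name, norm, dict(attributes or {}))


def denormalize(polygon: PolygonInstance, width_px: int, height_px: int) -> np.ndarray:
    return polygon.vertices_norm * [width_px, height_px]


def rasterize(polygon: PolygonInstance, width_px: int, height_px: int) -> BinaryMask:
    """Pixel-center even-odd rasterization; the inverse oracle of
    vectorization (connector bridges do not fill holes)."""
    return BinaryMask(rasterize_path(denormalize(polygon, width_px, height_px), width_px, height_px))


# ---------------------------------------------------------------------------
# full vectorization pipeline


def mask_to_instances(
    mask: BinaryMask,
    class_name: str = "",
    attributes: Optional[dict[str, str]] = None,
    simplify_tolerance_px: float = 0.5,
    min_area_px: int = MIN_CONTOUR_AREA_PX,
) -> list[PolygonInstance]:
    """Vectorize a mask: split components, extract and simplify contours,
    drop tiny fragments, merge holes, normalize.

    One polygon per surviving connected component (plus one per island
    nested inside a hole).
    """
    instances: list[PolygonInstance] = []
    for component in split_components(mask):
        contours = extract_contours(component)
        contours = [simplify_contour(c, simplify_tolerance_px) for c in contours]
        contours = filter_small(contours, min_area_px)
        for idx, contour in enumerate(contours):
            if contour.role != "outer":
                continue
            holes = [c for c in contours if c.role == "hole" and c.parent_index == idx]
            merged = merge_donut(contour, holes)
            instances.append(
                normalize_polygon(
                    merged, mask.width_px, mask.height_px, class_name, attributes
                )
            )
    return instances
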