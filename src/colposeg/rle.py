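"""Run-length codec for binary masks.

Three dialects are supported:

``cvat-bbox``
    Runs are row-major *within the shape's tight bounding box*, as in CVAT
    brush-mask exports.  The payload carries the box as ``(left, top, width,
    height)``.
``coco-uncompressed``
    Runs are column-major (Fortran order) over the whole frame, as in COCO
    ``segmentation: {"counts": [...], "size": [h, w]}`` records.
``coco-compressed``
    Same run order as ``coco-uncompressed``; the COCO compressed-counts
    string codec is provided by :func:`compress_counts` /
    :func:`decompress_counts` (5-bit chunks, delta-coded from the
    next-to-previous run, printable ASCII offset 48).

In every dialect runs alternate background / foreground starting with
background; ``decode(encode(m)) == m`` exactly for every mask.
"""

from __future__ import annotations

import numpy as np

from .model import BinaryMask, PayloadError, RlePayload


def _runs_from_flat(flat: np.ndarray) -> tuple[int, ...]:
    """Alternating run lengths of a flat boolean array, background first."""
    if flat.size == 0:
        return ()
    boundaries = np.flatnonzero(np.diff(flat.view(np.int8)))
    lengths = np.diff(np.concatenate(([0], boundaries + 1, [flat.size])))
    runs = tuple(int(x) for x in lengths)
    if flat[0]:  # leading zero-length background run
        runs = (0,) + runs
    return runs


def _flat_from_runs(runs: tuple[int, ...], size: int) -> np.ndarray:
    if sum(runs) != size:
        raise PayloadError(f"run sum {sum(runs)} does not match area {size}")
    flat = np.zeros(size, dtype=bool)
    pos = 0
    for i, run in enumerate(runs):
        if i % 2 == 1:
            flat[pos : pos + run] = True
        pos += run
    return flat


def encode(mask: BinaryMask, dialect: str = "cvat-bbox") -> RlePayload:
    """Encode a mask; inverse of :func:`decode` (exact roundtrip)."""
    arr = mask.membership
    if dialect == "cvat-bbox":
        rows, cols = np.nonzero(arr)
        if rows.size == 0:
            # degenerate empty payload: no runs, zero-area anchor box
            return RlePayload((), (0, 0, 0, 0), dialect)
        top, bottom = int(rows.min()), int(rows.max())
        left, right = int(cols.min()), int(cols.max())
        window = arr[top : bottom + 1, left : right + 1]
        runs = _runs_from_flat(window.ravel(order="C"))
        return RlePayload(runs, (left, top, right - left + 1, bottom - top + 1), dialect)
    if dialect in ("coco-uncompressed", "coco-compressed"):
        runs = _runs_from_flat(arr.ravel(order="F"))
        return RlePayload(runs, None, dialect)
    raise PayloadError(f"unknown RLE dialect: {dialect!r}")


def decode(payload: RlePayload, width_px: int, height_px: int) -> BinaryMask:
    """Decode a payload onto a ``height_px`` x ``width_px`` frame."""
    if payload.dialect == "cvat-bbox":
        left, top, w, h = payload.anchor_box
        if left < 0 or top < 0 or left + w > width_px or top + h > height_px:
            raise PayloadError(
                f"anchor box {payload.anchor_box} out of {width_px}x{height_px} frame"
            )
        window = _flat_from_runs(payload.runs, w * h).reshape(h, w)
        arr = np.zeros((height_px, width_px), dtype=bool)
        arr[top : top + h, left : left + w] = window
        return BinaryMask(arr)
    flat = _flat_from_runs(payload.runs, width_px * height_px)
    return BinaryMask(flat.reshape((height_px, width_px), order="F"))


def compress_counts(runs) -> str:
    """COCO compressed-counts string of a run sequence.

    Each count (delta-coded against the count two positions back, from the
    third on) is emitted as little-endian 5-bit chunks; bit 0x20 marks
    continuation and chunks are offset by 48 into printable ASCII.
    """
    runs = list(runs)
    out = []
    for i, count in enumerate(runs):
        x = count - runs[i - 2] if i > 2 else count
        while True:
            c = x & 0x1F
            x >>= 5
            more = (x != -1) if (c & 0x10) else (x != 0)
            if more:
                c |= 0x20
            out.append(chr(c + 48))
            if not more:
                break
    return "".join(out)


def decompress_counts(s: str) -> tuple[int, ...]:
    """Inverse of :func:`compress_counts`."""
    counts: list[int] = []
    pos = 0
    while pos < len(s):
        x = 0
        k = 0
        while True:
            c = ord(s[pos]) - 48
            x |= (c & 0x1F) << (5 * k)
            pos += 1
            k += 1
            if not (c & 0x20):
                if c & 0x10:  # sign-extend negative delta
                    x |= -1 << (5 * k)
                break
        if len(counts) > 2:
            x += counts[-2]
        counts.append(x)
    return tuple(counts)
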