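# Methods

This note records the conventions, defaults and design choices behind
`colposeg`, in the order data flows through the toolkit.

## Annotation model and RLE dialects

Annotations live in an `AnnotationSet`: a label vocabulary (three mask
categories — physiological/anatomical, findings, obstacles/artifacts —
with optional per-class attribute value sets, e.g. squamous epithelium's
`epithelium type ∈ {original, metaplastic}`) plus per-image records
carrying whole-image tags (procedural stage, clinical assessment, image
quality, technical) and run-length-encoded mask shapes.

Three RLE dialects are supported, all alternating background/foreground
runs starting with background:

- `cvat-bbox` — row-major within the shape's tight bounding box, as CVAT
  brush exports store masks. The box travels as `(left, top, width,
  height)`.
- `coco-uncompressed` — column-major over the whole frame (`counts` list).
- `coco-compressed` — same order, serialized with the COCO 5-bit
  delta-coded printable-ASCII string codec, implemented in `colposeg.rle`.

The codec is a bijection: `decode(encode(m)) == m` exactly, for every
dialect, property-tested on random masks. Correctness is defined by this
roundtrip, not by byte-equality with any particular exporter's files —
the run convention of third-party exports is not normative, so a foreign
file is normalized on parse and may re-serialize with different bytes but
identical pixels.

Unknown labels encountered while parsing warn and are added to the
vocabulary by default (`on_unknown="warn"`); strict mode (`"fail"`) raises
instead. Patient identifiers have no native slot in either dialect; they
are read and written as an optional `patient_id` attribute on CVAT
`<image>` elements and a `patient_id` key on COCO image records. Images
without ids cannot be split at patient level — that is an explicit error,
never a silent fallback.

## Geometry

**Coordinate convention.** Continuous frame coordinates span
`[0, W] × [0, H]`; the center of pixel `(row r, col c)` is
`(c + 0.5, r + 0.5)`. A pixel belongs to a polygon iff its center is
inside under the **even-odd rule**. This pairing is what makes the donut
connector bridge exactly zero-area: the bridge is traversed once in each
direction, scanlines cross it twice, and parity is unchanged. A 1e-9
symbolic perturbation in the scanline fill assigns centers that lie
exactly on an edge (possible when a bridge runs along a half-integer
column) consistently to one side.

**Contours** come from marching squares at level 0.5 on a zero-padded
mask, with 8-connected foreground. Marching-squares vertices always have
one integer coordinate in this frame, so pixel centers never sit exactly
on extracted contour edges and rasterization is unambiguous. Hierarchy is
recovered by even-odd containment depth: even depth → outer, odd → hole;
a hole's parent is the smallest enclosing contour one level up.

**Simplification** is Douglas–Peucker on the closed ring, split at the two
mutually farthest vertices so the chain endpoints are guaranteed
survivors. Tolerance 0 removes exactly collinear vertices; the default
tolerance is 0.5 px (configurable) — small enough that vectorize →
rasterize conserves pixel sets to Dice ≥ 0.99 for structures ≥ 100 px.

**Size filter.** Contours enclosing fewer than 30 pixels are discarded;
area exactly 30 is retained ("below 30" is strict). Area means enclosed
pixel-center count — the reading consistent with mask semantics — not
vertex count or perimeter. Filtering runs before donut merging, so holes
inherit their outer's fate; `mask_to_instances(min_area_px=...)` exposes
the threshold.

**Donut merge.** Holes are merged largest-first; each is spliced at the
(merged-path vertex, hole vertex) pair of minimal Euclidean distance, ties
broken by lowest vertex index; the hole is traversed opposite to the
outer's orientation. The merged vertex count is exactly
`outer + Σ(hole + 2)` (two splice duplicates per hole), which tests audit.

**Component splitting** uses 8-connectivity (matching the contour
extractor) and orders components by first foreground pixel in row-major
scan order. Outputs are pairwise disjoint and union exactly to the input.

## Dataset curation

Filtering is pure selection: images tagged `Unusable image` or
`Low quality image` are rejected (set configurable), annotation-free
images are dropped, and by default only the two most common `(width,
height)` pairs survive. Resolution ties break by count desc, then pixel
area desc, then lexicographic — documented so the comparator is testable.

Class datasets come in a *general* variant (the class as a whole) or an
*extended* one (a single attribute value as the label). Backgrounds are
sampled with a seeded generator: *general* backgrounds lack the class
entirely; *difficult* backgrounds (extended only) carry the class under a
different attribute value. Requested counts exceeding the pool are capped
with a warning. Non-target shapes are dropped from retained images, so
backgrounds export as empty label files — deliberate negative evidence
for one-class models. Background images count toward split proportions
like any other image.

Splits shuffle units (images, or whole patient groups) with a seeded
generator; subset sizes are `floor(n·p)` with the remainder handed to
train, then val, then test, so `n` divisible by 10 under the default
70/20/10 gives exact sizes. Splitting is per class dataset; callers
wanting one global split can split the parent set once and reuse the
manifest.

Exports: YOLO-seg label files (`<class_idx> x1 y1 x2 y2 …`, 6-decimal
normalized coordinates, one polygon per line, `<out>/<subset>/labels/`),
per-subset COCO JSON with category ids stable across subsets, and a YAML
manifest (seed, proportions, assignment). Identical inputs and seed yield
byte-identical bundles. The class index map defaults to alphabetical.

## Evaluation

Per image and class, both prediction and ground truth are collapsed to the
union of their instances before the pixel confusion is computed — one
record per image per class, so summary SDs measure per-image spread. An
image whose ground truth contains the class but which received no
prediction scores zero (models do omit whole masks); images without the
class stay out of that class's summary. SD is the sample (n−1) standard
deviation; a single record reports SD 0.

ε = 1e-8 is added to every pixel-metric denominator, applied literally:
an empty-vs-empty confusion scores 0, not 1. The identities
Dice = 2·IoU/(1+IoU) and Dice = harmonic mean(precision, recall) hold to
1e-9 and are property-tested.

Instance matching is COCO-style: predictions sorted by confidence
(ties by image id, then input order), each greedily matched to the
unmatched ground-truth instance of highest mask IoU at or above the
threshold. AP uses 101-point interpolation; mAP50-95 averages thresholds
0.50…0.95 in 0.05 steps; with no ground truth AP is defined as 0.
Instance F1 uses plain count ratios (the ε rule belongs to the pixel
formulas) at IoU 0.5, maximized over observed confidence cutoffs — the
convention of mainstream detector tooling, which is what the composite
objective `0.7·F1 + 0.3·mAP50-95` is meant to mirror. The test suite
checks the greedy sweep against a naive oracle that re-matches from
scratch at every cutoff. Instance-level aggregation assumes a uniform
frame size per class batch (true of the curated datasets, which filter to
two resolutions and evaluate per class).

## Synthetic scenes

The generator emulates the structural hazards of real colposcopy
annotations, not their appearance: a large elliptical cervix, an
axis-aligned rectangular epithelium ring whose foreground count is exact
by construction (outer − hole), a thin instrument, and multi-component
lesions. Overlaps resolve by draw order (later occludes earlier).
Rasters are flat-shaded; passing tests therefore demonstrate correctness
of geometry, codecs, curation and metrics on exactly known ground truth —
they say nothing about perception of real tissue, stain dynamics, or
annotation noise. Perturbed predictions (shift, dilate/erode, drops,
confidence jitter) are seeded and reproducible; a horizontal shift of k px
on a w×h rectangle gives the closed-form IoU (w−k)/(w+k) used as an exact
oracle.

Default test problem sizes (scenes of 120×100 px, batches of 5–100
images, masks up to 256×256 for codec properties) keep the full suite in
a few seconds while covering every boundary the larger originals would.

## Known limitations

- Marching-squares contours cut corners at single-pixel diagonal steps;
  conservation is exact for rectilinear shapes and ≥ 0.99 Dice for blobby
  ones ≥ 100 px, but single-pixel filaments can drop below that.
- The CVAT writer emits the toolkit's own run convention; byte-level
  compatibility with any specific CVAT server version is not guaranteed
  (pixel-level equivalence is).
- `instance_f1`'s best-cutoff search is exact only because greedy matching
  of a confidence-ordered prefix equals the prefix of the full greedy
  matching; if a different matcher is substituted this shortcut must be
  revisited.
- No bootstrap confidence intervals or significance tests; no box-level
  mAP.
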