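# Methods

## The measurement problem

Wide-field micrographs of fission yeast typically carry a bright-field
plane (channel 1) and one or two fluorescent planes (channels 2–3). The
quantities of interest per cell are its length, width, and area, and the
mean fluorescence of its nucleus and of the whole cell, background
subtracted. Cells are convex rods ("capsules"); nuclei are roughly
circular disks occupying on the order of 15 % of the cell's projected
area. `halocell` computes these per-cell quantities fully automatically,
with one optional manual exclusion step.

## Bright-field cell segmentation

Segmentation does not operate on in-focus cell bodies (which have weak,
variable contrast) but on the narrow bright halo that slight defocusing
draws around each cell. The stages, each a pure function:

1. **Sharpen** — unsharp mask `I + a·(I − G_σ(I))`, σ =
   `sharpen_radius_px` (default 1.0 px), `a = sharpen_amount` (0.8).
   Integer planes are clipped back to their dtype range.
2. **Halo threshold** — a pixel is halo iff it strictly exceeds
   `(2 − s)` times the mean of its 15×15 neighborhood (reflective
   borders), `s = halo_threshold_sensitivity = 0.55`. The mapping from
   sensitivity to the scale factor is this package's definition: it is
   monotone (higher sensitivity ⇒ lower threshold ⇒ more foreground),
   equals 1.45× the local mean at the default, and makes a constant
   plane yield an all-false mask (strict inequality), which is the
   sensible degenerate answer. Local adaptive thresholding is used
   rather than a single global threshold because illumination varies
   across real fields.
3. **Invert and repair** — the complement makes interiors foreground.
   Holes are then filled *selectively*: a background hole is filled only
   if it is adjacent to exactly one foreground component. This repairs
   genuine intra-cell defects (noise-punched holes) while never filling
   the halo ring itself — the ring is an enclosed background region
   bordered by two components (outer background and cell interior), and
   filling it would fuse every cell with the background into one
   border-touching blob that the next stage would delete. Components
   under `invert_min_component_px` (600) are removed.
4. **Border clearing** — components 8-connected to any edge pixel are
   removed (truncated cells cannot be measured), then components under
   `border_clear_min_component_px` (1200).
5. **Labeling and area band** — 4-connected labeling in raster-scan
   order; areas outside the inclusive band
   [`cell_area_min_px`, `cell_area_max_px`] = [500, 100000] px are
   dropped. Both bounds are inclusive: the filter removes strictly
   smaller and strictly larger objects.
6. **Convexity filter** — per region, `AspectRatio` (major/minor axis of
   the ellipse with identical normalized second central moments; axis
   length = 4·√eigenvalue of the pixel-coordinate covariance) and
   `AreaRatio` (convex hull area / area). A region is kept iff
   `AspectRatio ≥ slope·AreaRatio − intercept` with slope 12.8571 and
   intercept 12.5. Retention is non-strict: a region exactly on the line
   is kept; ties are measure-zero on real data so the choice only needs
   to be fixed. Convex rods have `AreaRatio ≈ 1` and easily clear the
   cutoff (≈ 0.36 at `AreaRatio = 1`); concave fusions of a cell with
   background push `AreaRatio` up until the cutoff exceeds any
   plausible aspect ratio.
7. **Renumber / manual exclusion** — labels compact to 1..N in
   raster-scan order; an explicit index list (CLI `--exclude`) removes
   regions and renumbers. An interactive prompt exists but is opt-in,
   keeping batch runs reproducible.

Touching cells are not split (no watershed); the design accepts false
negatives over false positives.

## Nuclear segmentation and background

Because cytoplasmic expression varies strongly from cell to cell, no
single threshold separates all nuclei. Each cell is processed
independently: Otsu's threshold computed on the cell's own pixel values
(the masked set, not its bounding box), binarized, opened with a
`nuc_opening_struct_px`-square structuring element (5×5), clipped back to
the parent mask, and components under `nuc_min_component_px` (200)
removed. A cell with constant intensity yields no nuclei rather than an
arbitrary split. An optional upper area cap (`nuc_mask_area_cap_px`) is
available but disabled by default: with the 200-px floor active, a
155-px cap would leave no admissible nucleus, so only one of the two can
be meaningful at a time.

The plausibility filter then removes any nucleus whose area exceeds
`nuc_cell_ratio_max` (0.2, strictly) of its parent cell's area: when
nuclear contrast is too low, Otsu admits a large chunk of cytoplasm, and
the resulting "nucleus" is far larger than the ~15 % a real nucleus
occupies. The cell is never deleted — its nuclear mean is reported as 0
and whole-cell fluorescence remains usable.

Per fluorescent channel, the background is the modal intensity of the
whole plane: integer planes use unit-width bins over the attained range,
float planes 256 equal bins over [min, max] (modal bin center); ties
break toward the lowest intensity. The mode is robust here because the
extracellular background dominates the pixel population.

## Measurements and output schema

Cell length/width are the moment-ellipse major/minor axis lengths; area
is the pixel count. With calibration (read from TIFF resolution tags,
converted to µm/px) lengths scale linearly and areas quadratically;
without it, output is in pixels. All intensity columns are means;
nuclear means are taken over the union of a cell's surviving nuclei, in
every (intensity channel *i*, mask channel *j*) permutation, because a
nucleus may segment well in one channel only. Background-subtracted
columns are `mean − mode`; they may go negative, but the 0 sentinel of a
failed nuclear segmentation is passed through unchanged so it cannot
masquerade as a measured value.

The two-channel schema has 11 columns, the three-channel schema 23. The
three-channel column order follows the two-channel prefix with the
channel-3 and cross-channel permutations appended; the final
`2/3: Nuc Area` column reports the area of channel-3-segmented nuclei
alongside the `2/3` intensity permutation, which makes the extension set
symmetric. A bright-field-only input produces a geometry-only table
(index, length, area, width) as a documented extension.

## Synthetic scenes

`halocell.scenes` renders what the pipeline needs from real data and
nothing more: capsule supports (so planted cells are convex rods that
must pass the convexity filter, with a defect mode fusing two capsules
into a concave object that must fail it), a halo as a
morphological-dilation ring (default 4 px) at high intensity, interiors
darker than the background, and fluorescent planes with dim background,
per-cell-jitterable cytoplasm, and nuclear disks. Placement is seeded
rejection sampling with a minimum halo-to-halo clearance (default
2·halo width) so rings never merge; border-truncated cells can be
planted deliberately to exercise border clearing.

Default conditions: 16-bit-like counts (background 1000, interior 400,
halo 3000; fluorescent background 100, cytoplasm 500, nucleus 2000),
additive Gaussian noise σ = 20, cell lengths 55–90 px and widths
28–34 px (≈ 7–12 µm × 3.6–4.4 µm at a 60× wide-field scale of
~0.13 µm/px), nuclear area fraction 0.16 — the typical 2-D nuclear:cell
area ratio for fission yeast, comfortably under the 0.2 cap. Binucleate
(post-mitotic) cells, when requested, are drawn from the top third of
the length range (post-mitotic cells are near division length) and each
daughter nucleus gets 2^(−2/3) of the mononucleate cross-section area
(half the volume).

What the generator does **not** model: point-spread-function blur,
photobleaching, camera noise statistics, uneven illumination, touching
or overlapping cells, and partially defocused halos. Passing the
ground-truth-recovery tests therefore demonstrates the correctness of
the algorithmic chain under clean imaging assumptions, not robustness to
degraded real-world acquisitions — on real data the practical failure
mode is false negatives, which the filters are deliberately biased
toward.

A note on length accuracy: the moment-equivalent major axis of a
uniform capsule exceeds its end-to-end length (by ~15 % for a thin
rectangle, 0 % for a disk; ~8–9 % at the default aspect ratios). The
end-to-end recovery tests bound length error at 10 % against planted
end-to-end lengths, which the default geometry satisfies analytically;
users comparing to manual tip-to-tip measurements should expect the
same systematic offset, which is a property of moment-based length on
rods, not an implementation artifact.

## Numerical and design choices

- Image origin is top-left, coordinates are (row, column), labels are
  assigned in raster-scan order of first-encountered pixels —
  determinism over cosmetics.
- Small-object removals that mirror a morphological area-opening use
  8-connectivity; cell and nucleus labeling use 4-connectivity; border
  contact uses 8-connectivity.
- TIFF is the native format (pages preferred over samples for channel
  layout); other containers attach via `register_reader` without the
  core parsing them. Calibration precision is limited by the 32-bit
  TIFF rational (~10⁻⁵ relative), far below physical relevance.
- Two runs with identical inputs, options, and parameters produce
  byte-identical CSVs; scenes are pure functions of their `SceneSpec`.

## Problem sizes

Tests run on 512²–1024² scenes with 5–20 cells; the end-to-end recovery
check uses 20 well-separated zero-noise cells on 1024², and oracle
(brute-force enumeration) checks use a single cell on 128². These sizes
give every filter a populated decision boundary while keeping the full
suite fast.

## Known limitations

- No watershed splitting: dense fields lose touching cells (by design).
- The halo must be a closed, bright ring; badly focused images fail
  upstream of any filter.
- The sensitivity→threshold mapping is this package's own; other
  adaptive-threshold implementations will need a re-tuned sensitivity.
- One image per invocation; batch processing is a shell loop.
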