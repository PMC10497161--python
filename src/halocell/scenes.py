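"""Synthetic fission-yeast scenes with exact ground truth.

The generator emulates the image features the pipeline relies on:

* a defocused bright-field plane in which every rod-shaped (capsule) cell
  is ringed by a narrow bright halo over a mid-grey background, with the
  cell interior darker than the background;
* fluorescent planes with a dim extracellular background, brighter
  cytoplasm (optionally jittered per cell, since cytoplasmic levels vary
  from cell to cell), and bright nuclear disks.

Cells are capsules — rectangles with semicircular caps — because fission
yeast are convex rods with a large aspect ratio; rendered cleanly they
must pass the convexity filter. A defect mode fuses two capsules at an
angle into a concave object that must fail it. Placement is seeded
rejection sampling with a minimum clearance between halos so that
neighboring rings never merge.

Everything is a pure function of the :class:`SceneSpec` (including its
seed), so scenes are exactly reproducible and every pipeline stage can be
tested against known truth without any real micrograph.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import disk as disk_footprint

from .imgio import MultiChannelImage


def _dilate_local(mask: np.ndarray, structure: np.ndarray) -> np.ndarray:
    """Binary dilation restricted to the mask's padded bounding box."""
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        return mask.copy()
    pad = max(structure.shape) // 2 + 1
    y0, y1 = max(0, rows.min() - pad), min(mask.shape[0], rows.max() + pad + 1)
    x0, x1 = max(0, cols.min() - pad), min(mask.shape[1], cols.max() + pad + 1)
    out = np.zeros_like(mask)
    out[y0:y1, x0:x1] = ndi.binary_dilation(
        mask[y0:y1, x0:x1], structure=structure
    )
    return out


class PlacementError(RuntimeError):
    """Raised when cells cannot be placed without overlap.

    Try fewer or smaller cells, or a larger image.
    """


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of a synthetic scene; the seed makes it fully reproducible.

    Intensity levels are on a 16-bit-like scale. Defaults model a 60x
    widefield acquisition at roughly 0.13 um/px: cell lengths 55-90 px
    (~7-12 um), widths 28-34 px (~3.6-4.4 um), and a nuclear area fraction
    of 0.16 (the 2-D nuclear:cell area ratio typical of fission yeast,
    safely under the 20% plausibility cap).
    """

    image_size: tuple[int, int] = (768, 768)
    n_cells: int = 12
    length_range: tuple[float, float] = (55.0, 90.0)
    width_range: tuple[float, float] = (28.0, 34.0)
    halo_width: int = 4
    halo_intensity: float = 3000.0
    interior_intensity: float = 400.0
    background_intensity: float = 1000.0
    cytoplasm_intensity: float = 500.0
    nucleus_intensity: float = 2000.0
    fluor_background_intensity: float = 100.0
    nucleus_area_fraction: float = 0.16
    cytoplasm_jitter_sd: float = 0.0
    binucleate_fraction: float = 0.0
    noise_sd: float = 20.0
    channel_count: int = 2
    n_defects: int = 0
    n_border_cells: int = 0
    min_gap: Optional[int] = None  # default: 2 * halo_width
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.nucleus_area_fraction < 1.0):
            raise ValueError("nucleus_area_fraction must be in (0, 1)")
        if not self.halo_intensity > self.background_intensity:
            raise ValueError("halo_intensity must exceed background_intensity")
        if not self.nucleus_intensity > self.cytoplasm_intensity:
            raise ValueError("nucleus_intensity must exceed cytoplasm_intensity")
        if self.channel_count not in (1, 2, 3):
            raise ValueError("channel_count must be 1, 2, or 3")

    @property
    def gap(self) -> int:
        return 2 * self.halo_width if self.min_gap is None else self.min_gap


@dataclass
class NucleusTruth:
    """A planted nuclear disk."""

    center: tuple[float, float]
    radius: float
    parent: int
    intensity: float


@dataclass
class CellTruth:
    """One planted cell: pose, size, rasterized support, and its nuclei."""

    center: tuple[float, float]
    orientation: float
    length: float
    width: float
    support: np.ndarray
    touches_border: bool = False
    is_defect: bool = False
    nuclei: list[NucleusTruth] = field(default_factory=list)

    @property
    def area_px(self) -> int:
        return int(self.support.sum())


@dataclass
class GroundTruth:
    """All planted objects of a scene."""

    cells: list[CellTruth] = field(default_factory=list)

    @property
    def interior_cells(self) -> list[CellTruth]:
        return [c for c in self.cells
                if not c.touches_border and not c.is_defect]


# ---------------------------------------------------------------------------
# Geometry


def generate_cell_support(
    length: float,
    width: float,
    orientation: float,
    center: tuple[float, float],
    image_size: tuple[int, int],
) -> np.ndarray:
    """Rasterize a capsule (rod with semicircular caps) at the given pose.

    ``length`` is end-to-end (caps included); a pixel belongs to the
    capsule iff its center lies within ``width/2`` of the central axis
    segment. ``length == width`` degenerates to a disk.
    """
    if not length >= width or width <= 0:
        raise ValueError("capsule requires length >= width > 0")
    h, w = image_size
    r = width / 2.0
    half = max(0.0, (length - width) / 2.0)
    cy, cx = center
    dy, dx = np.sin(orientation), np.cos(orientation)
    # evaluate only over the capsule's bounding window
    reach = length / 2.0 + 2.0
    y0, y1 = max(0, int(cy - reach)), min(h, int(cy + reach) + 2)
    x0, x1 = max(0, int(cx - reach)), min(w, int(cx + reach) + 2)
    out = np.zeros((h, w), dtype=bool)
    if y0 >= y1 or x0 >= x1:
        return out
    yy, xx = np.mgrid[y0:y1, x0:x1]
    # signed coordinates along / across the axis
    py = yy + 0.0 - cy
    px = xx + 0.0 - cx
    along = py * dy + px * dx
    along_clamped = np.clip(along, -half, half)
    dist2 = (py - along_clamped * dy) ** 2 + (px - along_clamped * dx) ** 2
    out[y0:y1, x0:x1] = dist2 <= r * r
    return out


def _fused_capsule_support(
    length: float,
    width: float,
    orientation: float,
    center: tuple[float, float],
    image_size: tuple[int, int],
    bend: float = np.pi / 2,
) -> np.ndarray:
    """Two capsules sharing an endpoint at an angle: a concave defect."""
    cy, cx = center
    half = length / 2.0
    end_y = cy + half * np.sin(orientation)
    end_x = cx + half * np.cos(orientation)
    second = orientation + bend
    c2y = end_y + half * np.sin(second)
    c2x = end_x + half * np.cos(second)
    a = generate_cell_support(length, width, orientation, (cy, cx), image_size)
    b = generate_cell_support(length, width, second, (c2y, c2x), image_size)
    return a | b


def exact_area_blob(
    area_px: int,
    image_size: tuple[int, int],
    top_left: tuple[int, int] = (0, 0),
) -> np.ndarray:
    """Compact 4-connected blob with an exact pixel count.

    Fills rows of a near-square footprint in raster order until exactly
    ``area_px`` pixels are set; used for sweeping area filters in 1-px
    steps.
    """
    if area_px < 0:
        raise ValueError("area_px must be non-negative")
    h, w = image_size
    y0, x0 = top_left
    side = int(np.ceil(np.sqrt(max(area_px, 1))))
    full_rows, rest = divmod(area_px, side)
    if y0 + full_rows + (1 if rest else 0) > h or x0 + side > w:
        raise ValueError(
            f"blob of {area_px} px does not fit at {top_left} in {image_size}"
        )
    mask = np.zeros((h, w), dtype=bool)
    mask[y0:y0 + full_rows, x0:x0 + side] = True
    if rest:
        mask[y0 + full_rows, x0:x0 + rest] = True
    return mask


# ---------------------------------------------------------------------------
# Placement


def _place_objects(spec: SceneSpec, rng: np.random.Generator) -> GroundTruth:
    h, w = spec.image_size
    occupancy = np.zeros((h, w), dtype=bool)
    clearance = disk_footprint(spec.halo_width + spec.gap)
    halo_pad = disk_footprint(spec.halo_width)
    truth = GroundTruth()
    max_attempts = 200

    def try_place(make_support, touches_border: bool, is_defect: bool,
                  length: float, width: float) -> Optional[CellTruth]:
        for _ in range(max_attempts):
            orientation = float(rng.uniform(0.0, np.pi))
            margin = length / 2.0 + spec.halo_width + 2
            if touches_border:
                # center sits on the border so the support is truncated
                edge = int(rng.integers(0, 4))
                if edge == 0:
                    cy, cx = 0.0, float(rng.uniform(margin, w - margin))
                elif edge == 1:
                    cy, cx = float(h - 1), float(rng.uniform(margin, w - margin))
                elif edge == 2:
                    cy, cx = float(rng.uniform(margin, h - margin)), 0.0
                else:
                    cy, cx = float(rng.uniform(margin, h - margin)), float(w - 1)
            else:
                if margin >= h - margin or margin >= w - margin:
                    raise PlacementError(
                        "image too small for requested cell sizes"
                    )
                cy = float(rng.uniform(margin, h - margin))
                cx = float(rng.uniform(margin, w - margin))
            support = make_support(length, width, orientation, (cy, cx))
            if not support.any():
                continue
            padded = _dilate_local(support, halo_pad)
            if (padded & occupancy).any():
                continue
            occupancy[_dilate_local(support, clearance)] = True
            return CellTruth(
                center=(cy, cx), orientation=orientation, length=length,
                width=width, support=support,
                touches_border=touches_border, is_defect=is_defect,
            )
        return None

    def capsule(length, width, orientation, center):
        return generate_cell_support(
            length, width, orientation, center, spec.image_size
        )

    def defect(length, width, orientation, center):
        return _fused_capsule_support(
            length, width, orientation, center, spec.image_size
        )

    binucleate_flags: list[bool] = []
    for kind, count in (("cell", spec.n_cells),
                        ("border", spec.n_border_cells),
                        ("defect", spec.n_defects)):
        for _ in range(count):
            lo, hi = spec.length_range
            two = (kind == "cell"
                   and spec.binucleate_fraction > 0
                   and rng.uniform() < spec.binucleate_fraction)
            if two:
                # post-mitotic cells are the longest (near division length)
                length = float(rng.uniform(lo + 2.0 * (hi - lo) / 3.0, hi))
            else:
                length = float(rng.uniform(lo, hi))
            width = float(rng.uniform(*spec.width_range))
            placed = try_place(
                defect if kind == "defect" else capsule,
                touches_border=(kind == "border"),
                is_defect=(kind == "defect"),
                length=length, width=width,
            )
            if placed is None:
                raise PlacementError(
                    f"could not place all requested objects on "
                    f"{spec.image_size}; try fewer or smaller cells"
                )
            truth.cells.append(placed)
            binucleate_flags.append(two)

    # plant nuclei in ordinary cells (defects get none)
    for idx, cell in enumerate(truth.cells):
        if cell.is_defect or spec.channel_count < 2:
            continue
        area = cell.area_px
        fraction = spec.nucleus_area_fraction
        if binucleate_flags[idx]:
            # each daughter nucleus carries half the volume, hence
            # 2**(-2/3) of the mononucleate cross-section area
            r = float(np.sqrt(fraction * area * 2.0 ** (-2.0 / 3.0) / np.pi))
            offset = cell.length / 4.0
            centers = []
            for sign in (-1.0, 1.0):
                centers.append((
                    cell.center[0] + sign * offset * np.sin(cell.orientation),
                    cell.center[1] + sign * offset * np.cos(cell.orientation),
                ))
        else:
            r = float(np.sqrt(fraction * area / np.pi))
            centers = [cell.center]
        for c in centers:
            cell.nuclei.append(NucleusTruth(
                center=c, radius=r, parent=idx,
                intensity=spec.nucleus_intensity,
            ))
    return truth


# ---------------------------------------------------------------------------
# Rendering


def _finalize(plane: np.ndarray, noise_sd: float,
              rng: np.random.Generator) -> np.ndarray:
    if noise_sd > 0:
        plane = plane + rng.normal(0.0, noise_sd, size=plane.shape)
    return np.clip(np.rint(plane), 0, 65535).astype(np.uint16)


def render_brightfield(
    gt: GroundTruth,
    spec: SceneSpec,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Render the defocused bright-field plane: halo rings around interiors.

    Background at ``background_intensity``, cell interiors at
    ``interior_intensity``, and a ``halo_width``-px dilation ring around
    each support at ``halo_intensity``; Gaussian noise of ``noise_sd``
    added and the result quantized to uint16.
    """
    rng = np.random.default_rng(spec.seed + 1) if rng is None else rng
    plane = np.full(spec.image_size, spec.background_intensity, dtype=np.float64)
    pad = disk_footprint(spec.halo_width)
    for cell in gt.cells:
        halo = _dilate_local(cell.support, pad) & ~cell.support
        plane[halo] = spec.halo_intensity
        plane[cell.support] = spec.interior_intensity
    return _finalize(plane, spec.noise_sd, rng)


def render_fluorescence(
    gt: GroundTruth,
    spec: SceneSpec,
    channel: int = 2,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Render a fluorescent plane: dim background, cytoplasm, nuclear disks.

    Cytoplasm intensity is optionally jittered per cell
    (``cytoplasm_jitter_sd``, emulating cell-to-cell expression
    variability); nuclear disks render at ``nucleus_intensity``.
    """
    rng = np.random.default_rng(spec.seed + 10 * channel) if rng is None else rng
    plane = np.full(
        spec.image_size, spec.fluor_background_intensity, dtype=np.float64
    )
    h, w = spec.image_size
    for cell in gt.cells:
        cyto = spec.cytoplasm_intensity
        if spec.cytoplasm_jitter_sd > 0:
            cyto = max(
                spec.fluor_background_intensity + 1.0,
                cyto + float(rng.normal(0.0, spec.cytoplasm_jitter_sd)),
            )
        plane[cell.support] = cyto
        for nuc in cell.nuclei:
            r = nuc.radius
            y0, y1 = max(0, int(nuc.center[0] - r) - 1), min(h, int(nuc.center[0] + r) + 2)
            x0, x1 = max(0, int(nuc.center[1] - r) - 1), min(w, int(nuc.center[1] + r) + 2)
            yy, xx = np.mgrid[y0:y1, x0:x1]
            d2 = (yy - nuc.center[0]) ** 2 + (xx - nuc.center[1]) ** 2
            plane[y0:y1, x0:x1][(d2 <= r * r) & cell.support[y0:y1, x0:x1]] = nuc.intensity
    return _finalize(plane, spec.noise_sd, rng)


def generate_scene(spec: SceneSpec) -> tuple[MultiChannelImage, GroundTruth]:
    """Generate a full multi-channel scene plus its ground truth.

    Placement, rendering, and noise all derive from ``spec.seed``; the
    same spec always yields bit-identical planes and truth.
    """
    rng = np.random.default_rng(spec.seed)
    truth = _place_objects(spec, rng)
    planes = [render_brightfield(truth, spec, rng)]
    for channel in range(2, spec.channel_count + 1):
        planes.append(render_fluorescence(truth, spec, channel, rng))
    return MultiChannelImage(planes=planes), truth
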