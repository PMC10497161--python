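"""Cell segmentation from the defocused bright-field channel.

Fission-yeast cells imaged slightly out of focus are ringed by a narrow
bright halo. The segmentation strategy is: sharpen, threshold the halos
with a local-mean adaptive threshold, invert so cell interiors become
foreground, repair small defects, drop border-touching and out-of-band
components, and finally reject concave shapes that cannot be rod-shaped
cells using the aspect-ratio vs. area-ratio decision line.

All stages are pure functions from arrays (plus parameters) to arrays, so
each one is testable in isolation and the composition is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.measure import label as sk_label
from skimage.measure import regionprops

from .params import PipelineParameters


class RegionMismatchError(ValueError):
    """Raised when shape records do not correspond to the label map."""


class UnknownRegionError(ValueError):
    """Raised when a deletion index does not name an existing region."""


@dataclass(frozen=True)
class RegionShape:
    """Geometry bundle for one labeled region.

    ``aspect_ratio`` is major/minor axis length of the moment-equivalent
    ellipse; ``area_ratio`` is convex-hull area over actual area (1 for
    convex shapes, > 1 for concave ones).
    """

    label: int
    area_px: int
    convex_area_px: int
    major_axis_px: float
    minor_axis_px: float
    aspect_ratio: float
    area_ratio: float


def _connectivity_arg(conn: int) -> int:
    # skimage/scipy express 4/8-connectivity as 1/2 (orthogonal steps)
    return 1 if conn == 4 else 2


def _remove_small(mask: np.ndarray, min_size: int, connectivity: int) -> np.ndarray:
    """Drop components with strictly fewer than ``min_size`` pixels."""
    labels = sk_label(mask, connectivity=connectivity)
    if labels.max() == 0:
        return mask.copy()
    areas = np.bincount(labels.ravel())
    bad = np.nonzero(areas < min_size)[0]
    bad = bad[bad > 0]
    if bad.size == 0:
        return mask.copy()
    return mask & ~np.isin(labels, bad)


# ---------------------------------------------------------------------------
# Steps 2-4: sharpen, threshold, invert/repair


def sharpen(plane: np.ndarray, p: PipelineParameters) -> np.ndarray:
    """Unsharp-mask the bright-field plane to crisp up the halos.

    Computes ``I + amount * (I - G_sigma(I))`` with sigma
    ``sharpen_radius_px``. Integer inputs are clipped to their dtype range
    and returned in that dtype; float inputs are returned as float64.
    """
    arr = np.asarray(plane, dtype=np.float64)
    blurred = ndi.gaussian_filter(arr, sigma=p.sharpen_radius_px)
    out = arr + p.sharpen_amount * (arr - blurred)
    if np.issubdtype(np.asarray(plane).dtype, np.integer):
        info = np.iinfo(np.asarray(plane).dtype)
        return np.clip(np.rint(out), info.min, info.max).astype(plane.dtype)
    return out


def threshold_halos(plane: np.ndarray, p: PipelineParameters) -> np.ndarray:
    """Binary mask of the bright halos via a local-mean adaptive threshold.

    A pixel is halo foreground iff it strictly exceeds
    ``(2 - sensitivity) * local_mean`` where the local mean is taken over a
    square ``halo_threshold_neighborhood`` window (reflective borders).
    Higher sensitivity therefore marks more pixels as foreground; a
    constant plane yields an all-false mask.
    """
    arr = np.asarray(plane, dtype=np.float64)
    size = p.halo_threshold_neighborhood
    local_mean = ndi.uniform_filter(arr, size=size, mode="reflect")
    scale = 2.0 - p.halo_threshold_sensitivity
    return arr > scale * local_mean


def _fill_holes_selective(mask: np.ndarray) -> np.ndarray:
    """Fill background holes that are enclosed by a single component.

    A hole bordered by two or more distinct foreground components (e.g. the
    halo ring separating a cell interior from the outer background) is a
    genuine separator and is left open; filling it would merge objects.
    """
    fg_labels = sk_label(mask, connectivity=2)
    holes = sk_label(~mask, connectivity=1)
    border = np.zeros_like(mask, dtype=bool)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    border_hole_ids = np.unique(holes[border & ~mask])
    out = mask.copy()
    for sl, hole_id in zip(ndi.find_objects(holes),
                           range(1, holes.max() + 1)):
        if sl is None or hole_id in border_hole_ids:
            continue
        sl = tuple(slice(max(s.start - 1, 0), s.stop + 1) for s in sl)
        hole = holes[sl] == hole_id
        ring = ndi.binary_dilation(hole, structure=np.ones((3, 3))) & ~hole
        neighbors = np.unique(fg_labels[sl][ring])
        neighbors = neighbors[neighbors > 0]
        if len(neighbors) == 1:
            out[sl][hole] = True
    return out


def invert_and_repair(halos: np.ndarray, p: PipelineParameters) -> np.ndarray:
    """Invert the halo mask so cells are foreground, then repair defects.

    The complement is hole-filled (selectively: only holes enclosed by a
    single component, so closed halo rings are never filled over) and
    components smaller than ``invert_min_component_px`` are removed.
    """
    cells = ~np.asarray(halos, dtype=bool)
    cells = _fill_holes_selective(cells)
    return _remove_small(cells, p.invert_min_component_px, connectivity=2)


# ---------------------------------------------------------------------------
# Steps 5-5b: border clearing, labeling, area band


def clear_border(cells: np.ndarray, p: PipelineParameters) -> np.ndarray:
    """Drop components touching the image border, then small remnants.

    Border contact is judged under ``border_clear_connectivity``;
    components below ``border_clear_min_component_px`` are removed
    afterwards.
    """
    mask = np.asarray(cells, dtype=bool)
    conn = _connectivity_arg(p.border_clear_connectivity)
    labels = sk_label(mask, connectivity=conn)
    border = np.zeros_like(mask, dtype=bool)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    touching = np.unique(labels[border & mask])
    out = mask & ~np.isin(labels, touching[touching > 0])
    return _remove_small(out, p.border_clear_min_component_px, connectivity=conn)


def relabel(cells: np.ndarray) -> np.ndarray:
    """Compact labels to 1..N in raster-scan order of first pixels."""
    cells = np.asarray(cells)
    labs, first = np.unique(cells.ravel(), return_index=True)
    keep = labs != 0
    labs, first = labs[keep], first[keep]
    if labs.size == 0:
        return np.zeros_like(cells)
    mapping = np.zeros(int(cells.max()) + 1, dtype=cells.dtype)
    mapping[labs[np.argsort(first)]] = np.arange(1, labs.size + 1, dtype=cells.dtype)
    return mapping[cells]


def label_and_area_filter(cells: np.ndarray, p: PipelineParameters) -> np.ndarray:
    """Label components and keep those within the cell area band.

    Components are labeled under ``cell_label_connectivity``; areas outside
    the inclusive band [``cell_area_min_px``, ``cell_area_max_px``] are
    zeroed. Surviving labels are compacted in raster-scan order.
    """
    mask = np.asarray(cells, dtype=bool)
    labels = sk_label(mask, connectivity=_connectivity_arg(p.cell_label_connectivity))
    if labels.max() == 0:
        return labels
    areas = np.bincount(labels.ravel())
    bad = np.nonzero(
        (areas < p.cell_area_min_px) | (areas > p.cell_area_max_px)
    )[0]
    labels[np.isin(labels, bad[bad > 0])] = 0
    return relabel(labels)


# ---------------------------------------------------------------------------
# Steps 6-8: shape metrics, convexity filter, manual deletion


def shape_metrics(cells: np.ndarray) -> list[RegionShape]:
    """Per-region geometry: areas, moment-ellipse axes, and the two ratios.

    Axis lengths come from the ellipse with identical normalized second
    central moments (length = 4 sqrt(largest eigenvalue of the pixel
    coordinate covariance)).
    """
    shapes = []
    for rp in regionprops(np.asarray(cells)):
        minor = float(rp.axis_minor_length)
        major = float(rp.axis_major_length)
        aspect = major / minor if minor > 0 else np.inf
        area = int(rp.area)
        convex = int(rp.area_convex)
        shapes.append(
            RegionShape(
                label=int(rp.label),
                area_px=area,
                convex_area_px=convex,
                major_axis_px=major,
                minor_axis_px=minor,
                aspect_ratio=aspect,
                area_ratio=convex / area,
            )
        )
    return shapes


def convex_filter(
    cells: np.ndarray,
    shapes: list[RegionShape],
    p: PipelineParameters,
) -> np.ndarray:
    """Keep regions on or above the convexity decision line.

    A region survives iff
    ``aspect_ratio >= slope * area_ratio - intercept``. Rod-shaped cells
    (area_ratio near 1, high aspect) pass; concave mis-segmentations
    (area_ratio well above 1) fall below the line and are zeroed.
    """
    cells = np.asarray(cells)
    present = set(np.unique(cells)) - {0}
    by_label = {s.label: s for s in shapes}
    if present != set(by_label):
        raise RegionMismatchError(
            f"shape records for labels {sorted(by_label)} do not match "
            f"label map labels {sorted(present)}"
        )
    out = cells.copy()
    for s in shapes:
        cutoff = p.convex_filter_slope * s.area_ratio - p.convex_filter_intercept
        if not s.aspect_ratio >= cutoff:
            out[out == s.label] = 0
    return out


def remove_regions(cells: np.ndarray, indices: list[int]) -> np.ndarray:
    """Zero the listed labels (user-directed deletions), then relabel."""
    cells = np.asarray(cells)
    valid = {int(v) for v in np.unique(cells)} - {0}
    unknown = [int(i) for i in indices if i not in valid]
    if unknown:
        raise UnknownRegionError(
            f"labels {unknown} not present; valid labels: {sorted(valid)}"
        )
    out = cells.copy()
    for i in indices:
        out[out == i] = 0
    return relabel(out)


def segment_cells(
    plane: np.ndarray,
    p: PipelineParameters,
    exclude_indices: list[int] | None = None,
) -> tuple[np.ndarray, list[RegionShape]]:
    """Run the full bright-field stage chain; return final labels + shapes.

    Convenience composition of sharpen → threshold_halos →
    invert_and_repair → clear_border → label_and_area_filter →
    shape_metrics → convex_filter → relabel → remove_regions.
    """
    sharp = sharpen(plane, p)
    halos = threshold_halos(sharp, p)
    cells = invert_and_repair(halos, p)
    cells = clear_border(cells, p)
    labels = label_and_area_filter(cells, p)
    shapes = shape_metrics(labels)
    labels = relabel(convex_filter(labels, shapes, p))
    labels = remove_regions(labels, exclude_indices or [])
    final_shapes = shape_metrics(labels)
    return labels, final_shapes
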