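"""Nuclear segmentation from fluorescent channels, one cell at a time.

Nuclei carrying a highly expressed fluorescent marker are bright disks over
dimmer cytoplasm, but cytoplasmic background varies from cell to cell, so
no single global threshold works. Each segmented cell is therefore
thresholded independently: Otsu's method on that cell's pixels only,
followed by a binary opening, a small-component floor, and an optional
area cap. A final plausibility filter discards any "nucleus" covering more
than ``nuc_cell_ratio_max`` of its parent cell — those are failed
segmentations where cytoplasm leaked into the nuclear mask — and the
affected cell's nuclear intensity is reported as zero downstream (the cell
itself is never deleted).

The whole-image background estimate is the modal intensity of the channel,
computed once per channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label

from .params import PipelineParameters


class ShapeMismatchError(ValueError):
    """Raised when a fluorescent plane does not match the cell map shape."""


@dataclass(frozen=True)
class BackgroundEstimate:
    """Modal intensity of one fluorescent channel."""

    channel: int
    value: float


@dataclass
class NucleusLabelMap:
    """Nuclei labeled over a fluorescent plane, with parentage.

    ``labels`` uses globally unique labels 1..N; ``parent_cell`` maps each
    nucleus label to the cell label whose mask produced it. Every nucleus
    pixel lies inside its parent cell's mask.
    """

    labels: np.ndarray
    parent_cell: dict[int, int] = field(default_factory=dict)

    @property
    def max_label(self) -> int:
        return int(self.labels.max()) if self.labels.size else 0


def estimate_background(plane: np.ndarray, channel: int = 2) -> BackgroundEstimate:
    """Modal intensity of the plane; ties break toward the lowest value.

    Integer planes use unit-width bins over the attained range; float
    planes use 256 equal bins over [min, max] and return the modal bin
    center.
    """
    arr = np.asarray(plane)
    if np.issubdtype(arr.dtype, np.integer):
        vals = arr.ravel()
        lo = int(vals.min())
        counts = np.bincount((vals - lo).astype(np.int64))
        mode = lo + int(np.argmax(counts))  # argmax takes the first (lowest) tie
        return BackgroundEstimate(channel=channel, value=float(mode))
    vals = arr.ravel().astype(np.float64)
    lo, hi = float(vals.min()), float(vals.max())
    if hi == lo:
        return BackgroundEstimate(channel=channel, value=lo)
    counts, edges = np.histogram(vals, bins=256, range=(lo, hi))
    i = int(np.argmax(counts))
    center = 0.5 * (edges[i] + edges[i + 1])
    return BackgroundEstimate(channel=channel, value=float(center))


def _connectivity_arg(conn: int) -> int:
    return 1 if conn == 4 else 2


def segment_nuclei_per_cell(
    plane: np.ndarray,
    cells: np.ndarray,
    p: PipelineParameters,
) -> NucleusLabelMap:
    """Segment nuclei inside each cell independently.

    Per cell: Otsu's threshold on the cell's own pixels, binary opening
    with a ``nuc_opening_struct_px``-square structuring element (result
    clipped back to the cell mask), removal of components below
    ``nuc_min_component_px`` (and above ``nuc_mask_area_cap_px`` when
    enabled), then labeling under ``nuc_label_connectivity``. Cells with a
    constant intensity yield no nuclei. Labels are globally unique across
    cells, in ascending cell order.
    """
    plane = np.asarray(plane)
    cells = np.asarray(cells)
    if plane.shape != cells.shape:
        raise ShapeMismatchError(
            f"fluorescent plane shape {plane.shape} != cell map shape "
            f"{cells.shape}"
        )
    out = np.zeros(cells.shape, dtype=np.int32)
    parent: dict[int, int] = {}
    next_label = 1
    structure = np.ones((p.nuc_opening_struct_px,) * 2, dtype=bool)
    conn = _connectivity_arg(p.nuc_label_connectivity)
    for cell_label in np.unique(cells):
        if cell_label == 0:
            continue
        mask = cells == cell_label
        values = plane[mask]
        if values.max() == values.min():
            continue  # flat histogram: no separable nucleus
        thr = threshold_otsu(values)
        candidate = mask & (plane > thr)
        candidate = ndi.binary_opening(candidate, structure=structure)
        candidate &= mask  # opening must not leak outside the parent cell
        comp = sk_label(candidate, connectivity=conn)
        for nuc_id in range(1, comp.max() + 1):
            support = comp == nuc_id
            area = int(support.sum())
            if area < p.nuc_min_component_px:
                continue
            if (p.nuc_mask_area_cap_px is not None
                    and area > p.nuc_mask_area_cap_px):
                continue
            out[support] = next_label
            parent[next_label] = int(cell_label)
            next_label += 1
    return NucleusLabelMap(labels=out, parent_cell=parent)


def nucleus_cell_ratio_filter(
    nuclei: NucleusLabelMap,
    cells: np.ndarray,
    p: PipelineParameters,
) -> NucleusLabelMap:
    """Discard nuclei covering too large a fraction of their parent cell.

    A nucleus is removed iff its area / parent-cell area strictly exceeds
    ``nuc_cell_ratio_max`` (a ratio exactly at the cap survives). Cells
    are never removed; a cell left without nuclei reports zero nuclear
    intensity downstream.
    """
    cells = np.asarray(cells)
    cell_areas = np.bincount(cells.ravel())
    labels = nuclei.labels.copy()
    parent: dict[int, int] = {}
    for nuc_label, cell_label in nuclei.parent_cell.items():
        area = int((nuclei.labels == nuc_label).sum())
        ratio = area / cell_areas[cell_label]
        if ratio > p.nuc_cell_ratio_max:
            labels[labels == nuc_label] = 0
        else:
            parent[nuc_label] = cell_label
    # compact labels to 1..N preserving order, keeping parentage aligned
    old = sorted(parent)
    remap = {o: i + 1 for i, o in enumerate(old)}
    out = np.zeros_like(labels)
    for o, n in remap.items():
        out[labels == o] = n
    return NucleusLabelMap(
        labels=out, parent_cell={remap[o]: parent[o] for o in old}
    )


def count_nuclei(nuclei: NucleusLabelMap, cells: np.ndarray) -> dict[int, int]:
    """Map each cell label to its surviving nucleus count (0, 1, 2, ...)."""
    counts = {int(lab): 0 for lab in np.unique(cells) if lab != 0}
    for cell_label in nuclei.parent_cell.values():
        counts[cell_label] += 1
    return counts
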