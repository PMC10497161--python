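"""Per-cell measurement and assembly of the fixed-schema results table.

Cell geometry comes from the moment-equivalent ellipse of each labeled
region (length = major axis, width = minor axis) plus the raw pixel count
for area; with pixel-size calibration present, lengths scale by the
micron-per-pixel factor and areas by its square. Fluorescent readouts are
mean intensities over nuclear or whole-cell masks; every reported
intensity also appears background-subtracted, where the background is the
channel's modal intensity.

The output schema is fixed: 11 columns for a two-channel image, 23 for a
three-channel image. Headers are ``prefix: Name`` where the prefix names
the source channel, and fraction-style prefixes ``i/j`` mean "intensity
from channel i over the mask segmented from channel j". With two
fluorescent channels all four (i, j) nuclear-mean permutations are
reported so users can pick the mask channel that segmented best.

A cell whose nucleus could not be segmented (or was discarded by the
nucleus:cell ratio filter) reports 0 for its nuclear means; the 0 is a
sentinel and is preserved through background subtraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import pandas as pd
from skimage.measure import regionprops

from .imgio import Calibration
from .nuclear import BackgroundEstimate, NucleusLabelMap


class ChannelMismatchError(ValueError):
    """Raised when a value and a background come from different channels."""


class IndexMismatchError(ValueError):
    """Raised when per-cell inputs disagree on the set of cell indices."""


class MeasureShapeError(ValueError):
    """Raised when a plane does not match the label map shape."""


@dataclass
class CellRecord:
    """Geometry plus whole-cell fluorescence for one retained cell."""

    index: int
    length: float
    width: float
    area: float
    whole_cell_mean_intensity: dict[int, float] = field(default_factory=dict)
    units_flag: str = "pixels"  # or "microns"


@dataclass
class NucleusRecord:
    """Nuclear union area and per-channel means for one (cell, mask) pair.

    ``area`` is the union area of the cell's surviving nuclei segmented
    from ``mask_channel`` (0 when none); ``mean_intensity`` maps each
    fluorescent channel i to the mean of channel-i pixels over that union
    (0 when none).
    """

    parent_index: int
    mask_channel: int
    area: float
    mean_intensity: dict[int, float] = field(default_factory=dict)


@dataclass
class ResultsTable:
    """Ordered headers plus one row per retained cell (sorted by index)."""

    headers: list[str]
    rows: list[list]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=self.headers)


def measure_geometry(
    cells: np.ndarray,
    cal: Optional[Calibration] = None,
) -> list[CellRecord]:
    """Measure length, width, and area per cell, applying calibration.

    Length and width are the major/minor axis lengths of the region's
    moment-equivalent ellipse; area is the pixel count. With calibration,
    lengths are in microns and areas in square microns; otherwise all
    values stay in pixel units.
    """
    scale = cal.microns_per_pixel if cal is not None and cal.present else None
    records = []
    for rp in regionprops(np.asarray(cells)):
        length = float(rp.axis_major_length)
        width = float(rp.axis_minor_length)
        area = float(rp.area)
        if scale is not None:
            length *= scale
            width *= scale
            area *= scale * scale
        records.append(
            CellRecord(
                index=int(rp.label),
                length=length,
                width=width,
                area=area,
                units_flag="microns" if scale is not None else "pixels",
            )
        )
    return sorted(records, key=lambda r: r.index)


def measure_whole_cell_intensity(
    plane: np.ndarray,
    cells: np.ndarray,
) -> dict[int, float]:
    """Mean intensity of the plane over each cell's mask."""
    plane = np.asarray(plane)
    cells = np.asarray(cells)
    if plane.shape != cells.shape:
        raise MeasureShapeError(
            f"plane shape {plane.shape} != cell map shape {cells.shape}"
        )
    out = {}
    for lab in np.unique(cells):
        if lab == 0:
            continue
        out[int(lab)] = float(plane[cells == lab].mean())
    return out


def measure_nuclear_intensity(
    plane: np.ndarray,
    nuclei: NucleusLabelMap,
    cells: np.ndarray,
) -> dict[int, float]:
    """Mean plane intensity over each cell's union of surviving nuclei.

    Cells without surviving nuclei report the 0 sentinel. The plane may be
    a different fluorescent channel than the one the nuclei were segmented
    from (the i/j permutations of the output table).
    """
    plane = np.asarray(plane)
    if plane.shape != nuclei.labels.shape:
        raise MeasureShapeError(
            f"plane shape {plane.shape} != nucleus map shape "
            f"{nuclei.labels.shape}"
        )
    out = {int(lab): 0.0 for lab in np.unique(cells) if lab != 0}
    per_cell_pixels: dict[int, list[np.ndarray]] = {}
    for nuc_label, cell_label in nuclei.parent_cell.items():
        per_cell_pixels.setdefault(cell_label, []).append(
            plane[nuclei.labels == nuc_label]
        )
    for cell_label, chunks in per_cell_pixels.items():
        vals = np.concatenate(chunks)
        out[int(cell_label)] = float(vals.mean())
    return out


def nuclear_union_area(
    nuclei: NucleusLabelMap,
    cells: np.ndarray,
    cal: Optional[Calibration] = None,
) -> dict[int, float]:
    """Union area of surviving nuclei per cell (0 when none), calibrated."""
    scale = cal.microns_per_pixel if cal is not None and cal.present else None
    out = {int(lab): 0.0 for lab in np.unique(cells) if lab != 0}
    for nuc_label, cell_label in nuclei.parent_cell.items():
        area = float((nuclei.labels == nuc_label).sum())
        if scale is not None:
            area *= scale * scale
        out[int(cell_label)] += area
    return out


def subtract_background(
    value: float,
    bg: BackgroundEstimate,
    value_channel: Optional[int] = None,
) -> float:
    """Background-subtract a mean intensity, preserving the 0 sentinel.

    A value of exactly 0 marks a cell without a segmented nucleus and is
    returned unchanged (0 − bg would masquerade as data). Other values may
    legitimately go negative. When ``value_channel`` is given it must
    match the background's channel.
    """
    if value_channel is not None and value_channel != bg.channel:
        raise ChannelMismatchError(
            f"value from channel {value_channel} cannot be corrected with "
            f"channel {bg.channel} background"
        )
    if value == 0:
        return 0.0
    return value - bg.value


def two_channel_headers() -> list[str]:
    return [
        "1: Cell Index",
        "2: Num Nuclei",
        "1: Cell Length",
        "2/2: Nuc Area",
        "1: Cell Area",
        "2/2: Mean Nuc Int",
        "1: Cell Width",
        "2/1: Whole Cell Int",
        "2: Background Int",
        "2/2: Nuc Int-bg",
        "2/1: Whole Cell Int-bg",
    ]


def three_channel_headers() -> list[str]:
    return two_channel_headers() + [
        "3/2: Mean Nuc Int",
        "3/3: Nuc Area",
        "3/3: Mean Nuc Int",
        "2/3: Mean Nuc Int",
        "3/1: Whole Cell Int",
        "3: Background Int",
        "3/3: Nuc Int-bg",
        "3/1: Whole Cell Int-bg",
        "3/2: Nuc Int-bg",
        "2/3: Nuc Int-bg",
        "3: Num Nuclei",
        "2/3: Nuc Area",
    ]


def geometry_only_headers() -> list[str]:
    return ["1: Cell Index", "1: Cell Length", "1: Cell Area", "1: Cell Width"]


def assemble_table(
    cells: list[CellRecord],
    nuclei: list[NucleusRecord],
    counts: dict[int, dict[int, int]],
    bgs: dict[int, BackgroundEstimate],
    channel_count: int,
) -> ResultsTable:
    """Assemble the fixed-schema per-cell results table.

    ``counts`` maps mask channel → (cell index → nucleus count); ``bgs``
    maps fluorescent channel → background estimate; ``nuclei`` holds one
    record per (cell, mask channel). Two-channel images yield the
    11-column schema, three-channel images the 23-column schema, and
    bright-field-only images a geometry-only table.
    """
    indices = [c.index for c in cells]
    cell_by_index = {c.index: c for c in cells}
    if channel_count == 1:
        rows = [
            [c.index, c.length, c.area, c.width]
            for c in sorted(cells, key=lambda c: c.index)
        ]
        return ResultsTable(headers=geometry_only_headers(), rows=rows)

    nuc_by_key = {(n.parent_index, n.mask_channel): n for n in nuclei}
    mask_channels = list(range(2, channel_count + 1))
    for j in mask_channels:
        if j not in counts:
            raise IndexMismatchError(f"missing nucleus counts for channel {j}")
        if set(counts[j]) != set(indices):
            raise IndexMismatchError(
                f"channel-{j} counts cover cells {sorted(counts[j])}, "
                f"geometry covers {sorted(indices)}"
            )
        for idx in indices:
            if (idx, j) not in nuc_by_key:
                raise IndexMismatchError(
                    f"no nucleus record for cell {idx}, mask channel {j}"
                )
    for ch in mask_channels:
        if ch not in bgs:
            raise IndexMismatchError(f"missing background for channel {ch}")

    def nuc(idx: int, j: int) -> NucleusRecord:
        return nuc_by_key[(idx, j)]

    rows = []
    for idx in sorted(indices):
        c = cell_by_index[idx]
        bg2 = bgs[2]
        row = [
            idx,
            counts[2][idx],
            c.length,
            nuc(idx, 2).area,
            c.area,
            nuc(idx, 2).mean_intensity[2],
            c.width,
            c.whole_cell_mean_intensity[2],
            bg2.value,
            subtract_background(nuc(idx, 2).mean_intensity[2], bg2, 2),
            subtract_background(c.whole_cell_mean_intensity[2], bg2, 2),
        ]
        if channel_count == 3:
            bg3 = bgs[3]
            row += [
                nuc(idx, 2).mean_intensity[3],
                nuc(idx, 3).area,
                nuc(idx, 3).mean_intensity[3],
                nuc(idx, 3).mean_intensity[2],
                c.whole_cell_mean_intensity[3],
                bg3.value,
                subtract_background(nuc(idx, 3).mean_intensity[3], bg3, 3),
                subtract_background(c.whole_cell_mean_intensity[3], bg3, 3),
                subtract_background(nuc(idx, 2).mean_intensity[3], bg3, 3),
                subtract_background(nuc(idx, 3).mean_intensity[2], bg2, 2),
                counts[3][idx],
                nuc(idx, 3).area,
            ]
        rows.append(row)

    headers = (
        three_channel_headers() if channel_count == 3 else two_channel_headers()
    )
    return ResultsTable(headers=headers, rows=rows)
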