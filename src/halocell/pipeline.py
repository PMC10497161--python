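"""End-to-end orchestration: image in, CSV + overlay(s) out.

:func:`run_pipeline` wires the stages in workflow order: read the image,
segment cells from the bright-field channel, optionally drop user-listed
regions, segment and filter nuclei per fluorescent channel, measure
geometry and intensities, assemble the fixed-schema table, and write the
CSV plus one overlay per fluorescent channel. The run is fully
deterministic: identical inputs, options, and parameters produce
byte-identical CSVs.

The one interactive quality-control step of the workflow (manual region
deletion) is expressed as an explicit ``exclude_indices`` list so that
batch runs are reproducible; an interactive prompt is opt-in.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence, Union

import numpy as np

from . import brightfield as bf
from . import imgio, measure, nuclear
from .params import PipelineParameters, default_parameters, load_parameters


class ChannelOrderError(ValueError):
    """Raised when a channel reordering is not a valid permutation."""


@dataclass
class RunOptions:
    """Options for one pipeline invocation."""

    input_path: Union[str, Path]
    output_dir: Union[str, Path]
    params_path: Optional[Union[str, Path]] = None
    exclude_indices: list[int] = field(default_factory=list)
    interactive: bool = False
    save_stages: bool = False
    channel_order: Optional[Sequence[int]] = None


@dataclass
class RunSummary:
    """What a run produced: object counts and output paths."""

    n_cells: int
    nuclei_per_channel: dict[int, int]
    csv_path: Path
    overlay_paths: list[Path]
    stage_paths: list[Path] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


def _log(msg: str) -> None:
    print(msg, file=sys.stderr)


def _reorder(image: imgio.MultiChannelImage,
             order: Optional[Sequence[int]]) -> imgio.MultiChannelImage:
    if order is None:
        return image
    order = list(order)
    if sorted(order) != list(range(1, image.channel_count + 1)):
        raise ChannelOrderError(
            f"channel_order {order} is not a permutation of "
            f"1..{image.channel_count}"
        )
    return imgio.MultiChannelImage(planes=[image.plane(c) for c in order])


def _save_stage(dir_: Path, number: int, name: str,
                array: np.ndarray, paths: list[Path]) -> None:
    from PIL import Image

    arr = np.asarray(array)
    if arr.dtype == bool:
        out = (arr * 255).astype(np.uint8)
    else:
        arr = arr.astype(np.float64)
        lo, hi = arr.min(), arr.max()
        out = (np.zeros(arr.shape, dtype=np.uint8) if hi <= lo
               else ((arr - lo) / (hi - lo) * 255).astype(np.uint8))
    path = dir_ / f"stage_{number:02d}_{name}.png"
    Image.fromarray(out).save(path)
    paths.append(path)


def _interactive_exclusions(labels: np.ndarray) -> list[int]:
    valid = sorted(set(np.unique(labels)) - {0})
    raw = input(
        f"Cells {valid} segmented; enter comma-separated indices to "
        "delete (empty = none): "
    )
    raw = raw.strip()
    return [int(tok) for tok in raw.split(",") if tok.strip()] if raw else []


def run_pipeline(opts: RunOptions) -> RunSummary:
    """Run the full workflow on one image; returns a :class:`RunSummary`.

    Zero retained cells is not an error: a header-only CSV is written and
    a warning recorded.
    """
    outdir = Path(opts.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    p = (load_parameters(opts.params_path) if opts.params_path
         else default_parameters())

    image, cal = imgio.read_image(opts.input_path)
    image = _reorder(image, opts.channel_order)
    _log(f"[1] read {opts.input_path}: {image.channel_count} channel(s), "
         f"calibration "
         f"{'%.4g um/px' % cal.microns_per_pixel if cal.present else 'absent'}")

    stage_paths: list[Path] = []
    if opts.save_stages:
        for old in outdir.glob("stage_*.png"):
            old.unlink()

    def stage(number: int, name: str, array: np.ndarray) -> None:
        if opts.save_stages:
            _save_stage(outdir, number, name, array, stage_paths)

    plane = image.brightfield
    sharp = bf.sharpen(plane, p)
    stage(2, "sharpen", sharp)
    halos = bf.threshold_halos(sharp, p)
    stage(3, "threshold_halos", halos)
    cells_mask = bf.invert_and_repair(halos, p)
    stage(4, "invert_and_repair", cells_mask)
    cells_mask = bf.clear_border(cells_mask, p)
    stage(5, "clear_border", cells_mask)
    labels = bf.label_and_area_filter(cells_mask, p)
    _log(f"[5b] area filter: {int(labels.max())} candidate cell(s)")
    stage(6, "label_and_area_filter", labels)
    shapes = bf.shape_metrics(labels)
    labels = bf.relabel(bf.convex_filter(labels, shapes, p))
    _log(f"[6-7] convexity filter: {int(labels.max())} cell(s) retained")
    stage(7, "convex_filter", labels)

    exclude = list(opts.exclude_indices)
    if opts.interactive:
        exclude += _interactive_exclusions(labels)
    labels = bf.remove_regions(labels, exclude)
    if exclude:
        _log(f"[8] removed regions {exclude}: {int(labels.max())} cell(s)")
    stage(8, "remove_regions", labels)

    warnings = []
    if labels.max() == 0:
        warnings.append("no cells retained; writing header-only CSV")
        _log("[!] " + warnings[0])

    cell_records = measure.measure_geometry(labels, cal)
    fluor = image.fluorescent_channels
    bgs: dict[int, nuclear.BackgroundEstimate] = {}
    nuclei_maps: dict[int, nuclear.NucleusLabelMap] = {}
    counts: dict[int, dict[int, int]] = {}
    for ch in fluor:
        fplane = image.plane(ch)
        bgs[ch] = nuclear.estimate_background(fplane, channel=ch)
        _log(f"[9] channel {ch} background: {bgs[ch].value}")
        stage(9 + (ch - 2) * 2, f"background_ch{ch}", fplane)
        nuc = nuclear.segment_nuclei_per_cell(fplane, labels, p)
        nuc = nuclear.nucleus_cell_ratio_filter(nuc, labels, p)
        nuclei_maps[ch] = nuc
        counts[ch] = nuclear.count_nuclei(nuc, labels)
        _log(f"[10-12] channel {ch}: {nuc.max_label} nucleus(ei) retained")
        stage(10 + (ch - 2) * 2, f"nuclei_ch{ch}", nuc.labels)

    for rec in cell_records:
        for ch in fluor:
            rec.whole_cell_mean_intensity[ch] = measure.measure_whole_cell_intensity(
                image.plane(ch), labels
            )[rec.index]

    nucleus_records: list[measure.NucleusRecord] = []
    for j in fluor:
        areas = measure.nuclear_union_area(nuclei_maps[j], labels, cal)
        means = {
            i: measure.measure_nuclear_intensity(
                image.plane(i), nuclei_maps[j], labels
            )
            for i in fluor
        }
        for rec in cell_records:
            nucleus_records.append(measure.NucleusRecord(
                parent_index=rec.index,
                mask_channel=j,
                area=areas[rec.index],
                mean_intensity={i: means[i][rec.index] for i in fluor},
            ))

    table = measure.assemble_table(
        cell_records, nucleus_records, counts, bgs, image.channel_count
    )
    csv_path = outdir / "results.csv"
    imgio.write_results_csv(table, csv_path)
    _log(f"[13] wrote {csv_path} ({len(table.rows)} cell(s), "
         f"{len(table.headers)} columns)")

    overlay_paths = []
    for ch in fluor:
        path = outdir / f"overlay_ch{ch}.png"
        imgio.write_overlay(plane, labels, nuclei_maps[ch].labels, path)
        overlay_paths.append(path)
    if not fluor:
        path = outdir / "overlay.png"
        imgio.write_overlay(plane, labels, None, path)
        overlay_paths.append(path)
    if opts.save_stages:
        stage(12, "overlay_final", labels)

    return RunSummary(
        n_cells=len(cell_records),
        nuclei_per_channel={ch: nuclei_maps[ch].max_label for ch in fluor},
        csv_path=csv_path,
        overlay_paths=overlay_paths,
        stage_paths=stage_paths,
        warnings=warnings,
    )
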