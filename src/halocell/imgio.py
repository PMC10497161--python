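"""Reading multi-channel micrographs and writing results (CSV, overlays).

TIFF is the reference input format: channel 1 is the (defocused)
bright-field plane, channels 2-3 are fluorescent planes. Channels may be
stored as pages or as samples; pages take precedence. Pixel-size
calibration is taken from the TIFF resolution tags when present and
converted to microns per pixel; without usable tags all downstream output
stays in pixel units.

Other container formats can be plugged in by registering a reader callable
with :func:`register_reader`; the core never parses proprietary containers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Callable, Optional, Sequence, Union

import numpy as np
import tifffile
from PIL import Image, ImageDraw
from skimage.segmentation import find_boundaries


class ImageReadError(ValueError):
    """Raised when an input file cannot be interpreted as a 1-3 plane image."""


class OverlayShapeError(ValueError):
    """Raised when label maps do not match the bright-field plane shape."""


@dataclass(frozen=True)
class Calibration:
    """Physical pixel size; ``microns_per_pixel`` is ``None`` when unknown."""

    microns_per_pixel: Optional[float] = None

    @property
    def present(self) -> bool:
        return self.microns_per_pixel is not None


@dataclass
class MultiChannelImage:
    """Ordered 2-D intensity planes; plane 0 is the bright-field channel."""

    planes: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        shapes = {p.shape for p in self.planes}
        if len(shapes) > 1:
            raise ImageReadError(f"planes have differing shapes: {shapes}")
        for p in self.planes:
            if p.ndim != 2:
                raise ImageReadError(f"plane is not 2-D (shape {p.shape})")

    @property
    def channel_count(self) -> int:
        return len(self.planes)

    @property
    def brightfield(self) -> np.ndarray:
        return self.planes[0]

    @property
    def fluorescent_channels(self) -> list[int]:
        """1-based channel numbers of the fluorescent planes (2 and/or 3)."""
        return list(range(2, self.channel_count + 1))

    def plane(self, channel: int) -> np.ndarray:
        """Return the plane for a 1-based channel number."""
        return self.planes[channel - 1]


# ---------------------------------------------------------------------------
# Reading

_READERS: dict[str, Callable[[Path], "tuple[MultiChannelImage, Calibration]"]] = {}


def register_reader(
    suffix: str,
    reader: Callable[[Path], "tuple[MultiChannelImage, Calibration]"],
) -> None:
    """Register a reader for a file suffix (e.g. ``.dv``).

    The callable receives the path and must return
    ``(MultiChannelImage, Calibration)``.
    """
    _READERS[suffix.lower()] = reader


_UNIT_TO_MICRONS = {
    2: 25400.0,   # inch
    3: 10000.0,   # centimeter
}


def _tiff_calibration(tif: tifffile.TiffFile) -> Calibration:
    page = tif.pages[0]
    tags = page.tags
    xres = tags.get("XResolution")
    unit = tags.get("ResolutionUnit")
    if xres is None or unit is None:
        return Calibration()
    unit_value = unit.value if not hasattr(unit.value, "value") else unit.value.value
    microns_per_unit = _UNIT_TO_MICRONS.get(int(unit_value))
    if microns_per_unit is None:
        return Calibration()
    num, den = xres.value
    if num == 0 or den == 0:
        return Calibration()
    pixels_per_unit = Fraction(int(num), int(den))
    if pixels_per_unit <= 0:
        return Calibration()
    return Calibration(microns_per_pixel=float(microns_per_unit / pixels_per_unit))


def _read_tiff(path: Path) -> tuple[MultiChannelImage, Calibration]:
    with tifffile.TiffFile(path) as tif:
        cal = _tiff_calibration(tif)
        if len(tif.pages) > 1:
            planes = [np.asarray(page.asarray()) for page in tif.pages]
        else:
            arr = tif.pages[0].asarray()
            if arr.ndim == 2:
                planes = [arr]
            elif arr.ndim == 3:
                # samples-per-pixel layout; channel axis is the smallest one
                axis = int(np.argmin(arr.shape))
                planes = [np.take(arr, i, axis=axis) for i in range(arr.shape[axis])]
            else:
                raise ImageReadError(
                    f"{path}: unsupported TIFF layout with shape {arr.shape}"
                )
    if len(planes) > 3:
        raise ImageReadError(
            f"{path}: {len(planes)} planes found; at most 3 channels are "
            "supported — select the bright-field and up to two fluorescent "
            "channels before analysis"
        )
    return MultiChannelImage(planes=[np.asarray(p) for p in planes]), cal


def read_image(path: Union[str, Path]) -> tuple[MultiChannelImage, Calibration]:
    """Read a 1-3 channel image plus calibration metadata.

    TIFF is handled natively; other suffixes dispatch to readers added via
    :func:`register_reader`. Raises :class:`ImageReadError` for unreadable
    files or more than three planes.
    """
    path = Path(path)
    if not path.exists():
        raise ImageReadError(f"no such file: {path}")
    suffix = path.suffix.lower()
    if suffix in _READERS:
        return _READERS[suffix](path)
    if suffix in (".tif", ".tiff"):
        try:
            return _read_tiff(path)
        except ImageReadError:
            raise
        except Exception as exc:
            raise ImageReadError(f"cannot read {path}: {exc}") from exc
    raise ImageReadError(
        f"no reader for suffix {path.suffix!r}; TIFF is supported natively, "
        "other formats require register_reader()"
    )


def write_tiff(
    image: MultiChannelImage,
    path: Union[str, Path],
    calibration: Optional[Calibration] = None,
) -> None:
    """Write planes as a multi-page TIFF, embedding calibration when given."""
    kwargs = {}
    if calibration is not None and calibration.present:
        pixels_per_cm = 10000.0 / calibration.microns_per_pixel
        kwargs["resolution"] = (pixels_per_cm, pixels_per_cm)
        kwargs["resolutionunit"] = "CENTIMETER"
    with tifffile.TiffWriter(path) as writer:
        for plane in image.planes:
            writer.write(plane, **kwargs)


# ---------------------------------------------------------------------------
# Results CSV


def write_results_csv(table, path: Union[str, Path]) -> None:
    """Serialize a results table (see ``measure.assemble_table``) to CSV."""
    df = table.to_dataframe() if hasattr(table, "to_dataframe") else table
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Overlay rendering

_CELL_COLOR = (255, 210, 60)     # cell outlines: amber
_NUCLEUS_COLOR = (90, 200, 255)  # nucleus outlines: cyan
_TEXT_COLOR = (255, 80, 80)


def _to_8bit(plane: np.ndarray) -> np.ndarray:
    plane = plane.astype(np.float64)
    lo, hi = plane.min(), plane.max()
    if hi <= lo:
        return np.zeros(plane.shape, dtype=np.uint8)
    return ((plane - lo) / (hi - lo) * 255.0).astype(np.uint8)


def write_overlay(
    brightfield: np.ndarray,
    cells: np.ndarray,
    nuclei: Optional[np.ndarray],
    path: Union[str, Path],
) -> None:
    """Render cell/nucleus outlines and cell index numerals over the image.

    Cell boundaries are drawn in one hue, nuclear boundaries in another, and
    each retained cell's index number is printed at its centroid, matching
    the indices of the CSV rows.
    """
    cells = np.asarray(cells)
    if cells.shape != brightfield.shape:
        raise OverlayShapeError(
            f"cell label map shape {cells.shape} != image shape "
            f"{brightfield.shape}"
        )
    if nuclei is not None and np.asarray(nuclei).shape != brightfield.shape:
        raise OverlayShapeError(
            f"nucleus label map shape {np.asarray(nuclei).shape} != image "
            f"shape {brightfield.shape}"
        )
    rgb = np.stack([_to_8bit(brightfield)] * 3, axis=-1)
    cell_edges = find_boundaries(cells, mode="outer") & (cells == 0) | \
        find_boundaries(cells, mode="inner")
    rgb[cell_edges] = _CELL_COLOR
    if nuclei is not None:
        nuc_edges = find_boundaries(np.asarray(nuclei), mode="inner")
        rgb[nuc_edges] = _NUCLEUS_COLOR

    img = Image.fromarray(rgb)
    draw = ImageDraw.Draw(img)
    for label in np.unique(cells):
        if label == 0:
            continue
        rows, cols = np.nonzero(cells == label)
        cy, cx = float(rows.mean()), float(cols.mean())
        draw.text((cx, cy), str(int(label)), fill=_TEXT_COLOR, anchor="mm")
    img.save(path)
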