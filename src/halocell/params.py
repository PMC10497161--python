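"""Pipeline tunables: defaults, validation, and key=value config files.

Every knob the segmentation and measurement stages consult lives in a single
:class:`PipelineParameters` record. The defaults are the reference parameter
set the pipeline was calibrated with and should rarely need modification;
they can be overridden from a flat ``key=value`` text file (``#`` comments
allowed) so that runs remain reproducible and scriptable.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union


class ParameterError(ValueError):
    """Raised for unknown keys, malformed values, or invalid parameter sets."""


@dataclass(frozen=True)
class PipelineParameters:
    """Tunables for the whole pipeline.

    Attributes
    ----------
    halo_threshold_sensitivity:
        Local-threshold sensitivity in [0, 1]; higher values mark more
        pixels as halo foreground.
    halo_threshold_neighborhood:
        Side length (odd, pixels) of the square neighborhood over which the
        local mean is computed.
    invert_min_component_px:
        Smallest foreground component (pixels) kept after inverting the
        halo mask.
    border_clear_connectivity:
        Pixel connectivity (4 or 8) used to decide whether a component
        touches the image border.
    border_clear_min_component_px:
        Smallest component kept after border clearing.
    cell_label_connectivity:
        Connectivity used when labeling cell components.
    cell_area_min_px, cell_area_max_px:
        Inclusive area band (pixels) for retained cells.
    convex_filter_slope, convex_filter_intercept:
        The convexity decision line: a region is kept iff
        ``aspect_ratio >= slope * area_ratio - intercept``.
    nuc_opening_struct_px:
        Side of the square structuring element for the binary opening
        applied to per-cell nuclear masks.
    nuc_min_component_px:
        Smallest nuclear component kept.
    nuc_label_connectivity:
        Connectivity used when labeling nuclear components.
    nuc_mask_area_cap_px:
        Optional upper area cap on nuclear components; ``None`` disables it.
    nuc_cell_ratio_max:
        Largest admissible nucleus:cell area ratio; nuclei strictly above
        it are discarded and their mean intensity reported as zero.
    sharpen_radius_px, sharpen_amount:
        Unsharp-mask radius (Gaussian sigma, pixels) and amount.
    """

    halo_threshold_sensitivity: float = 0.55
    halo_threshold_neighborhood: int = 15
    invert_min_component_px: int = 600
    border_clear_connectivity: int = 8
    border_clear_min_component_px: int = 1200
    cell_label_connectivity: int = 4
    cell_area_min_px: int = 500
    cell_area_max_px: int = 100000
    convex_filter_slope: float = 12.8571
    convex_filter_intercept: float = 12.5
    nuc_opening_struct_px: int = 5
    nuc_min_component_px: int = 200
    nuc_label_connectivity: int = 4
    nuc_mask_area_cap_px: Optional[int] = None
    nuc_cell_ratio_max: float = 0.2
    sharpen_radius_px: float = 1.0
    sharpen_amount: float = 0.8


_INT_FIELDS = {
    "halo_threshold_neighborhood",
    "invert_min_component_px",
    "border_clear_connectivity",
    "border_clear_min_component_px",
    "cell_label_connectivity",
    "cell_area_min_px",
    "cell_area_max_px",
    "nuc_opening_struct_px",
    "nuc_min_component_px",
    "nuc_label_connectivity",
}
_FLOAT_FIELDS = {
    "halo_threshold_sensitivity",
    "convex_filter_slope",
    "convex_filter_intercept",
    "nuc_cell_ratio_max",
    "sharpen_radius_px",
    "sharpen_amount",
}
_OPTIONAL_INT_FIELDS = {"nuc_mask_area_cap_px"}


def default_parameters() -> PipelineParameters:
    """Return the reference parameter set.

    The values are the calibrated defaults of the pipeline (adaptive halo
    threshold sensitivity 0.55 over a 15x15 neighborhood, cell area band
    [500, 100000] px, convexity line slope 12.8571 / intercept 12.5,
    nuclear floor 200 px, nucleus:cell ratio cap 0.2, ...).
    """
    return PipelineParameters()


def validate_parameters(p: PipelineParameters) -> list[str]:
    """Return a list of human-readable invariant violations (empty = valid)."""
    v: list[str] = []
    if not (0.0 <= p.halo_threshold_sensitivity <= 1.0):
        v.append(
            f"halo_threshold_sensitivity must be in [0, 1], got "
            f"{p.halo_threshold_sensitivity}"
        )
    if p.halo_threshold_neighborhood < 3 or p.halo_threshold_neighborhood % 2 == 0:
        v.append(
            f"halo_threshold_neighborhood must be an odd integer >= 3, got "
            f"{p.halo_threshold_neighborhood}"
        )
    if not p.cell_area_min_px < p.cell_area_max_px:
        v.append(
            f"cell_area_min_px ({p.cell_area_min_px}) must be < "
            f"cell_area_max_px ({p.cell_area_max_px})"
        )
    if not (0.0 < p.nuc_cell_ratio_max < 1.0):
        v.append(
            f"nuc_cell_ratio_max must be in (0, 1), got {p.nuc_cell_ratio_max}"
        )
    for field in ("border_clear_connectivity", "cell_label_connectivity",
                  "nuc_label_connectivity"):
        conn = getattr(p, field)
        if conn not in (4, 8):
            v.append(f"{field} must be 4 or 8, got {conn}")
    for field in ("invert_min_component_px", "border_clear_min_component_px",
                  "nuc_min_component_px", "cell_area_min_px"):
        if getattr(p, field) < 0:
            v.append(f"{field} must be non-negative, got {getattr(p, field)}")
    if p.nuc_mask_area_cap_px is not None and p.nuc_mask_area_cap_px <= 0:
        v.append(
            f"nuc_mask_area_cap_px must be positive or disabled, got "
            f"{p.nuc_mask_area_cap_px}"
        )
    if p.nuc_opening_struct_px < 1:
        v.append(
            f"nuc_opening_struct_px must be >= 1, got {p.nuc_opening_struct_px}"
        )
    if p.sharpen_radius_px <= 0:
        v.append(f"sharpen_radius_px must be > 0, got {p.sharpen_radius_px}")
    if p.sharpen_amount < 0:
        v.append(f"sharpen_amount must be >= 0, got {p.sharpen_amount}")
    return v


def _parse_value(key: str, raw: str, lineno: int):
    raw = raw.strip()
    try:
        if key in _INT_FIELDS:
            return int(raw)
        if key in _FLOAT_FIELDS:
            return float(raw)
        if key in _OPTIONAL_INT_FIELDS:
            if raw.lower() in ("none", "off", "disabled", ""):
                return None
            return int(raw)
    except ValueError as exc:
        raise ParameterError(
            f"line {lineno}: malformed value {raw!r} for key {key!r}"
        ) from exc
    raise ParameterError(f"line {lineno}: unknown parameter key {key!r}")


def load_parameters(path: Union[str, Path]) -> PipelineParameters:
    """Load parameters from a flat ``key=value`` file.

    Unspecified keys fall back to the defaults. Lines beginning with ``#``
    and blank lines are ignored. The resulting parameter set is validated;
    any violation raises :class:`ParameterError`.
    """
    path = Path(path)
    overrides = {}
    known = _INT_FIELDS | _FLOAT_FIELDS | _OPTIONAL_INT_FIELDS
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ParameterError(
                f"line {lineno}: expected 'key = value', got {line!r}"
            )
        key, raw = line.split("=", 1)
        key = key.strip()
        if key not in known:
            raise ParameterError(f"line {lineno}: unknown parameter key {key!r}")
        overrides[key] = _parse_value(key, raw, lineno)
    p = dataclasses.replace(default_parameters(), **overrides)
    violations = validate_parameters(p)
    if violations:
        raise ParameterError("; ".join(violations))
    return p


def save_parameters(p: PipelineParameters, path: Union[str, Path]) -> None:
    """Write a parameter set as a ``key=value`` file (round-trips with load)."""
    lines = []
    for f in dataclasses.fields(p):
        val = getattr(p, f.name)
        lines.append(f"{f.name} = {'none' if val is None else val}")
    Path(path).write_text("\n".join(lines) + "\n")
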