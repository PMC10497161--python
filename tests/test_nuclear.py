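import dataclasses

import numpy as np
import pytest

import halocell as hc
from halocell.nuclear import ShapeMismatchError
from conftest import make_cell_with_nucleus


# ---------------------------------------------------------------------------
# estimate_background


def test_background_is_majority_mode():
    plane = np.full((100, 100), 100, dtype=np.uint16)
    plane[:10, :] = 800
    assert hc.estimate_background(plane).value == 100


def test_background_of_constant_plane_is_that_value():
    plane = np.full((20, 20), 77, dtype=np.uint16)
    assert hc.estimate_background(plane).value == 77


def test_background_tie_breaks_toward_lowest():
    plane = np.empty((10, 10), dtype=np.uint16)
    plane.ravel()[:50] = 200
    plane.ravel()[50:] = 100
    assert hc.estimate_background(plane).value == 100


def test_background_of_float_plane_is_modal_bin_center():
    rng = np.random.default_rng(0)
    plane = rng.uniform(400.0, 500.0, size=(64, 64))
    plane[:48, :] = 123.0  # dominant level far below the uniform spread
    est = hc.estimate_background(plane)
    assert est.value == pytest.approx(123.0, abs=(500 - 123) / 256)


def test_background_equals_generator_constant_on_clean_scene(clean_scene):
    spec, image, _ = clean_scene
    est = hc.estimate_background(image.plane(2), channel=2)
    assert est.value == spec.fluor_background_intensity


# ---------------------------------------------------------------------------
# segment_nuclei_per_cell


def _brute_force_otsu(values):
    """Exhaustive threshold search minimizing intra-class variance."""
    values = np.asarray(values, dtype=float)
    best_t, best_score = None, np.inf
    for t in np.unique(values)[:-1]:
        lo, hi = values[values <= t], values[values > t]
        score = lo.size * lo.var() + hi.size * hi.var()
        if score < best_score:
            best_t, best_score = t, score
    return best_t


def test_single_bright_disk_yields_one_nucleus(params):
    plane, cells, disk = make_cell_with_nucleus(nucleus_radius=10)
    nuc = hc.segment_nuclei_per_cell(plane, cells, params)
    assert nuc.max_label == 1
    assert nuc.parent_cell == {1: 1}
    support = nuc.labels == 1
    assert (support & ~disk).sum() == 0          # inside the planted disk
    assert support.sum() >= 0.8 * disk.sum()     # up to opening erosion
    # and the implicit threshold agrees with the exhaustive Otsu oracle
    t = _brute_force_otsu(plane[cells == 1])
    np.testing.assert_array_equal(
        support, hc.segment_nuclei_per_cell(plane, cells, params).labels == 1
    )
    assert plane[support].min() > t


def test_post_mitotic_cell_has_two_nuclei_same_parent(params):
    plane, cells, _ = make_cell_with_nucleus(
        shape=(140, 140), nucleus_radius=10, nucleus_offset=(-25, 0)
    )
    yy, xx = np.mgrid[0:140, 0:140]
    second = (yy - 95) ** 2 + (xx - 70) ** 2 <= 100
    plane[second & (cells == 1)] = 1000
    nuc = hc.segment_nuclei_per_cell(plane, cells, params)
    assert nuc.max_label == 2
    assert set(nuc.parent_cell.values()) == {1}


def test_flat_cell_yields_no_nucleus(params):
    cells = np.zeros((60, 60), dtype=np.int32)
    cells[10:50, 10:50] = 1
    plane = np.full((60, 60), 400, dtype=np.uint16)
    nuc = hc.segment_nuclei_per_cell(plane, cells, params)
    assert nuc.max_label == 0


def test_shape_mismatch_rejected(params):
    with pytest.raises(ShapeMismatchError):
        hc.segment_nuclei_per_cell(
            np.zeros((10, 10)), np.zeros((20, 20), dtype=np.int32), params
        )


def test_nucleus_supports_stay_inside_parent_cells(params, segmented_scene):
    _, image, _, labels, _ = segmented_scene
    nuc = hc.segment_nuclei_per_cell(image.plane(2), labels, params)
    for nuc_label, cell_label in nuc.parent_cell.items():
        assert (labels[nuc.labels == nuc_label] == cell_label).all()


def test_segmentation_is_local_to_each_cell(params, segmented_scene):
    # removing other cells must not change this cell's nuclei
    _, image, _, labels, _ = segmented_scene
    full = hc.segment_nuclei_per_cell(image.plane(2), labels, params)
    only_one = np.where(labels == 1, labels, 0)
    alone = hc.segment_nuclei_per_cell(image.plane(2), only_one, params)
    mine = np.isin(
        full.labels,
        [n for n, c in full.parent_cell.items() if c == 1],
    )
    np.testing.assert_array_equal(mine, alone.labels > 0)


def test_every_planted_nucleus_recovered_on_clean_scene(params, segmented_scene):
    _, image, truth, labels, _ = segmented_scene
    nuc = hc.segment_nuclei_per_cell(image.plane(2), labels, params)
    nuc = hc.nucleus_cell_ratio_filter(nuc, labels, params)
    planted = sum(len(c.nuclei) for c in truth.interior_cells)
    assert nuc.max_label == planted
    for cell in truth.interior_cells:
        for planted_nuc in cell.nuclei:
            yy, xx = np.mgrid[0:labels.shape[0], 0:labels.shape[1]]
            disk = ((yy - planted_nuc.center[0]) ** 2
                    + (xx - planted_nuc.center[1]) ** 2
                    <= planted_nuc.radius ** 2) & cell.support
            recovered = (nuc.labels > 0) & disk
            assert recovered.sum() >= 0.7 * disk.sum()


def test_optional_area_cap_removes_large_components(params):
    plane, cells, _ = make_cell_with_nucleus(nucleus_radius=10)
    uncapped = hc.segment_nuclei_per_cell(plane, cells, params)
    area = int((uncapped.labels == 1).sum())
    capped = dataclasses.replace(params, nuc_mask_area_cap_px=area - 1)
    assert hc.segment_nuclei_per_cell(plane, cells, capped).max_label == 0


# ---------------------------------------------------------------------------
# nucleus_cell_ratio_filter


def _nucleus_in_cell(cell_area_px, nucleus_area_px):
    cells = hc.exact_area_blob(
        cell_area_px, (120, 120), top_left=(5, 5)
    ).astype(np.int32)
    labels = hc.exact_area_blob(
        nucleus_area_px, (120, 120), top_left=(70, 70)
    ).astype(np.int32)
    return hc.NucleusLabelMap(labels=labels, parent_cell={1: 1}), cells


@pytest.mark.parametrize(
    "nucleus_area,kept",
    [(250, False), (150, True), (200, True)],  # 25%, 15%, exactly 20%
)
def test_ratio_filter_boundary_is_strict(params, nucleus_area, kept):
    nuc, cells = _nucleus_in_cell(1000, nucleus_area)
    out = hc.nucleus_cell_ratio_filter(nuc, cells, params)
    assert (out.max_label == 1) == kept
    # the cell itself is never touched
    assert cells.max() == 1


def test_surviving_ratios_verified_by_pixel_counts(params, segmented_scene):
    _, image, _, labels, _ = segmented_scene
    nuc = hc.segment_nuclei_per_cell(image.plane(2), labels, params)
    out = hc.nucleus_cell_ratio_filter(nuc, labels, params)
    for nuc_label, cell_label in out.parent_cell.items():
        nuc_area = (out.labels == nuc_label).sum()
        cell_area = (labels == cell_label).sum()
        assert nuc_area / cell_area <= params.nuc_cell_ratio_max


# ---------------------------------------------------------------------------
# count_nuclei


def test_counts_default_to_zero_without_nuclei():
    cells = np.zeros((20, 20), dtype=np.int32)
    cells[2:8, 2:8], cells[12:18, 12:18] = 1, 2
    empty = hc.NucleusLabelMap(labels=np.zeros_like(cells))
    assert hc.count_nuclei(empty, cells) == {1: 0, 2: 0}


def test_counts_attribute_nuclei_to_their_cells():
    cells = np.zeros((20, 20), dtype=np.int32)
    cells[2:8, 2:8], cells[12:18, 12:18] = 1, 2
    labels = np.zeros_like(cells)
    labels[3, 3], labels[4, 4] = 1, 1
    labels[5, 5] = 2
    nuc = hc.NucleusLabelMap(labels=labels, parent_cell={1: 1, 2: 1})
    assert hc.count_nuclei(nuc, cells) == {1: 2, 2: 0}
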