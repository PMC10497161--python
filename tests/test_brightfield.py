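import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import halocell as hc
from halocell.brightfield import (
    RegionMismatchError,
    UnknownRegionError,
    _fill_holes_selective,
)


# ---------------------------------------------------------------------------
# sharpen


def test_sharpen_of_constant_plane_is_identity(params):
    plane = np.full((40, 40), 700, dtype=np.uint16)
    np.testing.assert_array_equal(hc.sharpen(plane, params), plane)


def test_sharpen_amplifies_an_impulse(params):
    plane = np.zeros((41, 41), dtype=np.uint16)
    plane[20, 20] = 1000
    out = hc.sharpen(plane, params)
    assert out.shape == plane.shape
    assert out[20, 20] > 1000  # (1+a)I - a*G(I) exceeds I at the impulse


def test_sharpen_clips_to_integer_dtype_range(params):
    plane = np.zeros((41, 41), dtype=np.uint8)
    plane[20, 20] = 255
    out = hc.sharpen(plane, params)
    assert out.dtype == np.uint8 and out.max() == 255


# ---------------------------------------------------------------------------
# threshold_halos


def test_threshold_of_constant_plane_is_all_false(params):
    plane = np.full((50, 50), 1234.0)
    assert not hc.threshold_halos(plane, params).any()


def _brute_force_local_mean_threshold(plane, size, sensitivity):
    """Independent oracle: reflect-padded local mean, strict comparison."""
    pad = size // 2
    padded = np.pad(plane.astype(float), pad, mode="reflect")
    h, w = plane.shape
    out = np.zeros((h, w), dtype=bool)
    for i in range(h):
        for j in range(w):
            window = padded[i:i + size, j:j + size]
            out[i, j] = plane[i, j] > (2.0 - sensitivity) * window.mean()
    return out


def test_threshold_matches_brute_force_on_synthetic_ring(params):
    plane = np.full((40, 40), 100.0)
    yy, xx = np.mgrid[0:40, 0:40]
    d = np.sqrt((yy - 20) ** 2 + (xx - 20) ** 2)
    ring = (d >= 10) & (d <= 13)
    plane[ring] = 200.0
    got = hc.threshold_halos(plane, params)
    oracle = _brute_force_local_mean_threshold(
        plane, params.halo_threshold_neighborhood,
        params.halo_threshold_sensitivity,
    )
    np.testing.assert_array_equal(got, oracle)
    # ring pixels fire, far-away background does not
    assert got[ring].all()
    assert not got[d > 25].any()


# ---------------------------------------------------------------------------
# invert_and_repair


def test_invert_of_empty_halo_mask_is_all_true(params):
    halos = np.zeros((40, 40), dtype=bool)
    assert hc.invert_and_repair(halos, params).all()


@pytest.mark.parametrize("area,kept", [(599, False), (600, True)])
def test_small_component_floor_after_inversion(params, area, kept):
    halos = np.ones((80, 80), dtype=bool)
    blob = hc.exact_area_blob(area, (80, 80), top_left=(20, 20))
    halos[blob] = False
    out = hc.invert_and_repair(halos, params)
    assert out.any() == kept


def test_interior_hole_is_filled(params):
    # halo mask false everywhere except a closed box outline; its interior
    # becomes a foreground component with a small punched hole
    halos = np.zeros((60, 60), dtype=bool)
    cells = ~halos
    cells[30:32, 30:35] = False  # 10-px hole inside the big component
    out = _fill_holes_selective(cells)
    assert out.all()


def test_closed_halo_ring_is_not_filled_over():
    # complemented scene: outer background + interior are two components
    # separated by the ring; filling the ring would merge them
    mask = np.ones((60, 60), dtype=bool)
    yy, xx = np.mgrid[0:60, 0:60]
    d = np.sqrt((yy - 30) ** 2 + (xx - 30) ** 2)
    ring = (d >= 15) & (d <= 18)
    mask[ring] = False
    out = _fill_holes_selective(mask)
    np.testing.assert_array_equal(out, mask)


# ---------------------------------------------------------------------------
# clear_border


def test_component_touching_border_removed(params):
    mask = np.zeros((100, 100), dtype=bool)
    mask[0:40, 30:70] = True  # touches row 0; area 1600
    assert not hc.clear_border(mask, params).any()


@pytest.mark.parametrize("area,kept", [(1199, False), (1200, True)])
def test_border_clear_small_component_floor(params, area, kept):
    mask = hc.exact_area_blob(area, (100, 100), top_left=(30, 30))
    assert hc.clear_border(mask, params).any() == kept


def test_clear_border_of_empty_mask_is_empty(params):
    assert not hc.clear_border(np.zeros((50, 50), dtype=bool), params).any()


def test_no_retained_pixel_on_boundary(params, segmented_scene):
    *_, labels, _ = segmented_scene
    assert labels[0, :].max() == 0 and labels[-1, :].max() == 0
    assert labels[:, 0].max() == 0 and labels[:, -1].max() == 0


# ---------------------------------------------------------------------------
# label_and_area_filter


@pytest.mark.parametrize("area,n_labels", [(499, 0), (500, 1)])
def test_area_filter_lower_bound_is_inclusive(params, area, n_labels):
    mask = hc.exact_area_blob(area, (100, 100), top_left=(10, 10))
    assert hc.label_and_area_filter(mask, params).max() == n_labels


def test_area_filter_keeps_only_in_band_blob(params):
    mask = (
        hc.exact_area_blob(400, (600, 1200), top_left=(10, 10))
        | hc.exact_area_blob(5000, (600, 1200), top_left=(100, 100))
        | hc.exact_area_blob(150000, (600, 1200), top_left=(200, 200))
    )
    labels = hc.label_and_area_filter(mask, params)
    assert labels.max() == 1
    assert (labels > 0).sum() == 5000


# ---------------------------------------------------------------------------
# shape_metrics


def test_disk_metrics_match_moment_integrals(params):
    yy, xx = np.mgrid[0:100, 0:100]
    r = 20
    labels = (((yy - 50) ** 2 + (xx - 50) ** 2) <= r * r).astype(np.int32)
    (s,) = hc.shape_metrics(labels)
    assert s.major_axis_px == pytest.approx(2 * r, rel=0.03)
    assert s.minor_axis_px == pytest.approx(2 * r, rel=0.03)
    assert s.aspect_ratio == pytest.approx(1.0, abs=0.02)
    # hull rasterization slightly inflates the convex area of a disk
    assert s.area_ratio == pytest.approx(1.0, abs=0.05)


def test_rectangle_metrics_match_uniform_second_moments(params):
    a, b = 90, 30
    labels = np.zeros((120, 140), dtype=np.int32)
    labels[40:40 + b, 20:20 + a] = 1
    (s,) = hc.shape_metrics(labels)
    assert s.major_axis_px == pytest.approx(2 * a / np.sqrt(3), rel=0.02)
    assert s.aspect_ratio == pytest.approx(a / b, rel=0.02)


def test_concave_plus_sign_has_area_ratio_above_one(params):
    labels = np.zeros((60, 60), dtype=np.int32)
    labels[25:35, 5:55] = 1
    labels[5:55, 25:35] = 1
    (s,) = hc.shape_metrics(labels)
    assert s.area_ratio > 1.3


# ---------------------------------------------------------------------------
# convex_filter


def _fake_map_and_shapes(pairs):
    labels = np.zeros((1, len(pairs) * 2), dtype=np.int32)
    shapes = []
    for k, (aspect, area_ratio) in enumerate(pairs, start=1):
        labels[0, (k - 1) * 2] = k
        shapes.append(hc.RegionShape(
            label=k, area_px=1, convex_area_px=1, major_axis_px=aspect,
            minor_axis_px=1.0, aspect_ratio=aspect, area_ratio=area_ratio,
        ))
    return labels, shapes


@pytest.mark.parametrize(
    "aspect,area_ratio,kept",
    [
        (4.0, 1.05, True),    # cutoff 1.0
        (2.0, 1.30, False),   # cutoff ~4.21
        (1.0, 1.0, True),     # cutoff 0.357: any convex shape passes
    ],
)
def test_decision_line_examples(params, aspect, area_ratio, kept):
    labels, shapes = _fake_map_and_shapes([(aspect, area_ratio)])
    out = hc.convex_filter(labels, shapes, params)
    assert (out.max() > 0) == kept


def test_mismatched_shapes_rejected(params):
    labels, shapes = _fake_map_and_shapes([(3.0, 1.0), (3.0, 1.0)])
    with pytest.raises(RegionMismatchError):
        hc.convex_filter(labels, shapes[:1], params)


# ---------------------------------------------------------------------------
# relabel / remove_regions


def test_relabel_compacts_in_raster_order():
    labels = np.zeros((10, 10), dtype=np.int32)
    labels[1, 1] = 5
    labels[8, 8] = 2
    out = hc.relabel(labels)
    assert out[1, 1] == 1 and out[8, 8] == 2
    np.testing.assert_array_equal(out > 0, labels > 0)


def test_relabel_of_empty_map_is_empty():
    assert hc.relabel(np.zeros((5, 5), dtype=np.int32)).max() == 0


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_relabel_is_idempotent_and_gapless(seed):
    rng = np.random.default_rng(seed)
    labels = rng.integers(0, 6, size=(16, 16)).astype(np.int32) * 3
    once = hc.relabel(labels)
    present = sorted(set(once.ravel()) - {0})
    assert present == list(range(1, len(present) + 1))
    np.testing.assert_array_equal(hc.relabel(once), once)


def test_remove_regions_empty_list_just_relabels():
    labels = np.zeros((10, 10), dtype=np.int32)
    labels[2, 2] = 4
    np.testing.assert_array_equal(
        hc.remove_regions(labels, []), hc.relabel(labels)
    )


def test_remove_regions_deletes_and_renumbers():
    labels = np.zeros((10, 10), dtype=np.int32)
    labels[1, 1], labels[4, 4], labels[8, 8] = 1, 2, 3
    out = hc.remove_regions(labels, [2])
    assert out[1, 1] == 1 and out[8, 8] == 2 and out[4, 4] == 0


def test_remove_all_regions_empties_map():
    labels = np.zeros((10, 10), dtype=np.int32)
    labels[1, 1], labels[4, 4] = 1, 2
    assert hc.remove_regions(labels, [1, 2]).max() == 0


def test_remove_unknown_region_lists_valid_labels():
    labels = np.zeros((10, 10), dtype=np.int32)
    labels[1, 1] = 1
    with pytest.raises(UnknownRegionError, match=r"\[1\]"):
        hc.remove_regions(labels, [7])


# ---------------------------------------------------------------------------
# composition properties


def test_downstream_stages_only_remove_foreground(params, clean_scene):
    _, image, _ = clean_scene
    sharp = hc.sharpen(image.brightfield, params)
    halos = hc.threshold_halos(sharp, params)
    repaired = hc.invert_and_repair(halos, params)
    final, _ = hc.segment_cells(image.brightfield, params)
    assert not ((final > 0) & ~repaired).any()


def test_clean_scene_recovers_exact_cell_count(params, segmented_scene):
    _, _, truth, labels, _ = segmented_scene
    assert labels.max() == len(truth.interior_cells)


def test_convex_decision_matches_raw_pixel_recomputation(params, segmented_scene):
    # decision for every retained region must equal the sign test computed
    # from scratch on its pixel set
    *_, labels, _ = segmented_scene
    for s in hc.shape_metrics(labels):
        cutoff = (params.convex_filter_slope * s.area_ratio
                  - params.convex_filter_intercept)
        assert s.aspect_ratio >= cutoff
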