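"""Segmentation operators against analytic masks and brute-force oracles."""

import numpy as np
import pytest
from scipy.ndimage import distance_transform_edt

from conftest import make_stack
from scomorph.segment import (
    LabelMask,
    classify_marker_positive,
    expand_cell_territories,
    load_external_mask,
    segment_glomeruli,
    segment_nuclei,
)
from scomorph.validate import match_labels


def disc_image(shape, centers, radius, value=100.0, background=5.0):
    img = np.full(shape, background)
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    mask = np.zeros(shape, dtype=bool)
    for r, c in centers:
        mask |= (yy - r) ** 2 + (xx - c) ** 2 <= radius**2
    img[mask] = value
    return img, mask


# ---------------------------------------------------------------------------
# Glomeruli
# ---------------------------------------------------------------------------

def test_single_disc_recovered_with_high_iou():
    img, truth = disc_image((256, 256), [(128, 128)], radius=50)
    mask = segment_glomeruli(make_stack(img, pixel_size_um=0.5))
    assert mask.n_labels == 1
    inter = ((mask.labels > 0) & truth).sum()
    union = ((mask.labels > 0) | truth).sum()
    assert inter / union >= 0.95


def test_blank_if_channel_yields_no_glomeruli():
    mask = segment_glomeruli(make_stack(np.zeros((128, 128))))
    assert mask.n_labels == 0


def test_two_discs_give_two_labels_with_correct_areas():
    r = 40
    img, _ = disc_image((256, 256), [(70, 70), (180, 180)], radius=r)
    mask = segment_glomeruli(make_stack(img, pixel_size_um=0.5))
    assert mask.n_labels == 2
    analytic = np.pi * r**2 * 0.5**2
    for area in mask.areas_um2().values():
        assert abs(area - analytic) / analytic < 0.05


def test_min_area_filter_removes_specks():
    img, _ = disc_image((256, 256), [(128, 128)], radius=50)
    img[10:13, 10:13] = 100.0  # 9-px speck, far below 700 µm²
    mask = segment_glomeruli(make_stack(img, pixel_size_um=0.5))
    assert mask.n_labels == 1
    assert mask.labels[11, 11] == 0


# ---------------------------------------------------------------------------
# Nuclei
# ---------------------------------------------------------------------------

def test_simulated_nuclei_counted_exactly(small_scene):
    stack, truth = small_scene
    mask = segment_nuclei(stack)
    assert mask.n_labels == truth.nucleus_mask.n_labels
    score = match_labels(truth.nucleus_mask, mask)
    assert score.precision == 1.0


def test_blank_dapi_yields_no_nuclei():
    mask = segment_nuclei(make_stack(np.zeros((128, 128))))
    assert mask.n_labels == 0


def test_touching_ellipses_split_by_watershed():
    yy, xx = np.mgrid[0:128, 0:128].astype(float)
    e1 = ((yy - 64) / 14) ** 2 + ((xx - 48) / 18) ** 2 <= 1
    e2 = ((yy - 64) / 14) ** 2 + ((xx - 82) / 18) ** 2 <= 1  # overlap neck
    img = np.where(e1 | e2, 100.0, 2.0)
    assert (e1 & e2).sum() > 0
    mask = segment_nuclei(make_stack(img, pixel_size_um=0.189))
    assert mask.n_labels == 2


# ---------------------------------------------------------------------------
# External masks
# ---------------------------------------------------------------------------

def test_binary_external_mask_is_component_labeled(tmp_path):
    import tifffile

    mask = np.zeros((64, 64), dtype=np.uint8)
    mask[5:15, 5:15] = 1
    mask[30:40, 30:40] = 1
    mask[50:60, 5:15] = 1
    path = tmp_path / "m.tif"
    tifffile.imwrite(path, mask)
    loaded = load_external_mask(path, (64, 64))
    assert sorted(loaded.ids.tolist()) == [1, 2, 3]


def test_labeled_external_mask_relabeled_preserving_geometry(tmp_path):
    import tifffile

    mask = np.zeros((32, 32), dtype=np.uint16)
    mask[2:8, 2:8] = 5
    mask[20:28, 20:28] = 9
    path = tmp_path / "m.tif"
    tifffile.imwrite(path, mask)
    loaded = load_external_mask(path, (32, 32))
    assert sorted(np.unique(loaded.labels).tolist()) == [0, 1, 2]
    assert np.array_equal(loaded.labels == 1, mask == 5)
    assert np.array_equal(loaded.labels == 2, mask == 9)


def test_shape_mismatch_names_both_shapes(tmp_path):
    import tifffile

    path = tmp_path / "m.tif"
    tifffile.imwrite(path, np.zeros((16, 16), dtype=np.uint8))
    with pytest.raises(ValueError, match=r"16.*32"):
        load_external_mask(path, (32, 32))


def test_relabeling_preserves_geometry():
    rng = np.random.default_rng(0)
    labels = rng.integers(0, 4, (32, 32)).astype(np.int32) * 7  # ids {0,7,14,21}
    mask = LabelMask(labels, 0.2)
    rel = mask.relabel()
    for old, new in zip([7, 14, 21], [1, 2, 3]):
        assert np.array_equal(labels == old, rel.labels == new)


# ---------------------------------------------------------------------------
# Territories
# ---------------------------------------------------------------------------

def test_zero_radius_is_identity():
    labels = np.zeros((32, 32), dtype=np.int32)
    labels[10:14, 10:14] = 1
    mask = LabelMask(labels, 0.2)
    out = expand_cell_territories(mask, 0.0)
    assert np.array_equal(out.labels, labels)


def test_single_territory_equals_distance_threshold():
    labels = np.zeros((64, 64), dtype=np.int32)
    labels[30:34, 30:34] = 1
    ps = 0.5
    out = expand_cell_territories(LabelMask(labels, ps), 2.0)
    # brute-force oracle: distance to the nucleus pixel set, per pixel
    dist = distance_transform_edt(labels == 0)
    expected = dist <= 2.0 / ps
    assert np.array_equal(out.labels > 0, expected)
    assert np.all(out.labels[labels > 0] == 1)


def test_two_territories_follow_nearest_nucleus_rule():
    labels = np.zeros((128, 128), dtype=np.int32)
    labels[40:46, 40:46] = 1
    labels[80:86, 75:81] = 2
    ps = 0.2
    out = expand_cell_territories(LabelMask(labels, ps), 6.0)
    pts1 = np.argwhere(labels == 1)
    pts2 = np.argwhere(labels == 2)
    for r in range(128):
        for c in range(128):
            lab = out.labels[r, c]
            if lab == 0 or labels[r, c] != 0:
                continue
            d1 = np.sqrt(((pts1 - (r, c)) ** 2).sum(1)).min()
            d2 = np.sqrt(((pts2 - (r, c)) ** 2).sum(1)).min()
            own = d1 if lab == 1 else d2
            other = d2 if lab == 1 else d1
            assert own <= other + 1e-9
            assert own <= 6.0 / ps


def test_territory_partition_property(small_scene):
    _, truth = small_scene
    nuclei = truth.nucleus_mask
    out = expand_cell_territories(nuclei, 3.0)
    # every territory contains its nucleus
    assert np.all(out.labels[nuclei.labels > 0] == nuclei.labels[nuclei.labels > 0])
    # union is exactly the set of pixels within the radius of any nucleus
    dist = distance_transform_edt(nuclei.labels == 0)
    assert np.array_equal(out.labels > 0, dist <= 3.0 / nuclei.pixel_size_um)


# ---------------------------------------------------------------------------
# Marker calls
# ---------------------------------------------------------------------------

def test_zero_marker_channel_all_negative():
    labels = np.zeros((32, 32), dtype=np.int32)
    labels[5:10, 5:10] = 1
    labels[20:25, 20:25] = 2
    calls = classify_marker_positive(LabelMask(labels, 0.2), np.zeros((32, 32)),
                                     policy="absolute", threshold=1.0)
    assert calls.positive == {1: False, 2: False}


def test_simulated_marker_calls_match_ground_truth():
    """~40% marker-positive intraglomerular nuclei at 10x intensity
    separation are called exactly."""
    from scomorph.simulate import TissueSimParams, simulate_tissue_image

    params = TissueSimParams(image_size_px=(640, 640), n_glomeruli=1,
                             glom_radius_um=40.0, n_nuclei=25, seed=21)
    stack, truth = simulate_tissue_image(params)
    n_pos = sum(truth.marker_flags.values())
    assert 0 < n_pos < len(truth.marker_flags)  # scene exercises both classes
    calls = classify_marker_positive(truth.nucleus_mask, stack.channel("if"))
    assert calls.positive == truth.marker_flags


def test_single_label_otsu_falls_back_flagged():
    labels = np.zeros((16, 16), dtype=np.int32)
    labels[4:10, 4:10] = 1
    calls = classify_marker_positive(LabelMask(labels, 0.2),
                                     np.full((16, 16), 3.0), policy="otsu",
                                     threshold=5.0)
    assert calls.fallback
    assert calls.positive == {1: False}


def test_marker_shape_mismatch_raises():
    labels = np.zeros((16, 16), dtype=np.int32)
    with pytest.raises(ValueError):
        classify_marker_positive(LabelMask(labels, 0.2), np.zeros((8, 8)))
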