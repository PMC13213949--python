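"""Adaptive binarization, mask multiplication and seeded cell masks."""

import numpy as np
import pytest

from synoquant import (
    BinaryMask,
    RegionClass,
    RegionLabelMap,
    cell_masks_from_seeds,
    colocalize,
    count_seed_density,
    local_adaptive_binarize,
)


def naive_local_mean_mask(img, w):
    """O(n*w^2) strict local-mean threshold oracle (exact for int images)."""
    side = 2 * w + 1
    if np.issubdtype(img.dtype, np.integer):
        padded = np.pad(img.astype(np.int64), w, mode="symmetric")
        out = np.zeros(img.shape, dtype=bool)
        for r in range(img.shape[0]):
            for c in range(img.shape[1]):
                s = int(padded[r : r + side, c : c + side].sum())
                out[r, c] = int(img[r, c]) * side * side > s
        return out
    padded = np.pad(img.astype(np.float64), w, mode="symmetric")
    out = np.zeros(img.shape, dtype=bool)
    for r in range(img.shape[0]):
        for c in range(img.shape[1]):
            out[r, c] = img[r, c] > padded[r : r + side, c : c + side].mean()
    return out


@pytest.mark.parametrize("value", [0, 7, 40000])
def test_constant_int_image_all_false(value):
    img = np.full((40, 40), value, dtype=np.uint16)
    assert not local_adaptive_binarize(img, 5).mask.any()


@pytest.mark.parametrize("value", [0.0, 0.3, 0.7, 1.0])
def test_constant_float_image_all_false(value):
    img = np.full((64, 64), value, dtype=float)
    assert not local_adaptive_binarize(img, 11).mask.any()


def test_single_bright_pixel():
    img = np.zeros((200, 200), dtype=np.uint16)
    img[100, 120] = 1
    mask = local_adaptive_binarize(img, 50).mask
    assert mask[100, 120]
    assert mask.sum() == 1


def test_window_larger_than_image_degenerates_to_global_mean():
    img = np.zeros((64, 64), dtype=np.uint16)
    img[10, 10] = 100
    with pytest.warns(UserWarning, match="global-mean"):
        mask = local_adaptive_binarize(img, 50).mask
    assert mask[10, 10] and mask.sum() == 1


@pytest.mark.parametrize("w", [3, 5, 11])
def test_integer_oracle_exact(rng, w):
    img = rng.integers(0, 65536, size=(64, 64), dtype=np.uint16)
    got = local_adaptive_binarize(img, w).mask
    assert np.array_equal(got, naive_local_mean_mask(img, w))


@pytest.mark.parametrize("w", [3, 7])
def test_float_oracle(rng, w):
    img = rng.random((48, 48))
    got = local_adaptive_binarize(img, w).mask
    assert np.array_equal(got, naive_local_mean_mask(img, w))


def test_scale_invariance_strictly_positive(rng):
    img = rng.random((60, 60)) + 0.5
    base = local_adaptive_binarize(img, 5).mask
    for scale in (3.7e-3, 1.0e4):
        assert np.array_equal(local_adaptive_binarize(img * scale, 5).mask, base)


def test_translation_equivariance_away_from_borders(rng):
    pattern = rng.random((20, 20))
    img1 = np.full((100, 100), 0.2)
    img2 = np.full((100, 100), 0.2)
    img1[30:50, 30:50] = pattern
    img2[40:60, 45:65] = pattern
    m1 = local_adaptive_binarize(img1, 4).mask
    m2 = local_adaptive_binarize(img2, 4).mask
    assert np.array_equal(m1[30:50, 30:50], m2[40:60, 45:65])


def test_binarize_input_validation():
    with pytest.raises(ValueError, match="non-negative"):
        local_adaptive_binarize(np.array([[-1.0, 0.0]] * 4))
    with pytest.raises(ValueError, match="non-finite"):
        local_adaptive_binarize(np.array([[np.nan, 0.0]] * 4))


def test_colocalize_algebra(rng):
    a = BinaryMask(rng.random((30, 30)) > 0.5, "A", 50)
    b = BinaryMask(rng.random((30, 30)) > 0.5, "B", 50)
    ab = colocalize(a, b)
    # oracle: elementwise AND
    assert np.array_equal(ab.mask, a.mask & b.mask)
    # commutative, idempotent, absorbing
    assert np.array_equal(colocalize(b, a).mask, ab.mask)
    assert np.array_equal(colocalize(a, a).mask, a.mask)
    assert np.array_equal(colocalize(a, ab).mask, ab.mask)
    assert ab.mask.sum() <= min(a.mask.sum(), b.mask.sum())
    disjoint = BinaryMask(~a.mask, "notA", 50)
    assert colocalize(a, disjoint).mask.sum() == 0
    with pytest.raises(ValueError, match="shape"):
        colocalize(a, BinaryMask(np.zeros((5, 5), bool), "C", 50))


def brute_force_cell_labels(seeds, shape, radius):
    """Exhaustive nearest-seed-within-radius oracle; np.argmin's
    first-minimum rule implements the lower-seed-index tie break."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    d2 = np.stack(
        [(xx - x) ** 2 + (yy - y) ** 2 for x, y in seeds]
    )
    nearest = np.argmin(d2, axis=0)
    dmin = np.min(d2, axis=0)
    labels = (nearest + 1).astype(np.int32)
    labels[dmin > radius**2] = 0
    return labels


def disk_pixel_count(radius):
    n = 0
    for dx in range(-radius, radius + 1):
        for dy in range(-radius, radius + 1):
            if dx * dx + dy * dy <= radius * radius:
                n += 1
    return n


def test_single_seed_disk():
    clm = cell_masks_from_seeds([(100, 120)], (256, 256), radius_px=15)
    assert clm.cell_mask(1).sum() == disk_pixel_count(15)
    assert np.array_equal(
        clm.labels, brute_force_cell_labels([(100, 120)], (256, 256), 15)
    )


def test_two_distant_seeds_are_independent_disks():
    clm = cell_masks_from_seeds([(60, 60), (160, 60)], (256, 256), radius_px=15)
    assert clm.cell_mask(1).sum() == disk_pixel_count(15)
    assert clm.cell_mask(2).sum() == disk_pixel_count(15)
    assert not (clm.cell_mask(1) & clm.cell_mask(2)).any()


def test_close_seeds_partition_at_bisector():
    seeds = [(50, 60), (60, 60)]  # 10 px apart on a shared axis
    clm = cell_masks_from_seeds(seeds, (128, 128), radius_px=15)
    assert np.array_equal(clm.labels, brute_force_cell_labels(seeds, (128, 128), 15))
    # the tie column (x = 55, equidistant) belongs to the lower seed index
    tie = clm.labels[60, 55]
    assert tie == 1


def test_random_seed_sets_match_oracle(rng):
    for _ in range(3):
        seeds = [tuple(p) for p in rng.integers(0, 128, size=(25, 2))]
        seeds = list(dict.fromkeys(seeds))  # dedupe, preserving order
        clm = cell_masks_from_seeds(seeds, (128, 128), radius_px=15)
        oracle = brute_force_cell_labels(seeds, (128, 128), 15)
        assert np.array_equal(clm.labels, oracle)
        # radius bound holds for every labelled pixel
        yy, xx = np.nonzero(clm.labels)
        pts = np.asarray(seeds)[clm.labels[yy, xx] - 1]
        d2 = (xx - pts[:, 0]) ** 2 + (yy - pts[:, 1]) ** 2
        assert np.all(d2 <= 15**2)


def test_skimage_watershed_equivalence(rng):
    """Independent route: watershed of the seed distance transform equals
    the radius-constrained nearest-seed partition (well-separated seeds,
    no equidistant pixels in doubt)."""
    skimage = pytest.importorskip("skimage.segmentation")
    from scipy import ndimage

    seeds = [(30, 40), (90, 50), (60, 110), (110, 110)]
    shape = (144, 144)
    markers = np.zeros(shape, dtype=np.int32)
    for k, (x, y) in enumerate(seeds, start=1):
        markers[y, x] = k
    dist = ndimage.distance_transform_edt(markers == 0)
    ws = skimage.watershed(dist, markers=markers)
    ws[dist > 15] = 0
    clm = cell_masks_from_seeds(seeds, shape, radius_px=15)
    agree = (ws == clm.labels).mean()
    assert agree > 0.999  # boundary ties aside, the partitions coincide


def test_duplicate_seeds_rejected():
    with pytest.raises(ValueError, match=r"indices \[0, 2\]"):
        cell_masks_from_seeds([(5, 5), (9, 9), (5, 5)], (32, 32))


def test_out_of_image_seed_gives_empty_cell():
    clm = cell_masks_from_seeds([(500.0, 500.0), (10.0, 10.0)], (64, 64), 15)
    assert clm.cell_mask(1).sum() == 0
    assert clm.cell_mask(2).sum() > 0


def test_radius_monotonicity_for_isolated_seeds():
    seeds = [(40, 40), (110, 110)]  # pairwise distance >> 2 * 15
    small = cell_masks_from_seeds(seeds, (160, 160), radius_px=10)
    large = cell_masks_from_seeds(seeds, (160, 160), radius_px=15)
    for k in (1, 2):
        assert np.all(large.cell_mask(k)[small.cell_mask(k)])


def test_count_seed_density(uniform_labels):
    # 10 seeds on 2 mm^2 of SI_N
    seeds = [(float(5 + i), 50.0) for i in range(10)]
    d = count_seed_density(seeds, RegionClass.SI_N, uniform_labels)
    assert d == pytest.approx(5.0)
    assert count_seed_density([], RegionClass.SI_N, uniform_labels) == 0.0
    with pytest.raises(ValueError, match="ICL"):
        count_seed_density(seeds, RegionClass.ICL, uniform_labels)
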