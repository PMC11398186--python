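import numpy as np
import pytest
from scipy import ndimage

from rhizocurl.skeletonize import Skeleton, bridge_gaps, prune_spurs, thin, zhang_suen

from .oracles import random_blob_mask, zhang_suen_reference

_S8 = np.ones((3, 3), int)


def n_components(img):
    return ndimage.label(img, structure=_S8)[1]


def test_thin_matches_naive_reference_on_random_masks():
    """Vectorized thinning is pixel-identical to a per-pixel reference."""
    rng = np.random.default_rng(42)
    for _ in range(15):
        mask = random_blob_mask(rng)
        np.testing.assert_array_equal(zhang_suen(mask), zhang_suen_reference(mask))


def test_thin_diagonal_line_unchanged():
    img = np.zeros((20, 20), bool)
    for i in range(3, 17):
        img[i, i] = True
    np.testing.assert_array_equal(thin(img).image, img)


def test_thin_bar_gives_single_spanning_path():
    img = np.zeros((20, 60), bool)
    img[8:13, 5:55] = True
    skel = thin(img).image
    # one pixel wide: no 2x2 block fully set
    assert not (skel[:-1, :-1] & skel[1:, :-1] & skel[:-1, 1:] & skel[1:, 1:]).any()
    assert n_components(skel) == 1
    cols = np.flatnonzero(skel.any(axis=0))
    assert cols[-1] - cols[0] >= 44  # spans nearly the bar length


def test_thin_preserves_components_and_empty_mask():
    img = np.zeros((30, 30), bool)
    img[5:10, 5:10] = True
    img[20:26, 18:26] = True
    skel = thin(img).image
    assert n_components(skel) == 2
    assert thin(np.zeros((5, 5), bool)).count() == 0


def test_thin_idempotent_and_never_adds_components():
    rng = np.random.default_rng(11)
    for _ in range(10):
        mask = random_blob_mask(rng)
        once = thin(mask).image
        twice = thin(once).image
        np.testing.assert_array_equal(once, twice)
        assert n_components(once) <= n_components(mask)


def _path_img(points, shape=(40, 120)):
    img = np.zeros(shape, bool)
    for r, c in points:
        img[r, c] = True
    return img


def test_prune_removes_short_spur_keeps_main_path():
    main = [(20, c) for c in range(5, 105)]
    spur = [(19, 50), (18, 50)]  # 2-px spur off a junction
    skel = Skeleton(_path_img(main + spur), (40, 120))
    pruned = prune_spurs(skel, min_branch_px=5)
    for p in spur:
        assert p not in pruned.pixels
    for p in main:
        assert p in pruned.pixels


def test_prune_no_junction_unchanged_and_subset():
    main = [(20, c) for c in range(5, 30)]
    skel = Skeleton(_path_img(main), (40, 120))
    assert prune_spurs(skel, 5).pixels == skel.pixels
    spurred = Skeleton(_path_img(main + [(19, 15), (18, 15), (17, 15)]), (40, 120))
    assert prune_spurs(spurred, 10).pixels <= spurred.pixels


def test_prune_boundary_spur_of_exact_length_retained():
    main = [(20, c) for c in range(5, 60)]
    spur = [(19, 30), (18, 30), (17, 30)]  # 3 px
    skel = Skeleton(_path_img(main + spur), (40, 120))
    kept = prune_spurs(skel, min_branch_px=3)
    for p in spur:
        assert p in kept.pixels
    gone = prune_spurs(skel, min_branch_px=4)
    assert all(p not in gone.pixels for p in spur)


def test_bridge_collinear_gap_connects():
    seg1 = [(20, c) for c in range(5, 25)]
    seg2 = [(20, c) for c in range(28, 48)]  # 3-px gap
    skel = Skeleton(_path_img(seg1 + seg2), (40, 120))
    assert n_components(skel.image) == 2
    bridged = bridge_gaps(skel, max_gap_px=10, max_slope_diff_deg=20)
    assert n_components(bridged.image) == 1


def test_bridge_rejects_perpendicular_segments():
    seg1 = [(20, c) for c in range(5, 25)]
    seg2 = [(r, 28) for r in range(21, 38)]  # 3 px away but perpendicular
    skel = Skeleton(_path_img(seg1 + seg2), (40, 120))
    bridged = bridge_gaps(skel, max_gap_px=10, max_slope_diff_deg=20)
    assert n_components(bridged.image) == 2


def test_bridge_out_of_range_unchanged_and_never_splits():
    seg1 = [(20, c) for c in range(5, 25)]
    seg2 = [(20, c) for c in range(40, 60)]  # 15-px gap > max
    skel = Skeleton(_path_img(seg1 + seg2), (40, 120))
    bridged = bridge_gaps(skel, max_gap_px=10, max_slope_diff_deg=20)
    assert bridged.pixels == skel.pixels
    assert n_components(bridged.image) <= n_components(skel.image)


def test_parameter_validation():
    skel = Skeleton(np.zeros((5, 5), bool), (5, 5))
    with pytest.raises(ValueError):
        prune_spurs(skel, 0)
    with pytest.raises(ValueError):
        bridge_gaps(skel, 0)
    with pytest.raises(ValueError):
        bridge_gaps(skel, 5, 120)
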