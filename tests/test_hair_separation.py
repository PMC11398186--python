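import numpy as np
import pytest

from rhizocurl import CrossingSpec, SceneSpec, render_scene
from rhizocurl.hair_separation import (
    NoAxisError,
    attach_hairs,
    build_graph,
    separate_hairs,
)
from rhizocurl.skeletonize import Skeleton, thin

from .conftest import HAIR_LAYOUT, recovered_for_truth, run_separation


def test_graph_of_axis_with_three_hairs(separated_hairs):
    mask, truth, hairs = separated_hairs
    assert len(hairs) == len(truth.hairs)
    starts = sorted(h.path[0][0] for h in hairs)
    assert starts == pytest.approx([row for row, _ in HAIR_LAYOUT], abs=3)


def test_separated_hairs_reach_ground_truth_tips(separated_hairs):
    mask, truth, hairs = separated_hairs
    for ht in truth.hairs:
        rec = recovered_for_truth(hairs, ht)
        tip_err = np.hypot(rec.path[-1][0] - ht.tip[0], rec.path[-1][1] - ht.tip[1])
        assert tip_err <= 5


def test_hair_paths_are_valid(separated_hairs):
    mask, truth, hairs = separated_hairs
    boundary = None
    for hair in hairs:
        path = hair.path
        assert len(path) == len(set(path))  # duplicate-free
        steps = np.abs(np.diff(np.asarray(path), axis=0)).max(axis=1)
        assert (steps <= 1).all()  # 8-connected
        assert hair.length_mm == pytest.approx(hair.length_px * mask.mm_per_pixel)
        # first coordinate adjacent to the attachment boundary pixel
        assert max(
            abs(path[0][0] - hair.attachment[0]), abs(path[0][1] - hair.attachment[1])
        ) <= 1


def test_hairs_disjoint_except_junctions(separated_hairs):
    _, _, hairs = separated_hairs
    for i, a in enumerate(hairs):
        for b in hairs[i + 1 :]:
            shared = set(a.path) & set(b.path)
            assert len(shared) <= 3  # junction pixels only


def test_separation_deterministic(separated_hairs, hair_scene):
    mask, _ = hair_scene
    _, _, first = separated_hairs
    second = run_separation(mask)
    assert [h.path for h in first] == [h.path for h in second]


def test_empty_skeleton_raises_no_axis():
    with pytest.raises(NoAxisError):
        build_graph(Skeleton(np.zeros((30, 30), bool), (30, 30)))


def test_too_thin_structure_raises_no_axis(calibration):
    from rhizocurl import BinaryMask

    img = np.zeros((40, 40), bool)
    img[20, 5:35] = True  # 1-px line: no structure of axis width
    mask = BinaryMask(img, calibration.mm_per_pixel)
    with pytest.raises(NoAxisError):
        build_graph(thin(mask), mask, axis_min_width_px=5)


def test_floating_debris_dropped(calibration):
    from rhizocurl import BinaryMask

    img = np.zeros((120, 200), bool)
    img[10:110, 20:29] = True  # axis bar
    for c in range(30, 60):
        img[50, c] = True  # attached hair
    for c in range(90, 120):
        img[100, c] = True  # debris 60 px from the axis
    mask = BinaryMask(img, calibration.mm_per_pixel)
    graph = attach_hairs(build_graph(thin(mask), mask), max_gap_px=10)
    assert len(graph.attachments) == 1
    assert graph.dropped_hairs == 1
    hairs = separate_hairs(graph)
    assert len(hairs) == 1


def test_detached_hair_attached_across_small_gap(calibration):
    from rhizocurl import BinaryMask

    img = np.zeros((120, 200), bool)
    img[10:110, 20:29] = True
    for c in range(32, 70):  # 3-px gap to the axis surface at col 28
        img[60, c] = True
    mask = BinaryMask(img, calibration.mm_per_pixel)
    graph = attach_hairs(build_graph(thin(mask), mask), max_gap_px=10)
    assert len(graph.attachments) == 1
    hairs = separate_hairs(graph)
    assert len(hairs) == 1
    # the bridged path starts adjacent to the axis boundary
    assert hairs[0].path[0][1] <= 32


@pytest.mark.parametrize("pattern", ["a", "b", "c", "d"])
def test_crossing_patterns_resolved(pattern):
    """Junction rules pick the correct continuation for each pattern."""
    mask, truth = render_scene(
        SceneSpec(image_shape=(600, 600), crossings=[CrossingSpec(pattern=pattern)], seed=9)
    )
    hairs = run_separation(mask)
    for ht in truth.crossing_hairs[0]:
        rec = recovered_for_truth(hairs, ht)
        target = ht.tip if ht.expect == "full" else ht.terminate_at
        err = np.hypot(rec.path[-1][0] - target[0], rec.path[-1][1] - target[1])
        assert err <= 8, f"pattern {pattern}: endpoint off by {err:.1f} px"


def test_end_zone_turn_accepted_mid_zone_rejected():
    """A ~60-deg branch is followed near the tip (80-deg rule) but a
    moderate branch mid-hair is rejected (30-deg rule) and the hair ends."""
    mask_c, truth_c = render_scene(
        SceneSpec(image_shape=(600, 600), crossings=[CrossingSpec(pattern="c")], seed=4)
    )
    hairs = run_separation(mask_c)
    corner_hair = truth_c.crossing_hairs[0][0]
    rec = recovered_for_truth(hairs, corner_hair)
    assert corner_hair.turning_deg > 40  # its true path turns sharply at the end
    tip_err = np.hypot(rec.path[-1][0] - corner_hair.tip[0], rec.path[-1][1] - corner_hair.tip[1])
    assert tip_err <= 8

    mask_d, truth_d = render_scene(
        SceneSpec(image_shape=(600, 600), crossings=[CrossingSpec(pattern="d")], seed=4)
    )
    hairs_d = run_separation(mask_d)
    short_hair = truth_d.crossing_hairs[0][0]
    assert short_hair.expect == "terminate"
    rec_d = recovered_for_truth(hairs_d, short_hair)
    term_err = np.hypot(
        rec_d.path[-1][0] - short_hair.terminate_at[0],
        rec_d.path[-1][1] - short_hair.terminate_at[1],
    )
    assert term_err <= 8
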