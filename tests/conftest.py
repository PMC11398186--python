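import numpy as np
import pytest

from rhizocurl import Calibration, HairSpec, SceneSpec, render_scene
from rhizocurl.hair_separation import attach_hairs, build_graph, separate_hairs
from rhizocurl.skeletonize import bridge_gaps, prune_spurs, thin


@pytest.fixture
def calibration() -> Calibration:
    return Calibration(mm_per_pixel=0.01, visible_depth_L=1.0)


#: attachment rows and total turning of the shared multi-hair scene
HAIR_LAYOUT = [(120, 45.0), (330, 90.0), (540, 180.0), (750, 268.0), (960, 0.0)]


@pytest.fixture(scope="session")
def hair_scene():
    """One axis with five hairs of known turning, rendered once per session."""
    spec = SceneSpec(
        image_shape=(1100, 1100),
        hairs=[
            HairSpec(attachment_row=row, length_px=400,
                     total_turning_deg=turn, turn_start_fraction=0.6)
            for row, turn in HAIR_LAYOUT
        ],
        seed=3,
    )
    return render_scene(spec)


@pytest.fixture(scope="session")
def separated_hairs(hair_scene):
    """The shared scene pushed through the full separation pipeline."""
    mask, truth = hair_scene
    skel = bridge_gaps(prune_spurs(thin(mask), 5), 10, 20.0)
    graph = attach_hairs(build_graph(skel, mask), 10)
    return mask, truth, separate_hairs(graph)


def run_separation(mask):
    skel = bridge_gaps(prune_spurs(thin(mask), 5), 10, 20.0)
    graph = attach_hairs(build_graph(skel, mask), 10)
    return separate_hairs(graph)


def recovered_for_truth(hairs, hair_truth):
    """The separated hair whose start is nearest a ground-truth hair's start."""
    best, best_d = None, np.inf
    for hair in hairs:
        d = np.hypot(
            hair.path[0][0] - hair_truth.start[0],
            hair.path[0][1] - hair_truth.start[1],
        )
        if d < best_d:
            best, best_d = hair, d
    return best
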