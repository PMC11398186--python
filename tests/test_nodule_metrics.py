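import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rhizocurl import (
    BinaryMask,
    Calibration,
    NoduleSpec,
    SceneSpec,
    apply_conversion_policy,
    detect_nodules,
    observed_diameter,
    real_diameter,
    render_scene,
    visible_chord,
)
from rhizocurl.hair_separation import build_graph
from rhizocurl.skeletonize import thin

# observed vs calculated mean nodule diameters (mm) at L = 1 mm, by day
CONVERSION_TABLE = {
    25: (1.14, 1.32),
    30: (2.33, 2.36),
    35: (3.33, 3.77),
    40: (3.82, 4.65),
    45: (4.16, 5.33),
}


@pytest.mark.parametrize("day", sorted(CONVERSION_TABLE))
def test_conversion_reproduces_reference_row(day):
    d, expected = CONVERSION_TABLE[day]
    assert round(real_diameter(d, 1.0), 2) == expected


def test_degenerate_and_equality_points():
    assert real_diameter(0.0, 1.0) == pytest.approx(1.0)  # chord vanishes: D = L
    assert real_diameter(2.0, 1.0) == pytest.approx(2.0)  # d = 2L: D = d exactly
    with pytest.raises(ValueError):
        real_diameter(1.0, 0.0)
    with pytest.raises(ValueError):
        real_diameter(-1.0, 1.0)


def test_monotonicity_and_minimum():
    """D grows with the chord (minimum D = L at d = 0) while the
    conversion gap D - d shrinks below d = 2L, vanishes there exactly,
    and grows again above it."""
    d = np.linspace(0, 10, 2001)
    D = np.array([real_diameter(x, 1.0) for x in d])
    assert (np.diff(D) > 0).all()
    assert D[0] == pytest.approx(1.0) and D.min() >= 1.0
    gap = D - d
    assert (np.diff(gap[d <= 2.0]) < 0).all()
    assert (np.diff(gap[d >= 2.0]) > 0).all()
    assert gap.min() >= -1e-12
    assert real_diameter(2.0, 1.0) == pytest.approx(2.0)


@settings(deadline=None, derandomize=True)
@given(
    D=st.floats(min_value=1.0, max_value=10.0, allow_nan=False),
    L=st.floats(min_value=0.2, max_value=3.0, allow_nan=False),
)
def test_chord_round_trip_property(D, L):
    """Sectioning then converting recovers any sphere with D >= L."""
    if D < L:
        D, L = L, D
    if D == 0 or L == 0:
        return
    d = visible_chord(D, L)
    assert real_diameter(d, L) == pytest.approx(D, rel=1e-9, abs=1e-9)
    assert d <= D + 1e-12


def test_chord_round_trip_is_exact_inverse():
    for D in np.linspace(1.0, 10.0, 181):
        d = visible_chord(D, 1.0)
        assert real_diameter(d, 1.0) == pytest.approx(D, abs=1e-9)
    with pytest.raises(ValueError):
        visible_chord(0.5, 1.0)


def test_conversion_policy_threshold(calibration):
    not_conv = apply_conversion_policy(0.71, calibration)
    assert not not_conv.converted and not_conv.real_D_mm == pytest.approx(0.71)
    conv = apply_conversion_policy(1.14, calibration)
    assert conv.converted and round(conv.real_D_mm, 2) == 1.32
    boundary = apply_conversion_policy(1.0, calibration)  # strictly over L converts
    assert not boundary.converted


def test_observed_diameter_of_rendered_disc():
    mm_per_px = 0.05
    img = np.zeros((60, 60), bool)
    yy, xx = np.ogrid[:60, :60]
    img |= ((yy - 30) ** 2 + (xx - 30.5) ** 2) <= 19.8**2  # 40-px diameter
    mask = BinaryMask(img, mm_per_px)
    d = observed_diameter(mask, np.argwhere(img))
    assert d == pytest.approx(2.0, abs=mm_per_px)


def test_observed_diameter_tiny_regions():
    mask = BinaryMask(np.ones((5, 5), bool), 0.05)
    assert observed_diameter(mask, [(2, 2)]) == pytest.approx(0.05)
    assert observed_diameter(mask, [(2, 2), (2, 3)]) == pytest.approx(0.10)
    with pytest.raises(ValueError):
        observed_diameter(mask, [])


def test_equivalent_area_diameter_option():
    img = np.zeros((60, 60), bool)
    yy, xx = np.ogrid[:60, :60]
    img |= ((yy - 30) ** 2 + (xx - 30) ** 2) <= 15**2
    mask = BinaryMask(img, 1.0)
    d = observed_diameter(mask, np.argwhere(img), method="equivalent_area")
    assert d == pytest.approx(30.0, rel=0.05)


def _axis_graph(mask):
    return build_graph(thin(mask), mask)


def test_detect_single_bulge_and_plain_axis(calibration):
    img = np.zeros((200, 200), bool)
    img[10:190, 40:49] = True
    mask_plain = BinaryMask(img.copy(), calibration.mm_per_pixel)
    assert detect_nodules(mask_plain, _axis_graph(mask_plain)) == []

    yy, xx = np.ogrid[:200, :200]
    img |= ((yy - 100) ** 2 + (xx - 61) ** 2) <= 14**2  # ~3x axis width bulge
    mask = BinaryMask(img, calibration.mm_per_pixel)
    regions = detect_nodules(mask, _axis_graph(mask))
    assert len(regions) == 1


def test_detect_two_bulges_on_opposite_flanks(calibration):
    img = np.zeros((260, 200), bool)
    img[10:250, 90:99] = True
    yy, xx = np.ogrid[:260, :200]
    img |= ((yy - 70) ** 2 + (xx - 112) ** 2) <= 14**2
    img |= ((yy - 190) ** 2 + (xx - 76) ** 2) <= 14**2
    mask = BinaryMask(img, calibration.mm_per_pixel)
    regions = detect_nodules(mask, _axis_graph(mask))
    assert len(regions) == 2


def test_rendered_nodule_round_trip():
    """A buried-sphere cap rendered at day-45 scale measures back to its
    true diameter through the full detect/measure/convert chain."""
    spec = SceneSpec(
        image_shape=(900, 900),
        nodules=[NoduleSpec(true_D_mm=5.33, attachment_row=450)],
        seed=5,
    )
    mask, truth = render_scene(spec)
    regions = detect_nodules(mask, _axis_graph(mask))
    assert len(regions) == 1
    d = observed_diameter(mask, regions[0])
    assert d == pytest.approx(truth.nodules[0].expected_d_mm, abs=0.02)
    meas = apply_conversion_policy(d, Calibration(0.01, 1.0))
    assert meas.converted
    assert meas.real_D_mm == pytest.approx(5.33, abs=0.03)
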