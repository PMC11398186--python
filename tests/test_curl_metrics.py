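import math

import numpy as np
import pytest

from rhizocurl import arc_hair_path
from rhizocurl.curl_metrics import (
    CurlMeasurement,
    HairTooShortError,
    classify_curled,
    curl_angle,
    summarize_group,
)
from rhizocurl.hair_separation import RootHair

from .conftest import recovered_for_truth

TURNS = [0.0, 45.0, 90.0, 135.0, 180.0, 225.0, 268.0]


def make_hair(turning, heading=0.0, length=400.0, sign=1):
    path = arc_hair_path((700, 700), heading, length, turning, 0.6, sign)
    return RootHair(hair_id=0, path=path, attachment=path[0])


def test_straight_hair_is_zero():
    hair = make_hair(0.0, length=60.0)
    m = curl_angle(hair)
    assert m.beta_deg == pytest.approx(0.0, abs=1.0)
    assert m.beta_arccos_deg == pytest.approx(0.0, abs=1.0)
    assert not m.curled


def test_quarter_circle_tail_reads_ninety():
    m = curl_angle(make_hair(90.0))
    assert m.beta_deg == pytest.approx(90.0, abs=5.0)


@pytest.mark.parametrize("turning", TURNS)
def test_parameter_recovery_within_five_degrees(turning):
    """Hairs of known total turning are recovered within 5 degrees."""
    m = curl_angle(make_hair(turning))
    assert m.beta_deg == pytest.approx(turning, abs=5.0)


@pytest.mark.parametrize("turning", [t for t in TURNS if t <= 180.0])
def test_arccos_and_extended_agree_below_180(turning):
    m = curl_angle(make_hair(turning))
    assert m.beta_arccos_deg == pytest.approx(m.beta_deg, abs=5.0)


def test_reflex_angle_exceeds_arccos_cap():
    """Past 180 deg the cumulative estimator keeps rising while the
    arccos value folds back — the reason the extension exists."""
    m = curl_angle(make_hair(268.0))
    assert m.beta_deg > 180.0
    assert m.beta_arccos_deg < 180.0


def test_rigid_motion_invariance():
    """Rotating and translating the same path changes the angle < 1 deg."""
    path = np.asarray(make_hair(135.0).path, float)
    base = curl_angle(RootHair(0, [tuple(p) for p in path], tuple(path[0]))).beta_deg
    for k in range(1, 8):
        ang = k * math.pi / 4 + 0.1
        R = np.array([[math.cos(ang), -math.sin(ang)], [math.sin(ang), math.cos(ang)]])
        moved = path @ R.T + np.array([37.5, -12.25])
        rotated = RootHair(0, [tuple(p) for p in moved], tuple(moved[0]))
        assert curl_angle(rotated).beta_deg == pytest.approx(base, abs=1.0)


def test_point_convention_and_dl():
    hair = make_hair(90.0)
    m = curl_angle(hair)
    n = len(hair.path)
    mid = (n - 1) // 2
    assert m.P_i == hair.path[mid]
    assert m.P_j == hair.path[mid + 5]
    assert m.P_l == hair.path[-1]
    assert m.P_k == hair.path[-6]
    assert m.dL_px == (n - 6) - mid


def test_too_short_hair_rejected():
    path = [(0, c) for c in range(11)]
    with pytest.raises(HairTooShortError):
        curl_angle(RootHair(0, path, path[0]))
    assert RootHair(0, path, path[0], too_short=True).too_short


def _meas(beta):
    return CurlMeasurement(0, beta, beta, (0, 0), (0, 5), (0, 10), (0, 15), 10, beta > 90)


@pytest.mark.parametrize(
    "beta,expected", [(40.0, False), (90.0, False), (91.0, True), (268.0, True)]
)
def test_classify_curled_strict_threshold(beta, expected):
    assert classify_curled(_meas(beta)) is expected


def test_classify_with_custom_threshold():
    assert classify_curled(_meas(50.0), threshold_deg=45.0)


def test_summary_matches_brute_force():
    rng = np.random.default_rng(0)
    betas = rng.uniform(0, 300, size=30)
    ms = [_meas(float(b)) for b in betas]
    s = summarize_group(ms, "C", day=8)
    assert s.mean_beta_deg == pytest.approx(float(np.mean(betas)), abs=1e-9)
    assert s.sd_beta_deg == pytest.approx(float(np.std(betas, ddof=1)), abs=1e-9)
    assert s.n_hairs == 30
    assert s.proportion_curled == pytest.approx(float(np.mean(betas > 90)), abs=1e-12)


def test_summary_edge_cases():
    flat = [_meas(0.0) for _ in range(30)]
    s = summarize_group(flat, "control")
    assert s.mean_beta_deg == 0.0 and s.proportion_curled == 0.0
    mixed = [_meas(100.0)] * 10 + [_meas(10.0)] * 20
    assert summarize_group(mixed, "B").proportion_curled == pytest.approx(1 / 3)
    with pytest.raises(ValueError):
        summarize_group([], "A")


def test_pipeline_recovers_turning(separated_hairs):
    """Turning angles survive thinning + separation within 5 degrees."""
    _, truth, hairs = separated_hairs
    for ht in truth.hairs:
        rec = recovered_for_truth(hairs, ht)
        m = curl_angle(rec)
        assert m.beta_deg == pytest.approx(ht.turning_deg, abs=5.0)
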