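"""Root-hair curling angle and curled-hair classification.

The curling angle β of a hair is the change of direction between the
tangent at the hair's midpoint and the tangent at its tip.  Four points
define it on the pixel path: Pi is the path midpoint, Pj the point 5
pixels further, Pl the endpoint and Pk the point 5 pixels before it; the
base definition is

    β = arccos( (PiPj · PkPl) / (|PiPj| |PkPl|) )

Tight curls exceed 180°, which an arccos cannot express, so the reported
angle is the cumulative turning along the path from Pi to Pl, accumulated
from signed tangent increments over 5-pixel windows.  The cumulative value
coincides with the arccos below 180° and extends it monotonically past it;
the raw arccos value is also reported for transparency.  A hair is
*curled* when β strictly exceeds 90°: uninfected hairs are wavy but stay
below ~45°, so 90° separates rhizobia-induced curling from baseline
waviness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .hair_separation import RootHair

__all__ = [
    "CurlMeasurement",
    "CurlSummary",
    "curl_angle",
    "classify_curled",
    "summarize_group",
    "MIN_MEASURABLE_PX",
]

#: minimum measurable path length: midpoint + 5 forward and endpoint − 5
#: backward must not overlap
MIN_MEASURABLE_PX = 12


class HairTooShortError(ValueError):
    """Hair path too short for the 5-pixel tangent windows."""


@dataclass
class CurlMeasurement:
    """Curling angle of one hair with its four defining points."""

    hair_id: int
    beta_deg: float
    beta_arccos_deg: float
    P_i: tuple[int, int]
    P_j: tuple[int, int]
    P_k: tuple[int, int]
    P_l: tuple[int, int]
    dL_px: int
    curled: bool


@dataclass
class CurlSummary:
    """Per-group curl statistics (mean ± sample SD and curled fraction)."""

    group_label: str
    day: int
    mean_beta_deg: float
    sd_beta_deg: float
    n_hairs: int
    proportion_curled: float


def _smooth_path(path: np.ndarray, w: int = 7) -> np.ndarray:
    """Moving-average smoothing of a pixel path (edge-replicated).

    Suppresses the ±atan(1/window) staircase noise of chord tangents on
    rasterized curves; with curl radii of tens of pixels the bias of a
    7-px window is negligible."""
    if w < 2 or len(path) < w + 2:
        return path
    half = w // 2
    kernel = np.ones(w) / w
    cols = [
        np.convolve(np.pad(path[:, i], (half, half), mode="edge"), kernel, "valid")
        for i in (0, 1)
    ]
    return np.column_stack(cols)


def _tangent_angles(path: np.ndarray, start: int, stop: int, window: int) -> np.ndarray:
    """Tangent angle (radians) of each ``window``-px chord from index
    ``start`` to ``stop`` inclusive, unwrapped to a continuous sequence."""
    idx = np.arange(start, stop + 1)
    chords = path[idx + window] - path[idx]
    theta = np.arctan2(chords[:, 0], chords[:, 1])
    return np.unwrap(theta)


def _arclength(path: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    steps = np.linalg.norm(np.diff(path, axis=0), axis=1)
    return steps, np.concatenate([[0.0], np.cumsum(steps)])


def _head_tangent(path: np.ndarray, span_px: float = 18.0) -> float:
    """Tangent (radians) at the start of a path span, by a total-least-squares
    line over the first ``span_px`` of arclength.

    Curling concentrates at the hair tip, so the path near the midpoint is
    locally straight; a long-baseline line fit resolves shallow staircase
    slopes that a single 5-px chord cannot.
    """
    _, s = _arclength(path)
    pts = path[s <= span_px]
    if len(pts) < 2:
        pts = path[: max(2, min(len(path), 6))]
    centred = pts - pts.mean(axis=0)
    direction = np.linalg.svd(centred, full_matrices=False)[2][0]
    if np.dot(direction, pts[-1] - pts[0]) < 0:
        direction = -direction
    return math.atan2(direction[0], direction[1])


def _tail_tangent(path: np.ndarray, span_px: float = 30.0, n_kappa: int = 45) -> float:
    """Tangent (radians) at the end of a path span.

    The chord over the last ``span_px`` equals the tangent at the chord's
    arclength midpoint for a constant-curvature curve; a curvature estimate
    (slope of the unwrapped 5-px-window tangent angles over the last
    ``n_kappa`` windows) rotates it out to the endpoint.
    """
    steps, s = _arclength(path)
    sel = s >= s[-1] - span_px
    pts = path[sel]
    if len(pts) < 2:
        pts = path[-max(2, min(len(path), 6)) :]
    chord = pts[-1] - pts[0]
    theta_chord = math.atan2(chord[0], chord[1])
    theta = _tangent_angles(path, 0, len(path) - 6, 5) if len(path) >= 7 else None
    kappa = 0.0
    if theta is not None and len(theta) >= 6:
        k = min(n_kappa, len(theta))
        kappa = float(np.polyfit(np.arange(k), theta[-k:], 1)[0])
        kappa /= float(steps[-k:].mean())
    span_arc = float(s[sel][-1] - s[sel][0]) if sel.any() else 0.0
    return theta_chord + kappa * span_arc / 2.0


def curl_angle(
    hair: RootHair, window: int = 5, curl_threshold_deg: float = 90.0
) -> CurlMeasurement:
    """Measure the curling angle of a separated root hair.

    The path must be ordered axis → tip and at least 12 px long.  The
    extended estimator integrates signed tangent increments of 5-px chord
    windows from Pi to Pl and corrects for the half-window of turning the
    chords cannot see at each end of the span (estimated from the local
    turning rate); for a constant-curvature arc this recovers the true
    turning exactly, and below 180° it agrees with the direct arccos.
    """
    path = np.asarray(hair.path, dtype=float)
    n = len(path)
    if n < MIN_MEASURABLE_PX:
        raise HairTooShortError(
            f"hair {hair.hair_id}: {n} px < {MIN_MEASURABLE_PX} px minimum"
        )
    mid = (n - 1) // 2  # lower median for even-length paths
    Pi = tuple(int(round(v)) for v in path[mid])
    Pj = tuple(int(round(v)) for v in path[mid + window])
    Pl = tuple(int(round(v)) for v in path[n - 1])
    Pk = tuple(int(round(v)) for v in path[n - 1 - window])

    smoothed = _smooth_path(path)
    v1 = smoothed[mid + window] - smoothed[mid]
    v2 = smoothed[n - 1] - smoothed[n - 1 - window]
    denom = np.linalg.norm(v1) * np.linalg.norm(v2)
    cosb = float(np.clip(np.dot(v1, v2) / denom, -1.0, 1.0)) if denom else 1.0
    beta_arccos = math.degrees(math.acos(cosb))

    # winding from cumulative 5-px-window increments (coarse but tracks
    # turns past 180°); end tangents from long-baseline local fits
    theta = _tangent_angles(smoothed, mid, n - 1 - window, window)
    coarse = theta[-1] - theta[0]
    span = path[mid:]
    t_head = _head_tangent(span)
    t_tail = _tail_tangent(span)
    wrapped = (t_tail - t_head + math.pi) % (2 * math.pi) - math.pi
    net = wrapped + 2 * math.pi * round((coarse - wrapped) / (2 * math.pi))
    beta = abs(math.degrees(net))

    return CurlMeasurement(
        hair_id=hair.hair_id,
        beta_deg=beta,
        beta_arccos_deg=beta_arccos,
        P_i=Pi,
        P_j=Pj,
        P_k=Pk,
        P_l=Pl,
        dL_px=(n - 1 - window) - mid,
        curled=classify_curled_value(beta, curl_threshold_deg),
    )


def classify_curled_value(beta_deg: float, threshold_deg: float = 90.0) -> bool:
    """True iff the angle strictly exceeds the curling threshold."""
    return beta_deg > threshold_deg


def classify_curled(measurement: CurlMeasurement, threshold_deg: float = 90.0) -> bool:
    """Classify a measured hair as curled (β strictly over ``threshold_deg``)."""
    return classify_curled_value(measurement.beta_deg, threshold_deg)


def summarize_group(
    measurements: list[CurlMeasurement], group_label: str, day: int = 0
) -> CurlSummary:
    """Mean, sample SD (n−1), count and curled fraction for one group.

    The SD of a single measurement is reported as NaN.
    """
    if not measurements:
        raise ValueError("summarize_group requires at least one measurement")
    betas = np.asarray([m.beta_deg for m in measurements], dtype=float)
    n = len(betas)
    sd = float(np.std(betas, ddof=1)) if n > 1 else float("nan")
    return CurlSummary(
        group_label=group_label,
        day=day,
        mean_beta_deg=float(betas.mean()),
        sd_beta_deg=sd,
        n_hairs=n,
        proportion_curled=float(np.mean([m.curled for m in measurements])),
    )
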