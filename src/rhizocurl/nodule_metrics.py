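"""Nodule diameter measurement and observed→real conversion.

A nodule is close to a buried sphere, and the imaging window perceives
only the soil down to the visible depth L (about 1 mm for micro- and
minirhizotrons).  Once the sphere's diameter exceeds L, the visible
cross-section is a chord d smaller than the true diameter D.  Sectioning
a sphere of diameter D at depth L gives the chord

    d = 2·sqrt(L·(D − L)),

whose inverse is the conversion applied to observed diameters:

    D = (4L² + d²) / (4L).

Observed diameters at or below L are reported unconverted: such nodules
are still fully within the visible layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull

from .hair_separation import SkeletonGraph
from .mask_io import BinaryMask, Calibration

__all__ = [
    "NoduleMeasurement",
    "real_diameter",
    "visible_chord",
    "apply_conversion_policy",
    "observed_diameter",
    "detect_nodules",
]

_STRUCT8 = np.ones((3, 3), int)


@dataclass
class NoduleMeasurement:
    """Observed diameter d, visible depth L and real diameter D of a nodule."""

    nodule_id: int
    day: int
    observed_d_mm: float
    visible_depth_L_mm: float
    real_D_mm: float
    converted: bool


def real_diameter(observed_d_mm: float, visible_depth_L_mm: float) -> float:
    """Real sphere diameter from a visible chord at depth L.

    D = (4L² + d²)/(4L); strictly decreasing in d below d = 2L and
    increasing above, with minimum D = L at d = 0.
    """
    if observed_d_mm < 0:
        raise ValueError(f"observed diameter must be >= 0, got {observed_d_mm}")
    if visible_depth_L_mm <= 0:
        raise ValueError(f"visible depth L must be > 0, got {visible_depth_L_mm}")
    L, d = visible_depth_L_mm, observed_d_mm
    return (4.0 * L * L + d * d) / (4.0 * L)


def visible_chord(true_D_mm: float, visible_depth_L_mm: float) -> float:
    """Chord visible at depth L of a buried sphere of diameter D (inverse
    of :func:`real_diameter` for D ≥ L)."""
    L, D = visible_depth_L_mm, true_D_mm
    if D < L:
        raise ValueError(f"sphere of diameter {D} lies within the visible depth {L}")
    return 2.0 * math.sqrt(L * (D - L))


def apply_conversion_policy(
    observed_d_mm: float,
    calibration: Calibration,
    nodule_id: int = 0,
    day: int = 0,
) -> NoduleMeasurement:
    """Convert an observed diameter to the real diameter when it exceeds L.

    Diameters strictly over the visible depth are converted with
    :func:`real_diameter`; smaller ones are reported as-is, flagged not
    converted (the nodule is still fully visible).
    """
    L = calibration.visible_depth_L
    if observed_d_mm > L:
        return NoduleMeasurement(
            nodule_id, day, observed_d_mm, L, real_diameter(observed_d_mm, L), True
        )
    return NoduleMeasurement(nodule_id, day, observed_d_mm, L, observed_d_mm, False)


def _feret_extent_px(coords: np.ndarray) -> float:
    """Maximal Feret extent of a pixel region, in pixels.

    Computed as the maximum pairwise centre distance over the convex hull
    plus one pixel, so a single pixel has extent 1 and an n-pixel row has
    extent n.
    """
    if len(coords) == 1:
        return 1.0
    pts = coords.astype(float)
    if len(pts) > 3:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except Exception:  # collinear region: qhull degenerate, use all points
            pass
    diff = pts[:, None, :] - pts[None, :, :]
    dmax = float(np.sqrt((diff**2).sum(-1)).max())
    return dmax + 1.0


def observed_diameter(
    mask: BinaryMask,
    blob_region: Iterable[tuple[int, int]] | np.ndarray,
    method: Literal["feret", "equivalent_area"] = "feret",
) -> float:
    """Observed diameter of a nodule region, in mm.

    ``feret`` (default) is the maximal caliper extent — nodules are
    near-circular caps and perceived widths are caliper widths;
    ``equivalent_area`` is the diameter of the circle of equal area.
    """
    coords = np.asarray(list(blob_region) if not isinstance(blob_region, np.ndarray) else blob_region)
    if coords.size == 0:
        raise ValueError("empty nodule region")
    if method == "feret":
        extent = _feret_extent_px(coords)
    elif method == "equivalent_area":
        extent = 2.0 * math.sqrt(len(coords) / math.pi)
    else:
        raise ValueError(f"unknown diameter method {method!r}")
    return extent * mask.mm_per_pixel


def detect_nodules(
    mask: BinaryMask,
    skeleton_graph: SkeletonGraph,
    swell_factor: float = 2.0,
) -> list[np.ndarray]:
    """Detect nodule candidate regions as swellings initiated at the axis.

    A nodule core is a foreground region whose local width (twice the
    distance transform) exceeds ``swell_factor`` × the median axis width.
    Each core adjacent to the axis region is grown back to the full disc:
    all mask pixels within the core's maximal inscribed radius of its
    deepest point.  Returns a list of (n, 2) coordinate arrays, raster
    ordered by core position; an empty list if the axis bears no swelling.
    """
    dt = ndimage.distance_transform_edt(mask.pixels)
    width_thresh = swell_factor * skeleton_graph.median_axis_width_px
    core = mask.pixels & (2.0 * dt > width_thresh)
    lab, n = ndimage.label(core, structure=_STRUCT8)
    if n == 0:
        return []
    # adjacency to the axis region (within a small dilation)
    near_axis = ndimage.binary_dilation(
        skeleton_graph.axis_region, structure=_STRUCT8, iterations=2
    )
    regions: list[np.ndarray] = []
    order = []
    for lab_id in range(1, n + 1):
        comp = lab == lab_id
        if not (comp & near_axis).any():
            # cores buried deep inside the axis region still qualify if they
            # stick out of it; cores fully disjoint from the axis do not
            continue
        coords = np.argwhere(comp)
        deepest = coords[np.argmax(dt[tuple(coords.T)])]
        radius = float(dt[tuple(deepest)])
        yy, xx = np.ogrid[: mask.pixels.shape[0], : mask.pixels.shape[1]]
        disc = ((yy - deepest[0]) ** 2 + (xx - deepest[1]) ** 2) <= (radius + 0.5) ** 2
        region = np.argwhere(mask.pixels & disc)
        order.append((tuple(deepest), len(regions)))
        regions.append(region)
    order.sort()
    return [regions[i] for _, i in order]
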