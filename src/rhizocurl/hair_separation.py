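"""Root-axis identification and separation of crossing root hairs.

The skeleton is decomposed into a pixel graph; the root axis is the
structure that was thick before thinning (axes are millimetre-scale, hairs
tens of microns).  Hairs are attached to the axis boundary and each hair is
traced from its attachment point to its tip.  At skeleton junctions — where
hairs cross or overlap — the continuation with the smallest change of
tangent direction is taken, subject to a positional threshold: root hairs
grow smoothly, so mid-hair the allowed direction change is small (30° by
default), while near the tip, where curling concentrates, a larger change
(80°) is accepted.  If no continuation passes, the hair ends at the
junction ("no sudden break point").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from . import _pixelgraph
from ._pixelgraph import PixelGraph, angle_between_deg, chain_direction, signed_angle_deg
from .mask_io import BinaryMask
from .skeletonize import Skeleton

logger = logging.getLogger(__name__)

__all__ = ["SkeletonGraph", "RootHair", "build_graph", "attach_hairs", "separate_hairs"]

_STRUCT8 = np.ones((3, 3), int)


@dataclass
class RootHair:
    """One separated root hair: an ordered pixel path from axis to tip."""

    hair_id: int
    path: list[tuple[int, int]]
    attachment: tuple[int, int]
    mm_per_pixel: float = 1.0
    too_short: bool = False

    @property
    def length_px(self) -> int:
        return len(self.path)

    @property
    def length_mm(self) -> float:
        return self.length_px * self.mm_per_pixel


@dataclass
class SkeletonGraph:
    """Skeleton pixel graph with the root axis identified.

    ``axis_pixels`` are the skeleton pixels classified as axis (one
    connected component); ``axis_boundary`` are the raster-ordered boundary
    coordinates of the axis region in the pre-thinning mask, used to attach
    hairs.  ``hair_graph`` is the pixel graph of the non-axis skeleton.
    """

    skeleton: Skeleton
    mask: BinaryMask | None
    axis_pixels: set[tuple[int, int]]
    axis_boundary: list[tuple[int, int]]
    axis_region: np.ndarray
    hair_graph: PixelGraph
    mm_per_pixel: float = 1.0
    attachments: list[dict] = field(default_factory=list)
    dropped_hairs: int = 0
    median_axis_width_px: float = 0.0


class NoAxisError(ValueError):
    """Raised when no structure qualifies as a root axis."""


def _largest_component(img: np.ndarray) -> np.ndarray:
    lab, n = ndimage.label(img, structure=_STRUCT8)
    if n == 0:
        return np.zeros_like(img)
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=range(1, n + 1))
    return lab == (1 + int(np.argmax(sizes)))


def build_graph(
    skeleton: Skeleton,
    mask: BinaryMask | None = None,
    axis_min_width_px: float = 5.0,
    axis_min_px: int = 20,
) -> SkeletonGraph:
    """Decompose a skeleton and identify the root axis.

    With the pre-thinning ``mask`` available, the axis is the largest
    connected set of skeleton pixels whose local width (twice the mask's
    Euclidean distance transform) is at least ``axis_min_width_px`` — axes
    are visibly thicker than hairs.  Without a mask the longest single
    chain of at least ``axis_min_px`` pixels is used as a fallback.
    """
    skel_img = skeleton.image
    if skel_img.sum() == 0:
        raise NoAxisError("empty skeleton: no axis found")

    if mask is not None:
        dt = ndimage.distance_transform_edt(mask.pixels)
        width = 2.0 * dt * skel_img
        wide = skel_img & (width >= axis_min_width_px)
        axis_img = _largest_component(wide)
        if axis_img.sum() == 0:
            raise NoAxisError(
                f"no skeleton structure of width >= {axis_min_width_px} px"
            )
        axis_pixels = {tuple(p) for p in np.argwhere(axis_img)}
        median_width = float(np.median(width[axis_img]))
        # axis region: mask pixels whose nearest skeleton pixel is an axis pixel
        skel_coords = np.argwhere(skel_img)
        axis_flags = axis_img[tuple(skel_coords.T)]
        tree = cKDTree(skel_coords)
        mask_coords = np.argwhere(mask.pixels)
        _, nearest = tree.query(mask_coords, k=1)
        region = np.zeros_like(skel_img)
        sel = axis_flags[nearest]
        region[tuple(mask_coords[sel].T)] = True
    else:
        graph_all = _pixelgraph.decompose(skel_img)
        if not graph_all.edges:
            raise NoAxisError("no chains in skeleton: no axis found")
        longest = max(graph_all.edges, key=len)
        if len(longest) < axis_min_px:
            raise NoAxisError(
                f"longest chain has {len(longest)} px < axis_min_px={axis_min_px}"
            )
        axis_pixels = set(longest.path)
        region = np.zeros_like(skel_img)
        for p in axis_pixels:
            region[p] = True
        median_width = 1.0

    # boundary: axis-region pixels with an 8-neighbour outside the region
    eroded = ndimage.binary_erosion(region, structure=_STRUCT8, border_value=0)
    boundary_img = region & ~eroded
    axis_boundary = [tuple(p) for p in np.argwhere(boundary_img)]

    hair_img = skel_img.copy()
    for p in axis_pixels:
        hair_img[p] = False
    hair_graph = _pixelgraph.decompose(hair_img)

    return SkeletonGraph(
        skeleton=skeleton,
        mask=mask,
        axis_pixels=axis_pixels,
        axis_boundary=axis_boundary,
        axis_region=region,
        hair_graph=hair_graph,
        mm_per_pixel=mask.mm_per_pixel if mask is not None else 1.0,
        median_axis_width_px=median_width,
    )


def attach_hairs(graph: SkeletonGraph, max_gap_px: int = 10) -> SkeletonGraph:
    """Attach hair components to the axis boundary.

    For every connected hair component, the free endpoint nearest the axis
    region is its attachment end, provided it lies within ``max_gap_px``;
    the hair is attached to the nearest axis boundary coordinate (ties
    resolved by raster order).  Components with no endpoint in range are
    dropped and counted.  Each attachment will seed one traced root hair,
    so a component touching the axis at both ends yields two.
    """
    if not graph.axis_boundary:
        raise NoAxisError("axis has no boundary coordinates")
    boundary = np.asarray(graph.axis_boundary, dtype=float)
    btree = cKDTree(boundary)

    hg = graph.hair_graph
    comp_of_junction: dict[int, int] = {}
    # connected components of the hair graph via union of edge incidences
    parent = list(range(len(hg.junctions)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for e in hg.edges:
        a, b = find(e.j1), find(e.j2)
        if a != b:
            parent[a] = b
    for j in range(len(hg.junctions)):
        comp_of_junction[j] = find(j)

    attachments: list[dict] = []
    dropped = 0
    comps: dict[int, list[int]] = {}
    for j in range(len(hg.junctions)):
        comps.setdefault(comp_of_junction[j], []).append(j)

    for comp_id, junctions in sorted(comps.items()):
        # free endpoints: degree-1 single-pixel clusters
        endpoint_hits = []
        for j in junctions:
            if hg.junction_degree(j) != 1:
                continue
            p = hg.junctions[j][0]
            dist, idx = btree.query([float(p[0]), float(p[1])], k=1)
            endpoint_hits.append((float(dist), p, tuple(int(v) for v in boundary[idx])))
        endpoint_hits.sort()
        in_range = [h for h in endpoint_hits if h[0] <= max_gap_px]
        if not in_range:
            if junctions and any(len(hg.incidence.get(j, [])) > 0 for j in junctions):
                dropped += 1
            continue
        for dist, p, battach in in_range:
            attachments.append(
                {"start": p, "attachment": battach, "gap_px": dist, "component": comp_id}
            )

    attachments.sort(key=lambda a: a["start"])
    if dropped:
        logger.info("attach_hairs: dropped %d hair component(s) beyond gap", dropped)
    graph.attachments = attachments
    graph.dropped_hairs = dropped
    return graph


def _bridge_pixels(
    attachment: tuple[int, int], start: tuple[int, int]
) -> list[tuple[int, int]]:
    """Straight pixel run from just outside the axis boundary to the hair start."""
    from skimage.draw import line as _draw_line

    rr, cc = _draw_line(attachment[0], attachment[1], start[0], start[1])
    return [(int(r), int(c)) for r, c in zip(rr, cc)][1:-1]


def _trace(
    graph: SkeletonGraph,
    start: tuple[int, int],
    thresholds: tuple[float, float] | None,
    total_estimate: float | None,
    tangent_window: int = 5,
    max_steps: int = 10000,
) -> list[tuple[int, int]]:
    """Trace one hair from its start endpoint through the hair pixel graph.

    ``thresholds`` is (mid, end) in degrees, or None for the provisional
    pass, which uses the lax end-zone threshold everywhere to estimate the
    hair's total arclength.  ``total_estimate`` is that estimate during the
    final pass.
    """
    hg = graph.hair_graph
    j = hg.junction_of(start)
    if j is None:
        return [start]
    eids = hg.incidence.get(j, [])
    if not eids:
        return [start]
    path = list(hg.edges[eids[0]].oriented_from(j, at=start))
    if path[0] != start:
        path = path[::-1]
    visited = {eids[0]}
    cur_j = hg.edges[eids[0]].other(j) if hg.edges[eids[0]].j1 != hg.edges[eids[0]].j2 else j

    for _ in range(max_steps):
        candidates = []
        v_in = np.asarray(path[-1], float) - np.asarray(
            path[max(0, len(path) - 1 - tangent_window)], float
        )
        for eid in hg.incidence.get(cur_j, []):
            if eid in visited:
                continue
            edge = hg.edges[eid]
            for orient_from in ({edge.j1, edge.j2} if edge.j1 != edge.j2 else {edge.j1}):
                if orient_from != cur_j:
                    continue
                cand_path = edge.oriented_from(cur_j)
                variants = [cand_path]
                if edge.j1 == edge.j2 and len(cand_path) > 2:
                    variants.append(cand_path[::-1])
                for var in variants:
                    v_out = chain_direction(var, tangent_window)
                    if not np.any(v_out):
                        continue
                    dtheta = angle_between_deg(v_in, v_out)
                    signed = signed_angle_deg(v_in, v_out)
                    candidates.append((dtheta, signed, eid, var))
        if not candidates:
            break
        candidates.sort(key=lambda c: (c[0], 0 if c[1] < 0 else 1))
        if (
            len(candidates) > 1
            and abs(candidates[0][0] - candidates[1][0]) < 1e-9
        ):
            logger.info("ambiguous junction at %s: equal angle change", path[-1])
        dtheta, _signed, eid, cand_path = candidates[0]

        if thresholds is not None:
            mid_thresh, end_thresh = thresholds
            frac = len(path) / total_estimate if total_estimate else 1.0
            allowed = mid_thresh if frac <= 0.5 else end_thresh
        else:
            allowed = 80.0  # provisional pass: lax end-zone rule everywhere
        if dtheta > allowed:
            break

        visited.add(eid)
        # append, skipping pixels already on the path (junction overlap);
        # a multi-pixel junction cluster may leave a small jump between the
        # current tail and the next chain — fill it with a straight run
        seen = set(path)
        new_pixels = [p for p in cand_path if p not in seen]
        if new_pixels:
            gap = max(
                abs(new_pixels[0][0] - path[-1][0]),
                abs(new_pixels[0][1] - path[-1][1]),
            )
            if gap > 1:
                from skimage.draw import line as _draw_line

                rr, cc = _draw_line(*path[-1], *new_pixels[0])
                for q in zip(rr[1:-1], cc[1:-1]):
                    q = (int(q[0]), int(q[1]))
                    if q not in seen:
                        path.append(q)
                        seen.add(q)
            path.extend(new_pixels)
        edge = hg.edges[eid]
        cur_j = edge.other(cur_j) if edge.j1 != edge.j2 else cur_j
        if hg.junction_degree(cur_j) <= 1 and not any(
            e not in visited for e in hg.incidence.get(cur_j, [])
        ):
            break
    return path


def separate_hairs(
    graph: SkeletonGraph,
    angle_thresh_mid_deg: float = 30.0,
    angle_thresh_end_deg: float = 80.0,
    min_hair_px: int = 12,
    tangent_window: int = 5,
) -> list[RootHair]:
    """Separate crossing/overlapping hairs into individual ordered paths.

    One hair is traced per axis attachment, in raster order of attachment
    start.  The search is two-pass: a provisional trace (lax threshold)
    estimates each hair's total arclength, then the final trace applies the
    positional rule — direction changes at a junction must be at most
    ``angle_thresh_mid_deg`` while within the first half of the hair and at
    most ``angle_thresh_end_deg`` in the tip half, where genuine curling
    concentrates.  Hairs shorter than ``min_hair_px`` are flagged too
    short for curl measurement.  Deterministic: ties at a junction prefer
    the clockwise turn in image coordinates.
    """
    hairs: list[RootHair] = []
    for hid, att in enumerate(graph.attachments):
        start = att["start"]
        provisional = _trace(graph, start, None, None, tangent_window)
        total = float(len(provisional))
        path = _trace(
            graph,
            start,
            (angle_thresh_mid_deg, angle_thresh_end_deg),
            total,
            tangent_window,
        )
        bridge = _bridge_pixels(att["attachment"], start)
        full = bridge + path
        hairs.append(
            RootHair(
                hair_id=hid,
                path=full,
                attachment=att["attachment"],
                mm_per_pixel=graph.mm_per_pixel,
                too_short=len(full) < min_hair_px,
            )
        )
    return hairs
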