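"""Thinning, spur pruning and gap bridging for segmentation masks.

Masks are reduced to one-pixel-wide centrelines with the classic Zhang–Suen
two-subiteration parallel thinning algorithm, short terminal branches left
by thinning are pruned, and small breaks in hairs are bridged by joining
nearby free endpoints whose local slopes agree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.draw import line as _draw_line

from . import _pixelgraph
from .mask_io import BinaryMask

__all__ = ["Skeleton", "thin", "prune_spurs", "bridge_gaps", "zhang_suen"]


@dataclass
class Skeleton:
    """A one-pixel-wide centreline image.

    ``image`` is a boolean array of the same shape as the source mask;
    ``pixels`` exposes the foreground as a set of (row, col) tuples.
    """

    image: np.ndarray
    source_shape: tuple[int, int]

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=bool)

    @property
    def pixels(self) -> set[tuple[int, int]]:
        return {tuple(p) for p in np.argwhere(self.image)}

    def count(self) -> int:
        return int(self.image.sum())


def _neighbour_stack(img: np.ndarray) -> np.ndarray:
    """P2..P9 (N, NE, E, SE, S, SW, W, NW) for every pixel, clockwise."""
    a = np.pad(img, 1)
    return np.stack(
        [
            a[:-2, 1:-1],  # P2 N
            a[:-2, 2:],    # P3 NE
            a[1:-1, 2:],   # P4 E
            a[2:, 2:],     # P5 SE
            a[2:, 1:-1],   # P6 S
            a[2:, :-2],    # P7 SW
            a[1:-1, :-2],  # P8 W
            a[:-2, :-2],   # P9 NW
        ],
        axis=-1,
    )


def zhang_suen(img: np.ndarray) -> np.ndarray:
    """Classic two-subiteration parallel Zhang–Suen thinning.

    Both subiterations are applied in parallel over the whole image (all
    deletions of a subiteration are decided on the same snapshot), repeated
    until a full pass deletes nothing.
    """
    img = np.asarray(img, dtype=bool).copy()
    while True:
        changed = False
        for sub in (0, 1):
            P = _neighbour_stack(img)
            B = P.sum(axis=-1)
            seq = np.concatenate([P, P[..., :1]], axis=-1)
            A = ((~seq[..., :-1]) & seq[..., 1:]).sum(axis=-1)
            if sub == 0:
                c1 = ~(P[..., 0] & P[..., 2] & P[..., 4])  # P2·P4·P6 = 0
                c2 = ~(P[..., 2] & P[..., 4] & P[..., 6])  # P4·P6·P8 = 0
            else:
                c1 = ~(P[..., 0] & P[..., 2] & P[..., 6])  # P2·P4·P8 = 0
                c2 = ~(P[..., 0] & P[..., 4] & P[..., 6])  # P2·P6·P8 = 0
            delete = img & (B >= 2) & (B <= 6) & (A == 1) & c1 & c2
            if delete.any():
                img[delete] = False
                changed = True
        if not changed:
            return img


def thin(mask: BinaryMask | np.ndarray) -> Skeleton:
    """Thin a binary mask to a single-pixel-wide skeleton.

    An empty mask yields an empty skeleton; connectivity of foreground
    components is preserved.
    """
    arr = mask.pixels if isinstance(mask, BinaryMask) else np.asarray(mask, dtype=bool)
    if not arr.any():
        return Skeleton(image=np.zeros_like(arr), source_shape=arr.shape)
    # thin only the foreground bounding box (padded); identical result,
    # much cheaper on sparse scenes
    rows = np.flatnonzero(arr.any(axis=1))
    cols = np.flatnonzero(arr.any(axis=0))
    r0, r1 = max(rows[0] - 1, 0), min(rows[-1] + 2, arr.shape[0])
    c0, c1 = max(cols[0] - 1, 0), min(cols[-1] + 2, arr.shape[1])
    out = np.zeros_like(arr)
    out[r0:r1, c0:c1] = zhang_suen(arr[r0:r1, c0:c1])
    return Skeleton(image=out, source_shape=arr.shape)


def prune_spurs(skeleton: Skeleton, min_branch_px: int = 5) -> Skeleton:
    """Remove terminal branches shorter than ``min_branch_px``.

    Only branches running from a free endpoint to a junction are candidates;
    junction-to-junction chains and whole junction-free paths are never
    removed.  Branch length counts the branch's own pixels, excluding the
    junction it hangs from; a branch of exactly ``min_branch_px`` pixels is
    retained (strict ``<``).  A single pruning pass is applied.
    """
    if min_branch_px < 1:
        raise ValueError("min_branch_px must be >= 1")
    img = skeleton.image.copy()
    deg = _pixelgraph.neighbor_count(img)
    endpoints = [tuple(p) for p in np.argwhere(img & (deg == 1))]

    offsets = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]

    def fg_neighbours(p, exclude):
        out = []
        for dr, dc in offsets:
            q = (p[0] + dr, p[1] + dc)
            if q in exclude:
                continue
            if 0 <= q[0] < img.shape[0] and 0 <= q[1] < img.shape[1] and img[q]:
                out.append(q)
        return out

    def one_clump(pixels):
        # are the pixels mutually 8-connected without outside help?
        if len(pixels) <= 1:
            return True
        todo, seen = [pixels[0]], {pixels[0]}
        pixset = set(pixels)
        while todo:
            p = todo.pop()
            for q in pixset - seen:
                if max(abs(q[0] - p[0]), abs(q[1] - p[1])) <= 1:
                    seen.add(q)
                    todo.append(q)
        return seen == pixset

    to_delete: set[tuple[int, int]] = set()
    for end in endpoints:
        visited = [end]
        vset = {end}
        is_spur = False
        while len(visited) <= min_branch_px:
            nbrs = fg_neighbours(visited[-1], vset)
            if not nbrs:
                break  # reached the far end: a whole path, not a spur
            if len(nbrs) == 1:
                visited.append(nbrs[0])
                vset.add(nbrs[0])
                continue
            # branching: the current tail pixel sits at a junction.  If its
            # remaining neighbours stay connected without it, the tail pixel
            # belongs to the spur too; otherwise it is a main-line pixel.
            if not one_clump(nbrs):
                visited.pop()
            is_spur = True
            break
        if is_spur and len(visited) < min_branch_px:
            to_delete.update(visited)
    for p in to_delete:
        img[p] = False
    return Skeleton(image=img, source_shape=skeleton.source_shape)


def _endpoint_tangent(
    graph: "_pixelgraph.PixelGraph", endpoint: tuple[int, int], window: int = 5
) -> np.ndarray | None:
    """Outward direction at a free endpoint (from ``window`` px inward)."""
    j = graph.junction_of(endpoint)
    if j is None:
        return None
    eids = graph.incidence.get(j, [])
    if len(eids) != 1:
        return None
    path = graph.edges[eids[0]].oriented_from(j, at=endpoint)
    inward = _pixelgraph.chain_direction(path, window)
    return -inward if np.any(inward) else None


def bridge_gaps(
    skeleton: Skeleton, max_gap_px: int = 10, max_slope_diff_deg: float = 20.0
) -> Skeleton:
    """Join free skeleton endpoints across small gaps.

    Endpoint pairs in *different* connected components, closer than
    ``max_gap_px`` (Euclidean), whose local tangent lines (direction of the
    5 pixels adjacent to each endpoint, compared modulo 180°) differ by at
    most ``max_slope_diff_deg``, are joined by a straight pixel segment.
    Pairs are taken nearest-first and each endpoint is bridged at most once.
    """
    if max_gap_px < 1:
        raise ValueError("max_gap_px must be >= 1")
    if not 0 <= max_slope_diff_deg <= 90:
        raise ValueError("max_slope_diff_deg must be in [0, 90]")
    img = skeleton.image.copy()
    graph = _pixelgraph.decompose(img)
    from scipy import ndimage

    comp_lab, _ = ndimage.label(img, structure=np.ones((3, 3), int))

    endpoints: list[tuple[int, int]] = []
    tangents: dict[tuple[int, int], np.ndarray] = {}
    for j, cluster in enumerate(graph.junctions):
        if graph.junction_degree(j) == 1 and len(cluster) == 1:
            t = _endpoint_tangent(graph, cluster[0])
            if t is not None:
                endpoints.append(cluster[0])
                tangents[cluster[0]] = t
    endpoints.sort()

    candidates = []
    for i, p in enumerate(endpoints):
        for q in endpoints[i + 1 :]:
            if comp_lab[p] == comp_lab[q]:
                continue
            dist = float(np.hypot(p[0] - q[0], p[1] - q[1]))
            if dist > max_gap_px:
                continue
            slope = _pixelgraph.angle_between_deg(tangents[p], tangents[q])
            slope = min(slope, 180.0 - slope)  # undirected line slope
            if slope > max_slope_diff_deg:
                continue
            candidates.append((dist, p, q))
    candidates.sort()

    used: set[tuple[int, int]] = set()
    for _dist, p, q in candidates:
        if p in used or q in used:
            continue
        used.add(p)
        used.add(q)
        rr, cc = _draw_line(p[0], p[1], q[0], q[1])
        img[rr, cc] = True
    return Skeleton(image=img, source_shape=skeleton.source_shape)
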