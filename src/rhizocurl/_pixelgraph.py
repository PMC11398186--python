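"""Pixel-level graph decomposition of 1-px-wide skeletons.

A thinned mask is decomposed into *junction clusters* (8-connected groups of
pixels whose degree differs from 2 — endpoints and branch points) and *edges*
(maximal chains of degree-2 pixels running between clusters).  This is the
substrate for spur pruning and for the path search that separates crossing
root hairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

# 8-neighbourhood offsets, raster order
_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]

_STRUCT8 = np.ones((3, 3), dtype=int)


def neighbor_count(img: np.ndarray) -> np.ndarray:
    """Number of foreground 8-neighbours of every pixel."""
    img = img.astype(bool)
    counts = ndimage.convolve(img.astype(np.uint8), _STRUCT8, mode="constant") - img
    return counts


@dataclass
class Edge:
    """A maximal degree-2 pixel chain, endpoints included.

    ``path`` runs from a pixel in junction cluster ``j1`` to one in ``j2``
    (which may be the same cluster for loops).  Interior pixels all have
    skeleton degree 2.
    """

    path: list[tuple[int, int]]
    j1: int
    j2: int

    def __len__(self) -> int:
        return len(self.path)

    def oriented_from(self, junction: int, at: tuple[int, int] | None = None) -> list[tuple[int, int]]:
        """Return the path ordered leaving the given junction cluster."""
        if self.j1 == self.j2:
            # loop: orient by the concrete end pixel if given
            if at is not None and self.path[-1] == at and self.path[0] != at:
                return self.path[::-1]
            return self.path
        if junction == self.j1:
            return self.path
        if junction == self.j2:
            return self.path[::-1]
        raise ValueError("edge is not incident to that junction")

    def other(self, junction: int) -> int:
        return self.j2 if junction == self.j1 else self.j1


@dataclass
class PixelGraph:
    shape: tuple[int, int]
    junctions: list[list[tuple[int, int]]]  # pixel clusters, raster-sorted
    edges: list[Edge]
    incidence: dict[int, list[int]] = field(default_factory=dict)  # junction -> edge ids

    def junction_of(self, pixel: tuple[int, int]) -> int | None:
        return self._pixel2junction.get(pixel)

    def __post_init__(self) -> None:
        self._pixel2junction = {
            p: j for j, cluster in enumerate(self.junctions) for p in cluster
        }

    def junction_degree(self, j: int) -> int:
        return len(self.incidence.get(j, []))


def _trace_chain(
    img: np.ndarray,
    node_mask: np.ndarray,
    start: tuple[int, int],
    first: tuple[int, int],
) -> list[tuple[int, int]]:
    """Walk from node pixel *start* through degree-2 pixel *first* until the
    next node pixel (or chain end) is reached."""
    path = [start, first]
    prev, cur = start, first
    while not node_mask[cur]:
        # interior chain pixels have degree exactly 2: the next pixel is the
        # unique foreground neighbour other than the one we came from
        nxt = None
        for dr, dc in _OFFSETS:
            q = (cur[0] + dr, cur[1] + dc)
            if q == prev:
                continue
            if 0 <= q[0] < img.shape[0] and 0 <= q[1] < img.shape[1] and img[q]:
                nxt = q
                break
        if nxt is None:
            break  # dead end (single-pixel stub)
        path.append(nxt)
        prev, cur = cur, nxt
    return path


def _chain_key(chain: list[tuple[int, int]]) -> tuple:
    """Orientation-independent identity of a chain (ends + inner ends)."""
    a, b = chain[0], chain[-1]
    if len(chain) >= 3:
        ia, ib = chain[1], chain[-2]
        return (min(a, b), max(a, b), min(ia, ib), max(ia, ib))
    return (min(a, b), max(a, b))


def decompose(img: np.ndarray) -> PixelGraph:
    """Decompose a skeleton image into junction clusters and edge chains."""
    img = np.asarray(img, dtype=bool)
    deg = neighbor_count(img)
    node_mask = img & (deg != 2)

    labeled, n_lab = ndimage.label(node_mask, structure=_STRUCT8)
    junctions: list[list[tuple[int, int]]] = []
    for lab in range(1, n_lab + 1):
        coords = [tuple(p) for p in np.argwhere(labeled == lab)]
        coords.sort()
        junctions.append(coords)

    edges: list[Edge] = []
    seen_interior = np.zeros_like(img)
    seen_pairs: set[tuple[tuple[int, int], tuple[int, int]]] = set()

    for j, cluster in enumerate(junctions):
        for p in cluster:
            for dr, dc in _OFFSETS:
                q = (p[0] + dr, p[1] + dc)
                if not (0 <= q[0] < img.shape[0] and 0 <= q[1] < img.shape[1]):
                    continue
                if not img[q]:
                    continue
                if node_mask[q]:
                    # node adjacent to node: direct edge (distinct clusters only)
                    jq = labeled[q] - 1
                    if jq == j:
                        continue
                    key = _chain_key([p, q])
                    if key in seen_pairs:
                        continue
                    seen_pairs.add(key)
                    edges.append(Edge(path=[p, q], j1=j, j2=jq))
                    continue
                if seen_interior[q]:
                    continue
                chain = _trace_chain(img, node_mask, p, q)
                for pix in chain[1:]:
                    if not node_mask[pix]:
                        seen_interior[pix] = True
                end = chain[-1]
                j2 = labeled[end] - 1 if node_mask[end] else j
                key = _chain_key(chain)
                if key in seen_pairs:
                    continue
                seen_pairs.add(key)
                edges.append(Edge(path=chain, j1=j, j2=j2))

    # pure cycles: degree-2 pixels never reached from any node
    remaining = img & (deg == 2) & ~seen_interior & ~node_mask
    lab_cyc, n_cyc = ndimage.label(remaining, structure=_STRUCT8)
    for lab in range(1, n_cyc + 1):
        coords = [tuple(p) for p in np.argwhere(lab_cyc == lab)]
        coords.sort()
        start = coords[0]
        jid = len(junctions)
        junctions.append([start])
        nbrs = [
            (start[0] + dr, start[1] + dc)
            for dr, dc in _OFFSETS
            if (start[0] + dr, start[1] + dc) in set(coords)
        ]
        if not nbrs:
            edges.append(Edge(path=[start], j1=jid, j2=jid))
            continue
        node_like = np.zeros_like(img)
        node_like[start] = True
        chain = _trace_chain(img, node_like, start, nbrs[0])
        edges.append(Edge(path=chain, j1=jid, j2=jid))

    incidence: dict[int, list[int]] = {j: [] for j in range(len(junctions))}
    for eid, e in enumerate(edges):
        incidence[e.j1].append(eid)
        if e.j2 != e.j1:
            incidence[e.j2].append(eid)
        elif len(e.path) > 1:
            incidence[e.j1].append(eid)  # loop contributes both ends
    return PixelGraph(shape=img.shape, junctions=junctions, edges=edges, incidence=incidence)


def chain_direction(path: list[tuple[int, int]], window: int = 5) -> np.ndarray:
    """Unit direction of the first ``window`` steps of a pixel chain."""
    k = min(window, len(path) - 1)
    if k < 1:
        return np.zeros(2)
    v = np.asarray(path[k], dtype=float) - np.asarray(path[0], dtype=float)
    n = np.linalg.norm(v)
    return v / n if n else v


def angle_between_deg(v1: np.ndarray, v2: np.ndarray) -> float:
    """Unsigned angle between two direction vectors, in degrees [0, 180]."""
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        return 0.0
    c = float(np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0))
    return float(np.degrees(np.arccos(c)))


def signed_angle_deg(v1: np.ndarray, v2: np.ndarray) -> float:
    """Signed turn from v1 to v2 in (row, col) image coordinates, degrees."""
    cross = v1[0] * v2[1] - v1[1] * v2[0]
    dot = v1[0] * v2[0] + v1[1] * v2[1]
    return float(np.degrees(np.arctan2(cross, dot)))
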