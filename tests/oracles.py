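"""Independent reference implementations used as test oracles.

Deliberately naive (per-pixel loops, closed forms) and structurally
unrelated to the package's vectorized implementations.
"""

from __future__ import annotations

import numpy as np


def zhang_suen_reference(img: np.ndarray) -> np.ndarray:
    """Classic two-subiteration Zhang–Suen thinning, pixel-by-pixel."""
    img = img.astype(bool).copy()
    rows, cols = img.shape

    def neighbours(r: int, c: int) -> list[int]:
        # P2..P9 clockwise from north
        offs = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]
        out = []
        for dr, dc in offs:
            rr, cc = r + dr, c + dc
            out.append(int(img[rr, cc]) if 0 <= rr < rows and 0 <= cc < cols else 0)
        return out

    while True:
        changed = False
        for sub in (0, 1):
            to_delete = []
            for r in range(rows):
                for c in range(cols):
                    if not img[r, c]:
                        continue
                    P = neighbours(r, c)
                    B = sum(P)
                    if not 2 <= B <= 6:
                        continue
                    ring = P + [P[0]]
                    A = sum(1 for i in range(8) if ring[i] == 0 and ring[i + 1] == 1)
                    if A != 1:
                        continue
                    P2, P4, P6, P8 = P[0], P[2], P[4], P[6]
                    if sub == 0:
                        if P2 * P4 * P6 != 0 or P4 * P6 * P8 != 0:
                            continue
                    else:
                        if P2 * P4 * P8 != 0 or P2 * P6 * P8 != 0:
                            continue
                    to_delete.append((r, c))
            for r, c in to_delete:
                img[r, c] = False
            if to_delete:
                changed = True
        if not changed:
            return img


def ols_reference(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope, intercept and R² by the normal equations."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    X = np.column_stack([x, np.ones_like(x)])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    slope, intercept = float(beta[0]), float(beta[1])
    resid = y - (slope * x + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return slope, intercept, r2


def random_blob_mask(rng: np.random.Generator, shape: tuple[int, int] = (30, 30)) -> np.ndarray:
    """A random mask of overlapping discs and bars for thinning tests."""
    img = np.zeros(shape, bool)
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    for _ in range(rng.integers(2, 5)):
        r, c = rng.integers(4, shape[0] - 4), rng.integers(4, shape[1] - 4)
        rad = rng.integers(2, 7)
        img |= (yy - r) ** 2 + (xx - c) ** 2 <= rad**2
    if rng.random() < 0.5:
        r = rng.integers(4, shape[0] - 6)
        img[r : r + rng.integers(2, 5), 3 : shape[1] - 3] = True
    return img
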