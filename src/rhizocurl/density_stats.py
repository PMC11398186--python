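"""Dose–response regression of nodulation traits on rhizobia density.

Inoculant doses span four orders of magnitude (10⁵–10⁹ viable cells per
Leonard jar across groups A–D), so responses are regressed on the log10
midpoint of each dose interval.  Ordinary least squares with R² is the
whole contract; the uninoculated control group carries no dose and is
excluded from fits by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

__all__ = ["DoseResponseFit", "DensityCode", "encode_density", "fit_linear", "predict_nodule_number"]

#: log10 midpoints of the dose intervals (viable cells per Leonard jar):
#: A 10^5–10^6, B 10^6–10^7, C 10^7–10^8, D 10^8–10^9
_LOG10_MIDPOINTS = {"A": 5.5, "B": 6.5, "C": 7.5, "D": 8.5}
_RANKS = {"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0}


@dataclass(frozen=True)
class DensityCode:
    """Numeric encoding of a dose group; control is flagged unexposed."""

    group: str
    log10_cells: float
    unexposed: bool = False


@dataclass
class DoseResponseFit:
    """An ordinary least-squares dose–response line."""

    response_name: str
    slope: float
    intercept: float
    r_squared: float
    n_points: int


def encode_density(
    dose_group: str, scheme: Literal["log10_midpoint", "rank"] = "log10_midpoint"
) -> DensityCode:
    """Encode a dose-group label as a regression covariate.

    ``log10_midpoint`` (default) maps A→5.5 … D→8.5; ``rank`` maps A→1 …
    D→4.  ``control`` encodes as 0 with the unexposed flag set.
    """
    label = dose_group.strip()
    if label.lower() == "control":
        return DensityCode(group="control", log10_cells=0.0, unexposed=True)
    table = _LOG10_MIDPOINTS if scheme == "log10_midpoint" else _RANKS
    if label not in table:
        raise ValueError(f"unknown dose group {dose_group!r}; expected control/A/B/C/D")
    return DensityCode(group=label, log10_cells=table[label])


def fit_linear(
    x: Sequence[float], y: Sequence[float], response_name: str = "response"
) -> DoseResponseFit:
    """Ordinary least-squares fit of a response on log10 rhizobia density.

    R² = 1 − SS_res/SS_tot, which for a simple regression equals the
    squared Pearson correlation.  A constant response fits slope 0 with R²
    defined as 0; a constant covariate is an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D sequences of equal length")
    if len(x) < 3:
        raise ValueError(f"need at least 3 points, got {len(x)}")
    if np.ptp(x) == 0:
        raise ValueError("x is constant: dose–response slope undefined")
    if np.ptp(y) == 0:
        return DoseResponseFit(response_name, 0.0, float(y[0]), 0.0, len(x))
    res = stats.linregress(x, y)
    return DoseResponseFit(
        response_name=response_name,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_points=len(x),
    )


def predict_nodule_number(fit: DoseResponseFit, density_log10: float) -> float:
    """Predicted response at a given log10 density, floored at zero
    (counts cannot be negative)."""
    return max(0.0, fit.intercept + fit.slope * density_log10)
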