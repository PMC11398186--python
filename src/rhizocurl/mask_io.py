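"""Calibrated binary masks and tabular measurement I/O.

All downstream stages consume :class:`BinaryMask`: a 2-D boolean grid in
0-based ``(row, col)`` coordinates with origin at the top-left, plus the
physical calibration (mm per pixel) of the imaging window.  Masks are the
output of an upstream segmentation step; any nonzero pixel is foreground.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = [
    "BinaryMask",
    "Calibration",
    "read_mask",
    "write_mask",
    "write_measurements",
    "read_config",
    "write_config",
]


@dataclass(frozen=True)
class Calibration:
    """Physical calibration of a microrhizotron image.

    Parameters
    ----------
    mm_per_pixel
        Size of one pixel in millimetres.  Never stated by the imaging
        hardware itself; must be supplied by the user.
    visible_depth_L
        Depth into the soil the imaging window perceives, in mm.  Default
        1.0 mm; minirhizotron literature quotes 1–3 mm, and this value caps
        the visible chord of a buried nodule.
    """

    mm_per_pixel: float
    visible_depth_L: float = 1.0

    def __post_init__(self) -> None:
        if not self.mm_per_pixel > 0:
            raise ValueError(f"mm_per_pixel must be > 0, got {self.mm_per_pixel}")
        if not self.visible_depth_L > 0:
            raise ValueError(
                f"visible_depth_L must be > 0, got {self.visible_depth_L}"
            )


@dataclass
class BinaryMask:
    """A calibrated 2-D boolean image, the universal pipeline input."""

    pixels: np.ndarray
    mm_per_pixel: float
    label: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels, dtype=bool)
        if arr.ndim != 2 or arr.size == 0:
            raise ValueError("pixels must be a non-empty 2-D array")
        if not self.mm_per_pixel > 0:
            raise ValueError(f"mm_per_pixel must be > 0, got {self.mm_per_pixel}")
        self.pixels = arr

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def foreground_count(self) -> int:
        return int(self.pixels.sum())


def read_mask(path: str | Path, calibration: Calibration, label: str = "") -> BinaryMask:
    """Read a PNG/TIFF segmentation mask as a calibrated binary image.

    Any nonzero pixel is foreground; RGB images are collapsed channel-wise
    (a pixel is foreground if any colour channel is nonzero), which matches
    the grayscale binarization of a white-on-black mask.  An alpha channel,
    if present, is ignored.
    """
    path = Path(path)
    try:
        img = iio.imread(path)
    except (OSError, ValueError) as exc:
        raise OSError(f"could not read mask image {path}: {exc}") from exc
    arr = np.asarray(img)
    if arr.ndim == 3:
        arr = arr[..., :3].max(axis=-1)
    elif arr.ndim != 2:
        raise OSError(f"{path}: expected a 2-D or RGB image, got shape {arr.shape}")
    mask = BinaryMask(arr > 0, calibration.mm_per_pixel, label=label or path.stem)
    if mask.foreground_count() == 0:
        warnings.warn(f"{path}: mask contains no foreground pixels", stacklevel=2)
    return mask


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    """Write a binary mask as an 8-bit PNG/TIFF (foreground = 255)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, (mask.pixels.astype(np.uint8) * 255))


def _as_record(rec: Any) -> Mapping[str, Any]:
    if dataclasses.is_dataclass(rec) and not isinstance(rec, type):
        return dataclasses.asdict(rec)
    if isinstance(rec, Mapping):
        return rec
    raise TypeError(f"cannot serialise record of type {type(rec).__name__}")


def write_measurements(
    records: Iterable[Any],
    path: str | Path,
    fieldnames: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Write measurement rows (dataclasses or mappings) to a CSV with header.

    Coordinate-tuple fields are serialised as ``"row,col"`` strings so the
    file round-trips through ordinary CSV readers.  Returns the DataFrame
    that was written.  An empty record list with ``fieldnames`` yields a
    header-only file.
    """
    rows = [dict(_as_record(r)) for r in records]
    for row in rows:
        for key, val in row.items():
            if isinstance(val, tuple):
                row[key] = ",".join(str(v) for v in val)
    if rows:
        df = pd.DataFrame(rows, columns=fieldnames or list(rows[0]))
    else:
        df = pd.DataFrame(columns=list(fieldnames or []))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    try:
        df.to_csv(path, index=False)
    except OSError as exc:
        raise OSError(f"could not write measurements to {path}: {exc}") from exc
    return df


def read_config(path: str | Path) -> dict[str, Any]:
    """Read a JSON run configuration ({mm_per_pixel, visible_depth_L, ...})."""
    with open(path) as fh:
        return json.load(fh)


def write_config(config: Mapping[str, Any], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(dict(config), fh, indent=2, sort_keys=True)
        fh.write("\n")
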