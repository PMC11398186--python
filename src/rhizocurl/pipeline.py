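"""End-to-end pipeline: mask → skeleton → hairs → curl/nodule tables.

All stage thresholds live in :class:`RunConfig` with the method's default
values (30°/80° junction rules, 90° curl threshold, L = 1 mm); nothing is
hard-coded, because each of them is an operational choice of the method,
not a law.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

from . import __version__
from .curl_metrics import HairTooShortError, curl_angle
from .hair_separation import attach_hairs, build_graph, separate_hairs
from .mask_io import BinaryMask, Calibration, read_mask, write_measurements
from .nodule_metrics import apply_conversion_policy, detect_nodules, observed_diameter
from .skeletonize import bridge_gaps, prune_spurs, thin

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "process_mask"]


@dataclass
class RunConfig:
    """Complete configuration of a pipeline run."""

    calibration: Calibration = field(default_factory=lambda: Calibration(0.01, 1.0))
    min_branch_px: int = 5
    max_gap_px: int = 10
    max_slope_diff_deg: float = 20.0
    curl_threshold_deg: float = 90.0
    angle_thresh_mid_deg: float = 30.0
    angle_thresh_end_deg: float = 80.0
    swell_factor: float = 2.0
    axis_min_width_px: float = 5.0
    seed: int = 0
    output_dir: Path = Path("rhizocurl_out")

    def __post_init__(self) -> None:
        self.output_dir = Path(self.output_dir)
        for name in (
            "min_branch_px",
            "max_gap_px",
            "max_slope_diff_deg",
            "curl_threshold_deg",
            "angle_thresh_mid_deg",
            "angle_thresh_end_deg",
            "swell_factor",
            "axis_min_width_px",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("angle_thresh_mid_deg", "angle_thresh_end_deg"):
            if getattr(self, name) > 180:
                raise ValueError(f"{name} must be <= 180 degrees")

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["output_dir"] = str(self.output_dir)
        return d

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        calib = raw.pop("calibration", {})
        if isinstance(calib, dict):
            calib = Calibration(
                mm_per_pixel=calib.get("mm_per_pixel", 0.01),
                visible_depth_L=calib.get("visible_depth_L", 1.0),
            )
        return cls(calibration=calib, **raw)


def process_mask(mask: BinaryMask, config: RunConfig, day: int = 0) -> dict[str, Any]:
    """Run every stage on one mask; returns row lists for hairs, curls
    and nodules."""
    skel = thin(mask)
    skel = prune_spurs(skel, config.min_branch_px)
    skel = bridge_gaps(skel, config.max_gap_px, config.max_slope_diff_deg)
    graph = build_graph(skel, mask, axis_min_width_px=config.axis_min_width_px)
    graph = attach_hairs(graph, config.max_gap_px)
    hairs = separate_hairs(
        graph,
        angle_thresh_mid_deg=config.angle_thresh_mid_deg,
        angle_thresh_end_deg=config.angle_thresh_end_deg,
    )

    hair_rows, curl_rows = [], []
    for hair in hairs:
        hair_rows.append(
            {
                "hair_id": hair.hair_id,
                "attachment_row": hair.attachment[0],
                "attachment_col": hair.attachment[1],
                "length_px": hair.length_px,
                "length_mm": hair.length_mm,
                "too_short": hair.too_short,
            }
        )
        if hair.too_short:
            continue
        try:
            m = curl_angle(hair, curl_threshold_deg=config.curl_threshold_deg)
        except HairTooShortError:
            continue
        curl_rows.append(
            {
                "hair_id": m.hair_id,
                "beta_deg": m.beta_deg,
                "beta_arccos_deg": m.beta_arccos_deg,
                "curled": m.curled,
                "dL_px": m.dL_px,
                "P_i": m.P_i,
                "P_j": m.P_j,
                "P_k": m.P_k,
                "P_l": m.P_l,
            }
        )

    nodule_rows = []
    regions = detect_nodules(mask, graph, swell_factor=config.swell_factor)
    for nid, region in enumerate(regions):
        d_mm = observed_diameter(mask, region)
        meas = apply_conversion_policy(d_mm, config.calibration, nodule_id=nid, day=day)
        nodule_rows.append(
            {
                "nodule_id": nid,
                "day": day,
                "observed_d_mm": round(meas.observed_d_mm, 2),
                "L_mm": meas.visible_depth_L_mm,
                "real_D_mm": round(meas.real_D_mm, 2),
                "converted": meas.converted,
            }
        )
    return {"hairs": hair_rows, "curls": curl_rows, "nodules": nodule_rows}


def run_pipeline(config: RunConfig, mask_paths: list[str | Path]) -> dict[str, Any]:
    """Process masks and write per-mask CSVs plus a JSON run manifest.

    A failing mask keeps its partial outputs under a ``.partial`` suffix
    and is recorded in the manifest; the manifest's ``ok`` flag is False
    if any stage failed.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "tool": "rhizocurl",
        "version": __version__,
        "config": config.to_dict(),
        "inputs": [str(p) for p in mask_paths],
        "results": [],
        "ok": True,
    }
    schemas = {
        "hairs": [
            "hair_id", "attachment_row", "attachment_col",
            "length_px", "length_mm", "too_short",
        ],
        "curls": [
            "hair_id", "beta_deg", "beta_arccos_deg", "curled",
            "dL_px", "P_i", "P_j", "P_k", "P_l",
        ],
        "nodules": [
            "nodule_id", "day", "observed_d_mm", "L_mm", "real_D_mm", "converted",
        ],
    }
    for path in mask_paths:
        path = Path(path)
        stem = path.stem
        written: list[Path] = []
        try:
            mask = read_mask(path, config.calibration)
            tables = process_mask(mask, config)
            entry = {"input": str(path), "ok": True}
            for kind in ("hairs", "curls", "nodules"):
                out = outdir / f"{stem}_{kind}.csv"
                write_measurements(tables[kind], out, fieldnames=schemas[kind])
                written.append(out)
                entry[f"n_{kind}"] = len(tables[kind])
            manifest["results"].append(entry)
        except Exception as exc:  # noqa: BLE001 - per-mask isolation is the point
            logger.error("mask %s failed: %s", path, exc)
            for out in written:
                out.rename(out.with_suffix(out.suffix + ".partial"))
            manifest["results"].append({"input": str(path), "ok": False, "error": str(exc)})
            manifest["ok"] = False
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
        fh.write("\n")
    return manifest
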