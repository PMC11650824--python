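"""End-to-end orchestration: stitch -> segment -> extract -> bin/quarter -> compare.

A run is driven by a YAML config (see :class:`PipelineConfig`) and writes a
run directory containing, for every tube x date: the stitched composite, the
predicted mask, per-component, depth-profile and quarter CSVs; plus the
per-stratum regression CSV when a core table is configured, and a run log
with timings and fallback counts.  Identical config + seed give
byte-identical CSV outputs.
"""

from __future__ import annotations

import datetime as _dt
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from . import compare as _compare
from . import features as _features
from . import geometry as _geometry
from . import io as _io
from . import segnet as _segnet
from . import stitch as _stitch

logger = logging.getLogger("rhizopipe")


@dataclass
class PipelineConfig:
    """Validated configuration of one pipeline run."""

    input_dir: str
    output_dir: str
    model_checkpoint: str
    core_table: str | None = None
    filename_template: str = _io.DEFAULT_FILENAME_TEMPLATE
    dpi: float = _io.DEFAULT_DPI
    seed: int = 0
    mode: str = "paper"
    # stitcher block
    n_keypoints: int = 500
    ransac_threshold_px: float = 2.0
    ransac_max_trials: int = 1000
    nominal_overlap_cm: float = 1.0
    keep_fraction: float = 0.5
    # segmentation block
    patch_size: int = 256
    patch_overlap: float = 0.3
    threshold: float = 0.5
    min_area_px: int = _features.DEFAULT_MIN_AREA_PX
    # geometry block
    surface_angle_deg: float = 30.0
    soil_entry_col: int | None = None
    quarter_offset: int = 0
    # plot mapping: tube_id -> plot_id (defaults to tube_id itself)
    plots: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise _io.RhizopipeError(f"unknown config fields: {sorted(unknown)}")
        missing = [f for f in ("input_dir", "output_dir", "model_checkpoint") if f not in raw]
        if missing:
            raise _io.RhizopipeError(f"missing required config fields: {missing}")
        return cls(**raw)

    def validate(self) -> None:
        if not Path(self.input_dir).is_dir():
            raise _io.RhizopipeError(f"input_dir does not exist: {self.input_dir}")
        if not Path(self.model_checkpoint).is_file():
            raise _io.RhizopipeError(
                f"model_checkpoint does not exist: {self.model_checkpoint}"
            )
        if self.core_table is not None and not Path(self.core_table).is_file():
            raise _io.RhizopipeError(f"core_table does not exist: {self.core_table}")
        if self.mode not in ("paper", "physical"):
            raise _io.RhizopipeError(f"mode must be 'paper' or 'physical', got {self.mode!r}")


def _setup_run_logging(run_dir: Path) -> logging.Handler:
    handler = logging.FileHandler(run_dir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    return handler


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full pipeline; returns the run directory."""
    config.validate()
    run_dir = Path(config.output_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    handler = _setup_run_logging(run_dir)
    t0 = time.time()
    try:
        return _run(config, run_dir)
    finally:
        logger.info("pipeline finished in %.1f s", time.time() - t0)
        logger.removeHandler(handler)
        handler.close()


def _run(config: PipelineConfig, run_dir: Path) -> Path:
    scans = _io.load_scan_series(
        config.input_dir, config.filename_template, dpi=config.dpi
    )
    if not scans:
        raise _io.RhizopipeError(f"no scans found in {config.input_dir}")
    logger.info("loaded %d scans", len(scans))
    model = _segnet.SegmentationModel.load(config.model_checkpoint)
    stitch_cfg = _stitch.StitchConfig(
        n_keypoints=config.n_keypoints,
        ransac_threshold_px=config.ransac_threshold_px,
        ransac_max_trials=config.ransac_max_trials,
        seed=config.seed,
        nominal_overlap_cm=config.nominal_overlap_cm,
        keep_fraction=config.keep_fraction,
    )
    geom = _geometry.TubeGeometry(
        surface_angle_deg=config.surface_angle_deg,
        dpi=config.dpi,
        soil_entry_col=config.soil_entry_col,
        quarter_offset=config.quarter_offset,
    )

    groups: dict[tuple[str, _dt.date], list[_io.ScanImage]] = {}
    for s in groups_key_sorted(scans):
        groups.setdefault((s.tube_id, s.scan_date), []).append(s)

    profiles: list[_geometry.DepthProfile] = []
    quarters: list[_geometry.QuarterSummary] = []
    comp_rows: list[dict] = []
    n_scans_used = 0
    n_fallbacks = 0
    for (tube_id, scan_date), series in sorted(groups.items()):
        plot_id = config.plots.get(tube_id, tube_id)
        stage = "stitch"
        try:
            composite = _stitch.stitch_series(series, stitch_cfg)
            n_fallbacks += composite.n_fallbacks
            n_scans_used += len(series)
            iio.imwrite(
                run_dir / f"{tube_id}_{scan_date}_composite.png", composite.pixels
            )
            stage = "segment"
            mask = _segnet.predict_mask(
                model,
                composite.pixels,
                size=config.patch_size,
                overlap=config.patch_overlap,
                threshold=config.threshold,
            )
            _io.write_mask(mask, run_dir / f"{tube_id}_{scan_date}_mask.png")
            stage = "extract"
            components = _features.extract_root_components(
                mask, config.dpi, config.min_area_px
            )
            stage = "geometry"
            profile = _geometry.assign_depth_bins(
                components, geom, config.mode, tube_id, scan_date, plot_id
            )
            quarter = _geometry.assign_quarters(
                components, geom, mask.shape[0], tube_id, scan_date, plot_id
            )
        except _io.RhizopipeError as exc:
            raise _io.RhizopipeError(
                f"stage {stage!r} failed for tube {tube_id} on {scan_date}: {exc}"
            ) from exc
        profiles.append(profile)
        quarters.append(quarter)
        for c in components:
            comp_rows.append(
                {
                    "tube_id": tube_id,
                    "plot_id": plot_id,
                    "scan_date": str(scan_date),
                    "label": c.label,
                    "length_cm": c.length_cm,
                    "centroid_col": c.centroid_col,
                    "quarter": c.quarter,
                }
            )
        logger.info(
            "tube %s %s: %d scans, %d components, total length %.3f cm",
            tube_id,
            scan_date,
            len(series),
            len(components),
            sum(c.length_cm for c in components),
        )

    _io.write_results_table(profiles, run_dir / "depth_profiles.csv")
    _io.write_results_table(quarters, run_dir / "quarter_summaries.csv")
    pd.DataFrame(
        comp_rows,
        columns=[
            "tube_id", "plot_id", "scan_date", "label",
            "length_cm", "centroid_col", "quarter",
        ],
    ).to_csv(run_dir / "components.csv", index=False, float_format="%.6f")
    _compare.quarter_long_table(quarters).to_csv(
        run_dir / "quarter_long.csv", index=False, float_format="%.6f"
    )

    if config.core_table is not None:
        cores = _io.read_core_table(config.core_table)
        results = _compare.compare_methods(profiles, cores)
        _compare.regression_table(results).to_csv(
            run_dir / "regressions.csv", index=False, float_format="%.6f"
        )

    logger.info(
        "run summary: %d/%d scans stitched, %d stitch fallbacks",
        n_scans_used,
        len(scans),
        n_fallbacks,
    )
    return run_dir


def groups_key_sorted(scans: list[_io.ScanImage]) -> list[_io.ScanImage]:
    return sorted(scans, key=lambda s: (s.tube_id, s.scan_date, s.position_index))
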