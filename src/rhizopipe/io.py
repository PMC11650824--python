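"""Reading and writing scan series, masks, and tabular results.

Minirhizotron scanners (e.g. the CI-600) export one unwrapped 360-degree
RGB raster per fixed position along the tube.  No vendor naming scheme is
assumed; files are matched against a configurable template whose default is
``{tube}_{date}_p{index}`` (e.g. ``T01_2022-05-23_p3.png``).

Orientation convention: image *left* = top of tube, image *right* = bottom
of tube, i.e. the along-tube axis runs left to right and the circumferential
axis top to bottom.  Loaders normalise every raster to 8-bit RGB in this
orientation.
"""

from __future__ import annotations

import datetime as _dt
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

logger = logging.getLogger("rhizopipe")

#: Nominal scanner calibration (CI-600 class instrument).
DEFAULT_DPI = 300.0
#: Along-tube extent of one scan, cm.
DEFAULT_SCAN_WIDTH_CM = 19.6
#: Circumferential extent of one scan (full unwrapped circumference), cm.
DEFAULT_SCAN_HEIGHT_CM = 21.6

CM_PER_INCH = 2.54

#: Fixed vertical depth bins used for profiles and the core comparison, cm.
DEPTH_BIN_EDGES = (0.0, 30.0, 60.0, 90.0, 120.0)
DEPTH_BIN_LABELS = ("0-30", "30-60", "60-90", "90-120")

QUARTER_LABELS = ("above", "right", "below", "left")

#: Default filename template; ``{index}`` must be last so the regex stays simple.
DEFAULT_FILENAME_TEMPLATE = "{tube}_{date}_p{index}"


class RhizopipeError(Exception):
    """Base class for fatal pipeline errors."""


@dataclass
class ScanImage:
    """One raw scanner capture plus its metadata and physical calibration."""

    pixels: np.ndarray  # (H, W, 3) uint8
    tube_id: str
    scan_date: _dt.date
    position_index: int  # 1 = shallowest scanner position
    plot_id: str = ""
    dpi: float = DEFAULT_DPI
    scan_width_cm: float = DEFAULT_SCAN_WIDTH_CM
    scan_height_cm: float = DEFAULT_SCAN_HEIGHT_CM

    def __post_init__(self) -> None:
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise RhizopipeError(
                f"ScanImage pixels must be (H, W, 3) RGB, got {self.pixels.shape}"
            )
        if self.position_index < 1:
            raise RhizopipeError("position_index must be >= 1")

    def check_calibration(self, tol_px: int = 2) -> bool:
        """True when raster dims match dpi x physical size within ``tol_px``."""
        h, w = self.pixels.shape[:2]
        exp_w = self.scan_width_cm / CM_PER_INCH * self.dpi
        exp_h = self.scan_height_cm / CM_PER_INCH * self.dpi
        return abs(w - exp_w) <= tol_px and abs(h - exp_h) <= tol_px


@dataclass
class CoreRecord:
    """Root length density from one destructive soil core, per depth bin."""

    plot_id: str
    depth_bin: str  # one of DEPTH_BIN_LABELS
    rld: float  # cm cm^-3
    sample_date: _dt.date

    def __post_init__(self) -> None:
        if self.depth_bin not in DEPTH_BIN_LABELS:
            raise RhizopipeError(
                f"depth_bin must be one of {DEPTH_BIN_LABELS}, got {self.depth_bin!r}"
            )
        if not (self.rld >= 0):
            raise RhizopipeError(f"rld must be non-negative, got {self.rld}")


def _template_to_regex(template: str) -> re.Pattern:
    pat = re.escape(template)
    pat = pat.replace(r"\{tube\}", r"(?P<tube>[^_]+)")
    pat = pat.replace(r"\{date\}", r"(?P<date>\d{4}-\d{2}-\d{2})")
    pat = pat.replace(r"\{index\}", r"(?P<index>\d+)")
    return re.compile(pat + r"$")


def _normalise_raster(arr: np.ndarray, path: Path) -> np.ndarray:
    """Coerce a raster to 8-bit RGB; 16-bit inputs are rescaled with a warning."""
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[-1] == 4:  # drop alpha
        arr = arr[..., :3]
    if arr.dtype == np.uint16:
        logger.warning("16-bit raster %s rescaled to 8-bit", path.name)
        arr = (arr.astype(np.float64) / 257.0).round().astype(np.uint8)
    elif arr.dtype != np.uint8:
        arr = np.clip(arr, 0, 255).astype(np.uint8)
    return np.ascontiguousarray(arr)


def load_scan_series(
    directory: str | Path,
    pattern: str = DEFAULT_FILENAME_TEMPLATE,
    plot_id: str = "",
    dpi: float = DEFAULT_DPI,
) -> list[ScanImage]:
    """Load all scans in ``directory`` matching the filename template.

    Returns scans sorted by position index ascending (shallowest first),
    independent of filesystem listing order.  Unparsable filenames and
    duplicate position indices are fatal.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise RhizopipeError(f"scan directory does not exist: {directory}")
    regex = _template_to_regex(pattern)
    scans: list[ScanImage] = []
    raster_exts = {".png", ".tif", ".tiff", ".jpg", ".jpeg"}
    for path in sorted(directory.iterdir()):
        if path.suffix.lower() not in raster_exts:
            continue
        m = regex.match(path.stem)
        if m is None:
            raise RhizopipeError(
                f"filename {path.name!r} does not match template {pattern!r}"
            )
        pixels = _normalise_raster(np.asarray(iio.imread(path)), path)
        scans.append(
            ScanImage(
                pixels=pixels,
                tube_id=m.group("tube"),
                scan_date=_dt.date.fromisoformat(m.group("date")),
                position_index=int(m.group("index")),
                plot_id=plot_id,
                dpi=dpi,
            )
        )
    seen: dict[tuple[str, _dt.date, int], str] = {}
    for s in scans:
        key = (s.tube_id, s.scan_date, s.position_index)
        if key in seen:
            raise RhizopipeError(
                f"duplicate position_index {s.position_index} for tube "
                f"{s.tube_id} on {s.scan_date}"
            )
        seen[key] = s.tube_id
    scans.sort(key=lambda s: (s.tube_id, s.scan_date, s.position_index))
    return scans


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a binary mask as single-channel PNG, root=255 / background=0."""
    mask = np.asarray(mask)
    vals = np.unique(mask)
    if not np.all(np.isin(vals, [0, 1])):
        raise RhizopipeError(f"mask must be binary {{0,1}}, found values {vals[:10]}")
    iio.imwrite(Path(path), (mask.astype(np.uint8) * 255), extension=".png")


def read_mask(path: str | Path) -> np.ndarray:
    """Read a mask PNG back to a {0,1} array (inverse of :func:`write_mask`)."""
    arr = np.asarray(iio.imread(Path(path)))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return (arr > 127).astype(np.uint8)


def write_results_table(rows: Sequence, path: str | Path) -> pd.DataFrame:
    """Write DepthProfile or QuarterSummary records as CSV.

    One row per (tube, date, bin); numeric columns are root lengths in cm
    written with 6 decimals.  Mixing record kinds is fatal.  An empty list
    yields a header-only depth-profile file.
    """
    kinds = {type(r).__name__ for r in rows}
    if len(kinds) > 1:
        raise RhizopipeError(f"mixed record kinds in results table: {sorted(kinds)}")
    records: list[dict] = []
    for r in rows:
        records.extend(r.to_rows())
    if records:
        df = pd.DataFrame.from_records(records)
    else:
        df = pd.DataFrame(
            columns=["tube_id", "plot_id", "scan_date", "bin_label", "root_length_cm"]
        )
    df.to_csv(path, index=False, float_format="%.6f")
    return df


def read_core_table(path: str | Path) -> list[CoreRecord]:
    """Read a destructive-core CSV with columns plot_id, depth_bin, rld, date."""
    df = pd.read_csv(path, dtype={"plot_id": str, "depth_bin": str})
    return [
        CoreRecord(
            plot_id=row["plot_id"],
            depth_bin=row["depth_bin"],
            rld=float(row["rld"]),
            sample_date=_dt.date.fromisoformat(str(row["date"])),
        )
        for _, row in df.iterrows()
    ]


def write_core_table(records: Iterable[CoreRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "plot_id": r.plot_id,
                "depth_bin": r.depth_bin,
                "rld": r.rld,
                "date": r.sample_date.isoformat(),
            }
            for r in records
        ]
    )
    df.to_csv(path, index=False, float_format="%.6f")
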