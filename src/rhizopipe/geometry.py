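"""Tube geometry: composite-image coordinates to soil depth and quarters.

The tube is installed at 30 degrees from the soil surface, so a distance d
along the tube below the soil entry point corresponds to a vertical depth
d*sin(angle).  Two conversion modes are shipped:

* ``paper`` (default): vertical depth = d * sin(60 deg), i.e. the along-tube
  boundary for a target depth t is t / sin(60 deg).  This is the published
  conversion for this instrument layout.
* ``physical``: vertical depth = d * sin(30 deg), the trigonometric identity
  for a tube inclined 30 degrees from the surface.

The two differ by the constant factor sin(60)/sin(30) = sqrt(3); both are
exposed because the published conversion is inconsistent with a 30-degree
installation and users may need either.

The circumferential (row) axis covers the full unwrapped tube circumference
and is divided into four equal quarter bands — above, right, below, left —
starting at a configurable rotational offset (scanner registration is
instrument-specific).
"""

from __future__ import annotations

import math
import logging
from dataclasses import dataclass

import numpy as np

from .io import (
    CM_PER_INCH,
    DEFAULT_DPI,
    DEPTH_BIN_EDGES,
    DEPTH_BIN_LABELS,
    QUARTER_LABELS,
    RhizopipeError,
)
from .features import RootComponent

logger = logging.getLogger("rhizopipe")

#: Along-tube length left above ground at installation, cm.
ABOVE_GROUND_TUBE_CM = 20.0


@dataclass
class TubeGeometry:
    """Physical installation geometry of one minirhizotron tube."""

    surface_angle_deg: float = 30.0  # inclination from the soil surface
    outer_diameter_mm: float = 70.0
    dpi: float = DEFAULT_DPI
    #: pixel column of the soil surface; None = 20 cm of above-ground tube
    soil_entry_col: int | None = None
    quarter_offset: int = 0  # circumferential rotation in rows

    def __post_init__(self) -> None:
        if not (0.0 < self.surface_angle_deg < 90.0):
            raise RhizopipeError("surface_angle_deg must be in (0, 90)")

    @property
    def complement_angle_deg(self) -> float:
        return 90.0 - self.surface_angle_deg

    @property
    def entry_col(self) -> int:
        if self.soil_entry_col is not None:
            return self.soil_entry_col
        return int(round(ABOVE_GROUND_TUBE_CM / CM_PER_INCH * self.dpi))

    def depth_factor(self, mode: str) -> float:
        """sin of the conversion angle: depth = along-tube distance x factor."""
        if mode == "paper":
            return math.sin(math.radians(self.complement_angle_deg))
        if mode == "physical":
            return math.sin(math.radians(self.surface_angle_deg))
        raise RhizopipeError(f"unknown depth mode {mode!r} (use 'paper' or 'physical')")


@dataclass
class DepthProfile:
    """Root length per vertical depth bin for one tube x date."""

    tube_id: str
    scan_date: object
    bins: dict[str, float]  # DEPTH_BIN_LABELS -> root length cm
    overflow_cm: float = 0.0  # length mapping beyond 120 cm vertical depth
    plot_id: str = ""
    mode: str = "paper"

    def to_rows(self) -> list[dict]:
        return [
            {
                "tube_id": self.tube_id,
                "plot_id": self.plot_id,
                "scan_date": str(self.scan_date),
                "bin_label": lab,
                "root_length_cm": self.bins[lab],
            }
            for lab in DEPTH_BIN_LABELS
        ]


@dataclass
class QuarterSummary:
    """Root length per circumferential quarter for one tube x date."""

    tube_id: str
    scan_date: object
    lengths: dict[str, float]  # QUARTER_LABELS -> root length cm
    plot_id: str = ""

    def to_rows(self) -> list[dict]:
        return [
            {
                "tube_id": self.tube_id,
                "plot_id": self.plot_id,
                "scan_date": str(self.scan_date),
                "bin_label": lab,
                "root_length_cm": self.lengths[lab],
            }
            for lab in QUARTER_LABELS
        ]


def along_tube_boundary(t_cm: float, mode: str, geom: TubeGeometry) -> float:
    """Along-tube distance (cm) at which vertical depth ``t_cm`` is reached.

    ``paper`` mode: t / sin(60 deg) for the default 30-degree installation;
    ``physical`` mode: t / sin(30 deg).
    """
    if t_cm < 0:
        raise RhizopipeError("vertical depth must be non-negative")
    return t_cm / geom.depth_factor(mode)


def pixel_vertical_depth(
    col: np.ndarray | float, geom: TubeGeometry, mode: str = "paper"
) -> np.ndarray | float:
    """Vertical soil depth (cm) of composite-image column(s); inverse of
    :func:`along_tube_boundary`.

    Columns above the soil entry point map to depth 0 (with a warning).
    """
    col = np.asarray(col, dtype=np.float64)
    d_cm = (col - geom.entry_col) * CM_PER_INCH / geom.dpi
    if np.any(d_cm < 0):
        logger.warning("column(s) above the soil entry point clamped to depth 0")
        d_cm = np.maximum(d_cm, 0.0)
    depth = d_cm * geom.depth_factor(mode)
    return float(depth) if depth.ndim == 0 else depth


def assign_depth_bins(
    components: list[RootComponent],
    geom: TubeGeometry,
    mode: str = "paper",
    tube_id: str = "",
    scan_date: object = "",
    plot_id: str = "",
) -> DepthProfile:
    """Length-weighted attribution of root length to vertical depth bins.

    Every skeleton pixel contributes its length weight to the bin of its own
    vertical depth, so components crossing a bin boundary are split rather
    than assigned wholesale.  Length beyond 120 cm accumulates in
    ``overflow_cm`` and is excluded from the profile bins.
    """
    bins = {lab: 0.0 for lab in DEPTH_BIN_LABELS}
    overflow = 0.0
    edges = np.asarray(DEPTH_BIN_EDGES)
    for comp in components:
        depths = pixel_vertical_depth(comp.skeleton_cols.astype(np.float64), geom, mode)
        depths = np.atleast_1d(depths)
        idx = np.searchsorted(edges, depths, side="right") - 1
        for lab_i, lab in enumerate(DEPTH_BIN_LABELS):
            bins[lab] += float(comp.pixel_lengths_cm[idx == lab_i].sum())
        overflow += float(comp.pixel_lengths_cm[idx >= len(DEPTH_BIN_LABELS)].sum())
    return DepthProfile(
        tube_id=tube_id,
        scan_date=scan_date,
        plot_id=plot_id,
        bins=bins,
        overflow_cm=overflow,
        mode=mode,
    )


def assign_quarters(
    components: list[RootComponent],
    geom: TubeGeometry,
    image_height: int,
    tube_id: str = "",
    scan_date: object = "",
    plot_id: str = "",
) -> QuarterSummary:
    """Length-weighted attribution to the four circumferential quarters.

    The row axis (full unwrapped circumference) is divided into four equal
    bands in the order above, right, below, left, after rotating by
    ``geom.quarter_offset`` rows.  Band sums equal the total skeleton length.
    """
    lengths = {lab: 0.0 for lab in QUARTER_LABELS}
    band = image_height / 4.0
    for comp in components:
        rows = (comp.skeleton_rows.astype(np.float64) - geom.quarter_offset) % image_height
        idx = np.minimum((rows / band).astype(int), 3)
        for lab_i, lab in enumerate(QUARTER_LABELS):
            lengths[lab] += float(comp.pixel_lengths_cm[idx == lab_i].sum())
        # set the component's dominant quarter for per-component reporting
        if len(rows):
            counts = np.bincount(idx, minlength=4)
            comp.quarter = QUARTER_LABELS[int(counts.argmax())]
    return QuarterSummary(
        tube_id=tube_id, scan_date=scan_date, plot_id=plot_id, lengths=lengths
    )
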