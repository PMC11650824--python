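"""Stitching consecutive tube scans into one composite image per tube.

Consecutive scanner positions share a nominal 1 cm overlap (~118 px at
300 dpi).  Each pair is aligned by matching ORB keypoints between the
grayscale images (Hamming-distance matching with cross-check) and fitting a
projective transform with RANSAC.  Because the scanner sits at fixed,
rigidly spaced positions inside the tube, the transform is reduced to its
horizontal displacement: the overlapping columns of the right image are
cropped and the images concatenated — no warping or blending.  Pairs that
cannot be aligned (featureless soil, too few inliers) fall back to the
nominal overlap and are logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage.color import rgb2gray
from skimage.feature import ORB, match_descriptors
from skimage.measure import ransac
from skimage.transform import ProjectiveTransform

from .io import CM_PER_INCH, RhizopipeError, ScanImage

logger = logging.getLogger("rhizopipe")


@dataclass
class StitchConfig:
    """Tunables for pairwise alignment; defaults follow the scanner geometry."""

    n_keypoints: int = 500
    ransac_threshold_px: float = 2.0
    ransac_max_trials: int = 1000
    seed: int = 0
    nominal_overlap_cm: float = 1.0  # fixed scanner positions overlap by 1 cm
    keep_fraction: float = 0.5
    #: restrict keypoint search to a band this many nominal overlaps wide
    #: at the seam; 0 disables the restriction
    search_band_overlaps: float = 3.0


@dataclass
class Correspondences:
    """Matched keypoint pairs between a left and a right image."""

    left_points: np.ndarray  # (N, 2) as (row, col)
    right_points: np.ndarray
    distances: np.ndarray  # Hamming distances of the matched descriptors

    def __len__(self) -> int:
        return len(self.left_points)


@dataclass
class StitchedTube:
    """Composite per-tube raster with its along-tube calibration."""

    pixels: np.ndarray  # (H, W, 3) uint8
    tube_id: str
    scan_date: object
    dpi: float
    column_origin_cm: float = 0.0  # along-tube distance of column 0
    plot_id: str = ""
    n_fallbacks: int = 0  # pairs stitched with the nominal offset

    @property
    def width_px(self) -> int:
        return self.pixels.shape[1]


def nominal_overlap_px(dpi: float, nominal_overlap_cm: float = 1.0) -> int:
    """Nominal scan overlap in pixels (1 cm at 300 dpi -> 118 px)."""
    return int(round(nominal_overlap_cm / CM_PER_INCH * dpi))


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Luminance grayscale (0.2125 R + 0.7154 G + 0.0721 B), values in [0,1]."""
    if image.ndim != 3 or image.shape[2] != 3:
        raise RhizopipeError(f"expected a 3-channel RGB image, got shape {image.shape}")
    return rgb2gray(image)


def trim_overlap(
    left: np.ndarray, right: np.ndarray, keep_fraction: float, overlap_px: int
) -> tuple[np.ndarray, np.ndarray]:
    """Zero out the nominal overlap band, keeping a fraction of the right image.

    The rightmost ``overlap_px`` columns of the left image and the leftmost
    ``(1 - keep_fraction) * overlap_px`` columns of the right image are set
    to zero; dimensions are unchanged.  An optional preprocessing step — the
    primary overlap removal is the RANSAC-based crop in :func:`stitch_pair`.
    """
    if not (0.0 <= keep_fraction <= 1.0):
        raise RhizopipeError(f"keep_fraction must be in [0, 1], got {keep_fraction}")
    if left.shape[0] != right.shape[0]:
        raise RhizopipeError("left and right images must share height")
    left = left.copy()
    right = right.copy()
    drop_right = int(round((1.0 - keep_fraction) * overlap_px))
    if overlap_px > 0:
        left[:, left.shape[1] - overlap_px :] = 0
    if drop_right > 0:
        right[:, :drop_right] = 0
    return left, right


def match_keypoints(
    left_gray: np.ndarray, right_gray: np.ndarray, n_keypoints: int = 500
) -> Correspondences:
    """ORB keypoints matched by minimum Hamming distance with cross-check.

    Returns empty correspondences when either image yields no keypoints
    (e.g. featureless soil); the caller decides the fallback.
    """
    if left_gray.ndim != 2 or right_gray.ndim != 2:
        raise RhizopipeError("match_keypoints expects single-channel images")
    empty = Correspondences(
        np.empty((0, 2)), np.empty((0, 2)), np.empty((0,))
    )
    orb_l = ORB(n_keypoints=n_keypoints)
    orb_r = ORB(n_keypoints=n_keypoints)
    try:
        orb_l.detect_and_extract(left_gray)
        orb_r.detect_and_extract(right_gray)
    except RuntimeError:  # raised by skimage when no keypoints are found
        return empty
    if len(orb_l.keypoints) == 0 or len(orb_r.keypoints) == 0:
        return empty
    matches = match_descriptors(
        orb_l.descriptors, orb_r.descriptors, metric="hamming", cross_check=True
    )
    if len(matches) == 0:
        return empty
    d = np.count_nonzero(
        orb_l.descriptors[matches[:, 0]] != orb_r.descriptors[matches[:, 1]], axis=1
    ).astype(float)
    return Correspondences(
        left_points=orb_l.keypoints[matches[:, 0]],
        right_points=orb_r.keypoints[matches[:, 1]],
        distances=d,
    )


def estimate_alignment(
    c: Correspondences,
    seed: int = 0,
    residual_threshold: float = 2.0,
    max_trials: int = 1000,
) -> tuple[ProjectiveTransform | None, np.ndarray]:
    """RANSAC projective fit mapping right-image points into left-image frame.

    Returns ``(transform, inlier_flags)``; ``(None, flags)`` signals
    alignment failure (under-determined or too few inliers) and is
    non-fatal — callers fall back to the nominal offset.
    """
    n = len(c)
    if n < 4:
        return None, np.zeros(n, dtype=bool)
    # skimage transforms use (x, y) = (col, row)
    src = c.right_points[:, ::-1]
    dst = c.left_points[:, ::-1]
    try:
        model, inliers = ransac(
            (src, dst),
            ProjectiveTransform,
            min_samples=4,
            residual_threshold=residual_threshold,
            max_trials=max_trials,
            rng=seed,
        )
    except ValueError:
        return None, np.zeros(n, dtype=bool)
    if model is None or inliers is None or inliers.sum() < 4:
        return None, np.zeros(n, dtype=bool)
    return model, inliers


def horizontal_displacement(
    c: Correspondences, inliers: np.ndarray
) -> float:
    """Column of the right image's origin in left-image coordinates.

    The projective model is reduced to its horizontal displacement — the
    dominant term for rigidly spaced scanner positions — measured as the
    median column shift over the RANSAC inliers.  (Evaluating the fitted
    projective matrix at the image corner instead would extrapolate far from
    the keypoint cluster and is numerically fragile.)
    """
    dx = c.left_points[inliers, 1] - c.right_points[inliers, 1]
    return float(np.median(dx))


def estimate_offset(
    left: ScanImage | np.ndarray,
    right: ScanImage | np.ndarray,
    config: StitchConfig | None = None,
) -> float | None:
    """Estimated horizontal offset (px) of ``right`` relative to ``left``.

    Convenience wrapper: grayscale -> ORB matching -> RANSAC -> horizontal
    displacement.  When ``config.search_band_overlaps`` > 0, keypoint search
    is restricted to a band around the expected seam, which speeds matching
    and discards far-field false matches.  Returns None on failure.
    """
    config = config or StitchConfig()
    lpix = left.pixels if isinstance(left, ScanImage) else left
    rpix = right.pixels if isinstance(right, ScanImage) else right
    dpi = left.dpi if isinstance(left, ScanImage) else 300.0
    gl = to_grayscale(lpix)
    gr = to_grayscale(rpix)
    band = 0
    if config.search_band_overlaps > 0:
        nom = nominal_overlap_px(dpi, config.nominal_overlap_cm)
        band = int(round(config.search_band_overlaps * nom))
    if band and band < gl.shape[1]:
        gl_band = gl[:, gl.shape[1] - band :]
        gr_band = gr[:, :band]
        shift_l = gl.shape[1] - band
    else:
        gl_band, gr_band, shift_l = gl, gr, 0
    c = match_keypoints(gl_band, gr_band, config.n_keypoints)
    if len(c) < 4:
        # band may have clipped the true seam; retry on the full frames
        if shift_l:
            c = match_keypoints(gl, gr, config.n_keypoints)
            shift_l = 0
        if len(c) < 4:
            return None
    model, inliers = estimate_alignment(
        c, config.seed, config.ransac_threshold_px, config.ransac_max_trials
    )
    if model is None:
        return None
    return horizontal_displacement(c, inliers) + shift_l


def stitch_pair(
    left: np.ndarray, right: np.ndarray, offset_px: float
) -> np.ndarray:
    """Crop the overlapping columns of ``right`` and concatenate.

    ``offset_px`` is the column of the right image's origin in the left
    image; the first ``left_width - offset`` columns of the right image
    duplicate the seam and are dropped.  A non-positive retained width is
    the caller's signal to fall back to the nominal offset.
    """
    if left.shape[0] != right.shape[0]:
        raise RhizopipeError("stitch_pair requires equal heights")
    w_left = left.shape[1]
    overlap = int(round(w_left - offset_px))
    overlap = max(overlap, 0)
    if overlap >= right.shape[1]:
        raise RhizopipeError(
            f"offset {offset_px:.1f} retains no columns of the right image"
        )
    return np.concatenate([left, right[:, overlap:]], axis=1)


def stitch_series(
    series: list[ScanImage], config: StitchConfig | None = None
) -> StitchedTube:
    """Stitch an ordered scan series into one composite per tube.

    Scans are stitched pairwise in position order (shallow to deep, left to
    right).  Pairs whose alignment fails — or whose estimated offset would
    retain nothing of the next scan — fall back to the nominal 1 cm overlap
    abutment; every fallback is logged and counted.
    """
    if not series:
        raise RhizopipeError("cannot stitch an empty series")
    config = config or StitchConfig()
    heights = {s.pixels.shape[0] for s in series}
    if len(heights) != 1:
        raise RhizopipeError(f"inconsistent scan heights: {sorted(heights)}")
    series = sorted(series, key=lambda s: s.position_index)
    first = series[0]
    nom = nominal_overlap_px(first.dpi, config.nominal_overlap_cm)
    composite = first.pixels
    n_fallbacks = 0
    for nxt in series[1:]:
        # align against the most recent tile-width window, not the whole composite
        prev_w = composite.shape[1]
        tile_w = nxt.pixels.shape[1]
        head_w = max(prev_w - tile_w, 0)
        left_ref = composite[:, head_w:]
        offset = estimate_offset(
            ScanImage(
                pixels=left_ref,
                tube_id=first.tube_id,
                scan_date=first.scan_date,
                position_index=1,
                dpi=first.dpi,
            ),
            nxt,
            config,
        )
        if offset is None or not (0 < left_ref.shape[1] - offset < tile_w):
            logger.warning(
                "stitch fallback to nominal overlap for tube %s position %d",
                nxt.tube_id,
                nxt.position_index,
            )
            n_fallbacks += 1
            offset = left_ref.shape[1] - nom
        merged = stitch_pair(left_ref, nxt.pixels, offset)
        composite = np.concatenate([composite[:, :head_w], merged], axis=1)
    return StitchedTube(
        pixels=composite,
        tube_id=first.tube_id,
        plot_id=first.plot_id,
        scan_date=first.scan_date,
        dpi=first.dpi,
        n_fallbacks=n_fallbacks,
    )
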