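"""Seeded synthetic minirhizotron data with analytic ground truth.

Real minirhizotron imagery shows brighter curvilinear roots on a darker,
spatially correlated soil background.  The generators here emulate exactly
that structure — band-limited earth-tone noise, smooth random polyline roots
of controllable width and contrast, tiled scans with known overlaps, and
paired core/minirhizotron observations on a stated linear relationship —
so every pipeline stage can be checked against known truth.

Ground-truth root lengths are *analytic* polyline arc lengths, computed from
the polyline vertices and never re-derived from any raster.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.draw import line as _draw_line
from skimage.morphology import dilation, disk

from .io import CM_PER_INCH, DEFAULT_DPI, RhizopipeError, ScanImage

#: Earth-tone base colour (RGB, 0-255) around which the soil texture varies.
SOIL_BASE_RGB = (110.0, 85.0, 60.0)
#: Root colour the blend moves towards at intensity 1 (pale root on dark soil).
ROOT_RGB = (225.0, 215.0, 190.0)


@dataclass
class SceneSpec:
    """Parameters of one synthetic scene.

    Defaults describe a test-scale scene: a 384x512 px canvas with a handful
    of non-crossing roots 3-7 px wide at a contrast well above the background
    noise, mimicking healthy pale wheat roots against moist loess soil.
    """

    canvas_shape: tuple[int, int] = (384, 512)
    n_roots: int = 6
    root_width_px: tuple[int, int] = (3, 7)
    root_intensity: float = 0.8  # blend fraction towards ROOT_RGB
    background_scale: float = 4.0  # texture correlation length, px
    seed: int = 0
    allow_crossings: bool = False

    def __post_init__(self) -> None:
        if self.n_roots < 0:
            raise RhizopipeError("n_roots must be >= 0")
        if min(self.root_width_px) < 1:
            raise RhizopipeError("root widths must be >= 1 px")


def generate_soil_background(
    shape: tuple[int, int], background_scale: float, seed: int
) -> np.ndarray:
    """Band-limited earth-tone noise texture, deterministic per seed.

    White noise is Gaussian-smoothed at ``background_scale`` (the texture
    correlation length in px) and renormalised, then mapped around the soil
    base colour with mild per-channel variation.
    """
    if shape[0] <= 0 or shape[1] <= 0:
        raise RhizopipeError("background shape must be positive")
    rng = np.random.default_rng(seed)
    field = rng.standard_normal(shape)
    if background_scale > 0:
        field = ndi.gaussian_filter(field, background_scale, mode="reflect")
        sd = field.std()
        if sd > 0:
            field = field / sd
    # finer component: gritty aggregate detail real scans are full of
    mid = ndi.gaussian_filter(
        rng.standard_normal(shape), max(background_scale / 4.0, 0.8), mode="reflect"
    )
    msd = mid.std()
    if msd > 0:
        mid = mid / msd
    # coarser component: large-scale shading typical of field soil
    coarse = ndi.gaussian_filter(
        rng.standard_normal(shape), 8 * max(background_scale, 1), mode="reflect"
    )
    csd = coarse.std()
    if csd > 0:
        coarse = coarse / csd
    tex = 0.7 * field + 0.5 * mid + 0.45 * coarse
    img = np.empty(shape + (3,), dtype=np.float64)
    for c, base in enumerate(SOIL_BASE_RGB):
        img[..., c] = base * (1.0 + 0.18 * tex)
    img += rng.normal(0.0, 6.0, size=img.shape)  # sensor-like pixel grain
    return np.clip(img, 0, 255).astype(np.uint8)


def _random_polyline(
    rng: np.random.Generator,
    shape: tuple[int, int],
    step_px: float = 4.0,
    max_turn_rad: float = 0.2,
    min_self_dist_px: float = 12.0,
) -> np.ndarray:
    """Smooth random-walk polyline inside the canvas, as (N, 2) (row, col).

    The heading performs a bounded random walk (curvature limit) and the walk
    is self-avoiding at ``min_self_dist_px`` so the rasterised root never
    touches itself — skeletonisation then stays well-behaved and length
    attribution unambiguous.  The walk stops at the canvas edge, hence no
    polyline leaves the canvas.
    """
    h, w = shape
    margin = 8
    r = rng.uniform(margin, h - margin)
    c = rng.uniform(margin, w - margin)
    theta = rng.uniform(0, 2 * np.pi)
    n_steps = int(rng.integers(20, 60))
    pts = [(r, c)]
    for _ in range(n_steps):
        theta += rng.uniform(-max_turn_rad, max_turn_rad)
        r += step_px * np.sin(theta)
        c += step_px * np.cos(theta)
        if not (margin <= r < h - margin and margin <= c < w - margin):
            break
        if len(pts) > 4:
            prev = np.asarray(pts[:-4])
            d2 = ((prev - (r, c)) ** 2).sum(axis=1)
            if d2.min() < min_self_dist_px**2:
                break
        pts.append((r, c))
    return np.asarray(pts, dtype=np.float64)


def _polyline_length_px(pts: np.ndarray) -> float:
    """Analytic arc length of a polyline in pixels."""
    if len(pts) < 2:
        return 0.0
    return float(np.sqrt(((np.diff(pts, axis=0)) ** 2).sum(axis=1)).sum())


def _rasterize_polyline(pts: np.ndarray, shape: tuple[int, int], width: int) -> np.ndarray:
    canvas = np.zeros(shape, dtype=bool)
    ipts = np.rint(pts).astype(int)
    for (r0, c0), (r1, c1) in zip(ipts[:-1], ipts[1:]):
        rr, cc = _draw_line(r0, c0, r1, c1)
        canvas[rr, cc] = True
    radius = max((width - 1) // 2, 0)
    if radius > 0:
        canvas = dilation(canvas, disk(radius))
    return canvas


def generate_root_mask(spec: SceneSpec) -> tuple[np.ndarray, list[dict]]:
    """Rasterize random root polylines; return the mask and analytic truths.

    Returns ``(mask, roots)`` where ``mask`` is a {0,1} uint8 raster and each
    entry of ``roots`` holds the polyline vertices, its drawn width and its
    analytic length in px and cm (at 300 dpi unless rescaled by the caller).
    With ``allow_crossings=False`` (default) roots are placed by rejection so
    their dilated footprints stay disjoint — length attribution is then
    unambiguous.
    """
    rng = np.random.default_rng(spec.seed)
    mask = np.zeros(spec.canvas_shape, dtype=bool)
    occupied = np.zeros(spec.canvas_shape, dtype=bool)
    roots: list[dict] = []
    attempts = 0
    while len(roots) < spec.n_roots and attempts < 60 * max(spec.n_roots, 1):
        attempts += 1
        pts = _random_polyline(rng, spec.canvas_shape)
        if _polyline_length_px(pts) < 40:
            continue
        width = int(rng.integers(spec.root_width_px[0], spec.root_width_px[1] + 1))
        footprint = _rasterize_polyline(pts, spec.canvas_shape, width)
        if not spec.allow_crossings:
            # forbid contact within a safety margin so components stay separate
            grown = dilation(footprint, disk(4))
            if (grown & occupied).any():
                continue
            occupied |= grown
        mask |= footprint
        length_px = _polyline_length_px(pts)
        roots.append(
            {
                "polyline": pts,
                "width_px": width,
                "length_px": length_px,
                "length_cm": length_px * CM_PER_INCH / DEFAULT_DPI,
            }
        )
    return mask.astype(np.uint8), roots


def render_scene(
    background: np.ndarray, mask: np.ndarray, root_intensity: float
) -> np.ndarray:
    """Blend root pixels over the soil background at the given contrast.

    ``root_intensity`` is the blend fraction towards the pale root colour:
    0 leaves the background untouched, 1 paints fully saturated roots.
    """
    if background.shape[:2] != mask.shape:
        raise RhizopipeError(
            f"background {background.shape[:2]} and mask {mask.shape} shapes differ"
        )
    out = background.astype(np.float64).copy()
    m = mask.astype(bool)
    root = np.asarray(ROOT_RGB, dtype=np.float64)
    out[m] = (1.0 - root_intensity) * out[m] + root_intensity * root
    return np.clip(out, 0, 255).astype(np.uint8)


def generate_scene(spec: SceneSpec) -> tuple[np.ndarray, np.ndarray, list[dict]]:
    """Convenience: background + mask + render, all from one spec/seed."""
    bg = generate_soil_background(spec.canvas_shape, spec.background_scale, spec.seed)
    mask, roots = generate_root_mask(spec)
    img = render_scene(bg, mask, spec.root_intensity)
    return img, mask, roots


def generate_tube_series(
    spec: SceneSpec,
    n_tiles: int,
    overlap_px: int,
    seed: int | None = None,
    tube_id: str = "T01",
    plot_id: str = "P01",
    scan_date: _dt.date = _dt.date(2022, 5, 23),
    dpi: float = DEFAULT_DPI,
) -> tuple[list[ScanImage], list[int], np.ndarray, np.ndarray]:
    """Render one wide canvas and cut it into overlapping scanner tiles.

    The canvas height is ``spec.canvas_shape[0]`` and the tile width is
    ``spec.canvas_shape[1]``; the canvas spans ``n_tiles`` tiles with exactly
    ``overlap_px`` shared columns between neighbours.  Returns the tiles as
    :class:`ScanImage` (positions 1..n, shallow to deep), the true tile
    offsets (column of each tile's origin in the canvas), and the
    ground-truth canvas and mask for round-trip checks.
    """
    if n_tiles < 1:
        raise RhizopipeError("n_tiles must be >= 1")
    tile_h, tile_w = spec.canvas_shape
    if overlap_px >= tile_w:
        raise RhizopipeError("overlap must be smaller than the tile width")
    canvas_w = n_tiles * tile_w - (n_tiles - 1) * overlap_px
    cspec = SceneSpec(
        canvas_shape=(tile_h, canvas_w),
        n_roots=spec.n_roots,
        root_width_px=spec.root_width_px,
        root_intensity=spec.root_intensity,
        background_scale=spec.background_scale,
        seed=spec.seed if seed is None else seed,
        allow_crossings=spec.allow_crossings,
    )
    canvas, mask, _ = generate_scene(cspec)
    stride = tile_w - overlap_px
    offsets = [i * stride for i in range(n_tiles)]
    tiles = [
        ScanImage(
            pixels=canvas[:, off : off + tile_w].copy(),
            tube_id=tube_id,
            plot_id=plot_id,
            scan_date=scan_date,
            position_index=i + 1,
            dpi=dpi,
        )
        for i, off in enumerate(offsets)
    ]
    return tiles, offsets, canvas, mask


def generate_paired_method_data(
    slope: float,
    intercept: float,
    sigma: float,
    n: int,
    seed: int,
    x_range: tuple[float, float] = (5.0, 150.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Paired core/minirhizotron observations on a known line.

    The predictor x is drawn uniformly on ``x_range``; its default spans the
    5-150 cm per-plot minirhizotron root lengths over which such method
    comparisons are fitted (with the published-scale coefficients, slope
    ~0.01 and intercept ~0.1, the response is then a core root length density
    of ~0.1-1.7 cm cm^-3).  y = intercept + slope*x + N(0, sigma).
    Deterministic per seed.
    """
    if n < 3:
        raise RhizopipeError("n must be >= 3")
    if sigma < 0:
        raise RhizopipeError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    x = rng.uniform(x_range[0], x_range[1], size=n)
    y = intercept + slope * x + rng.normal(0.0, sigma, size=n)
    return x, y
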