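"""Terrain morphometry from the gridded depth model.

Each cell's neighbourhood is fitted with a quadratic surface
``z = a x^2 + b y^2 + c x y + d x + e y + f`` in cell-centred metric
coordinates (x east, y north), from which slope, aspect, the four
convexities, the principal curvatures and the fit RMSE derive; roughness
layers come from the 3x3 neighbourhood directly.  Cells are then classified
into the six morphometric terrain types (peak, ridge, pass, plane, channel,
pit) from slope and curvature signs, at a configurable window scale.

The grid values are treated as the surface being analysed; pass elevations
(negative depths) if upward-positive conventions are wanted.  Positive
convexity/curvature means convex (dome-like).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from benthoscape.grids import CategoricalRaster, RasterGrid

MORPHO_LAYERS = (
    "absolute_roughness",
    "local_roughness",
    "slope",
    "aspect",
    "shaded_relief",
    "profile_convexity",
    "plan_convexity",
    "longitudinal_convexity",
    "cross_sectional_convexity",
    "minimum_curvature",
    "maximum_curvature",
    "rmse",
)

TERRAIN_LEGEND = ("peak", "ridge", "pass", "plane", "channel", "pit")


@dataclass
class MorphoStack:
    """The 12 morphometric layers plus mean bathymetry and fit coefficients."""

    layers: dict[str, np.ndarray]
    bathymetry: np.ndarray
    coefficients: np.ndarray  # (rows, cols, 6): a, b, c, d, e, f
    cell_size: float

    def __post_init__(self) -> None:
        missing = set(MORPHO_LAYERS) - set(self.layers)
        if missing:
            raise ValueError(f"missing layers: {sorted(missing)}")

    def as_array(self) -> np.ndarray:
        """Stack the 12 layers in canonical order, shape (12, rows, cols)."""
        return np.stack([self.layers[k] for k in MORPHO_LAYERS])


def window_cells(scale_m: float, cell_size: float) -> int:
    """Odd window size (cells) closest to a metric scale (e.g. 6 m -> 3x3)."""
    n = int(round(scale_m / cell_size))
    if n % 2 == 0:
        n += 1
    if n < 3:
        raise ValueError(f"scale {scale_m} m yields window < 3 cells")
    return n


def _window_coords(n: int, cell_size: float) -> tuple[np.ndarray, np.ndarray]:
    m = n // 2
    j = np.arange(n) - m
    x = np.tile(j, n).astype(float) * cell_size          # east
    y = -np.repeat(j, n).astype(float) * cell_size       # north (row 0 north)
    return x, y


def quadratic_design(n: int, cell_size: float) -> np.ndarray:
    """Design matrix of the local quadratic fit over an n x n window."""
    x, y = _window_coords(n, cell_size)
    return np.column_stack([x**2, y**2, x * y, x, y, np.ones_like(x)])


def fit_local_quadratic(window: np.ndarray, cell_size: float = 2.0) -> np.ndarray:
    """Least-squares coefficients (a, b, c, d, e, f) for one odd square window."""
    window = np.asarray(window, dtype=float)
    n = window.shape[0]
    if window.shape != (n, n) or n % 2 == 0:
        raise ValueError("window must be odd and square")
    A = quadratic_design(n, cell_size)
    coef, *_ = np.linalg.lstsq(A, window.ravel(), rcond=None)
    return coef


def _sliding_windows(values: np.ndarray, n: int) -> np.ndarray:
    """(rows, cols, n*n) view of nearest-padded windows around every cell."""
    m = n // 2
    padded = np.pad(values, m, mode="edge")
    win = np.lib.stride_tricks.sliding_window_view(padded, (n, n))
    return win.reshape(values.shape[0], values.shape[1], n * n)


def grid_quadratic_coefficients(values: np.ndarray, n: int, cell_size: float) -> np.ndarray:
    """Per-cell quadratic coefficients, shape (rows, cols, 6)."""
    A = quadratic_design(n, cell_size)
    pinv = np.linalg.pinv(A)
    return _sliding_windows(values, n) @ pinv.T


def _convexities(coef: np.ndarray) -> dict[str, np.ndarray]:
    a, b, c, d, e = (coef[..., i] for i in range(5))
    g2 = d**2 + e**2
    with np.errstate(divide="ignore", invalid="ignore"):
        profile = -200.0 * (a * d**2 + b * e**2 + c * d * e) / (g2 * (1 + g2) ** 1.5)
        plan = 200.0 * (b * d**2 + a * e**2 - c * d * e) / g2**1.5
        longitudinal = np.degrees(-2.0 * (a * d**2 + b * e**2 + c * d * e) / g2)
        cross = np.degrees(-2.0 * (b * d**2 + a * e**2 - c * d * e) / g2)
    flat = g2 == 0
    for arr in (profile, plan, longitudinal, cross):
        arr[flat] = 0.0
    disc = np.sqrt((a - b) ** 2 + c**2)
    return {
        "profile_convexity": profile,
        "plan_convexity": plan,
        "longitudinal_convexity": longitudinal,
        "cross_sectional_convexity": cross,
        "minimum_curvature": np.degrees(-a - b - disc),
        "maximum_curvature": np.degrees(-a - b + disc),
    }


def morpho_stack(
    grid: RasterGrid,
    sun_azimuth: float = 315.0,
    sun_elevation: float = 45.0,
    window: int = 3,
) -> MorphoStack:
    """Derive the 12 morphometric layers (plus mean bathymetry) of a grid."""
    rows, cols = grid.shape
    if rows < window or cols < window:
        raise ValueError("grid smaller than the fitting window")
    z = grid.values
    coef = grid_quadratic_coefficients(z, window, grid.cell_size)
    d, e = coef[..., 3], coef[..., 4]

    slope = np.degrees(np.arctan(np.hypot(d, e)))
    with np.errstate(invalid="ignore"):
        aspect = np.mod(np.degrees(np.arctan2(-d, -e)), 360.0)
    aspect[(d == 0) & (e == 0)] = np.nan

    # Lambertian shaded relief from the fitted gradient.
    az, el = np.radians(sun_azimuth), np.radians(sun_elevation)
    sun = np.array([np.sin(az) * np.cos(el), np.cos(az) * np.cos(el), np.sin(el)])
    norm = np.sqrt(d**2 + e**2 + 1.0)
    shade = np.clip((-d * sun[0] - e * sun[1] + sun[2]) / norm, 0.0, 1.0)

    win3 = _sliding_windows(z, 3)
    abs_rough = win3.std(axis=-1)
    # Local roughness: residual SD after removing the best-fit 3x3 plane.
    A3 = quadratic_design(3, grid.cell_size)[:, 3:]  # x, y, 1
    resid_proj = np.eye(9) - A3 @ np.linalg.pinv(A3)
    local_rough = np.sqrt(np.mean((win3 @ resid_proj.T) ** 2, axis=-1))

    Aq = quadratic_design(window, grid.cell_size)
    winq = _sliding_windows(z, window)
    resid = winq - coef @ Aq.T
    rmse = np.sqrt(np.mean(resid**2, axis=-1))

    layers = {
        "absolute_roughness": abs_rough,
        "local_roughness": local_rough,
        "slope": slope,
        "aspect": aspect,
        "shaded_relief": shade,
        "rmse": rmse,
        **_convexities(coef),
    }
    return MorphoStack(
        layers=layers,
        bathymetry=win3.mean(axis=-1),
        coefficients=coef,
        cell_size=grid.cell_size,
    )


def classify_terrain(
    grid: RasterGrid,
    scale_m: float = 6.0,
    slope_tol: float = 1.0,
    curv_tol: float = 0.005,
) -> CategoricalRaster:
    """Classify every cell into one of the six morphometric terrain types.

    On sloping cells (slope > ``slope_tol`` degrees) the sign of the
    cross-sectional convexity separates ridge / plane / channel; on level
    cells the signs of the principal curvatures separate peak, ridge, pass,
    plane, channel and pit.  ``curv_tol`` is in the curvature layers' units
    (degrees).
    """
    n = window_cells(scale_m, grid.cell_size)
    if min(grid.shape) < n:
        raise ValueError("grid smaller than the classification window")
    coef = grid_quadratic_coefficients(grid.values, n, grid.cell_size)
    conv = _convexities(coef)
    slope = np.degrees(np.arctan(np.hypot(coef[..., 3], coef[..., 4])))
    crosc = conv["cross_sectional_convexity"]
    minic = conv["minimum_curvature"]
    maxic = conv["maximum_curvature"]

    cls = np.full(grid.shape, TERRAIN_LEGEND.index("plane"), dtype=int)
    sloping = slope > slope_tol
    cls[sloping & (crosc > curv_tol)] = TERRAIN_LEGEND.index("ridge")
    cls[sloping & (crosc < -curv_tol)] = TERRAIN_LEGEND.index("channel")

    level = ~sloping
    max_pos, max_neg = maxic > curv_tol, maxic < -curv_tol
    min_pos, min_neg = minic > curv_tol, minic < -curv_tol
    cls[level & max_pos & min_pos] = TERRAIN_LEGEND.index("peak")
    cls[level & max_neg & min_neg] = TERRAIN_LEGEND.index("pit")
    cls[level & max_pos & min_neg] = TERRAIN_LEGEND.index("pass")
    cls[level & max_pos & ~min_pos & ~min_neg] = TERRAIN_LEGEND.index("ridge")
    cls[level & ~max_pos & ~max_neg & min_neg] = TERRAIN_LEGEND.index("channel")
    return CategoricalRaster(cls, TERRAIN_LEGEND, cell_size=grid.cell_size,
                             x0=grid.x0, y0=grid.y0)
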