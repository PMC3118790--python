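"""Seeded synthetic survey generator.

Generates the inputs every downstream stage consumes: a gridded depth model
with a shore-normal gradient and a shallow embayment, a latent seabed
structural-complexity field, a substratum truth map, per-sounding 532 nm
return waveforms (surface peak, exponentially decaying water-column return,
skewed benthic pulse) and station photo-quadrats as percent-cover matrices
over 12 biotic and 4 abiotic variables.

The benthic pulse follows a three-stage scenario tied to seabed structural
complexity: over flat ground the return is narrow with an elongated
right-hand tail (positive time-skew); as complexity rises the pulse
broadens its leading edge and loses its tail, ending left-skewed.  The pulse
is a skew-normal shape positioned so that its *mode* sits exactly at
``t_surface + KAPPA_NS_PER_M * depth``.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import skewnorm

from benthoscape.config import BenthoscapeConfig, ConfigurationError, KAPPA_NS_PER_M
from benthoscape.grids import CategoricalRaster, RasterGrid

# Waveform model constants (photo counts / ns).
SURFACE_TIME_NS = 12.0
SURFACE_AMP = 100.0
SURFACE_SIGMA_NS = 1.5
COLUMN_AMP = 12.0
COLUMN_DECAY_PER_NS = 0.1
BASELINE_COUNTS = 2.0
BENTHIC_AMP = 60.0
BENTHIC_ATTENUATION_PER_M = 0.09
BENTHIC_ALPHA_MAX = 5.0       # skew-normal shape at complexity 0 (negated at 1)
BENTHIC_OMEGA_FLAT_NS = 6.0   # pulse scale over flat ground
BENTHIC_OMEGA_COMPLEX_NS = 1.5

SUBSTRATUM_LEGEND = ("Fine sand", "Pebbles", "Cobbles", "Boulders")
#: Complexity thresholds separating the four substratum classes.
SUBSTRATUM_BREAKS = (0.3, 0.55, 0.75)


@dataclass
class Waveform:
    """A time-indexed full-waveform return for one sounding."""

    t0: float
    dt: float
    intensities: np.ndarray
    sounding_id: str = ""
    easting: float = 0.0
    northing: float = 0.0

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 1 or self.intensities.size < 50:
            raise ValueError("waveform needs at least 50 samples")
        if np.any(self.intensities < 0):
            raise ValueError("waveform intensities must be non-negative")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.intensities.size)


@lru_cache(maxsize=1)
def _mode_offset_table() -> tuple[np.ndarray, np.ndarray]:
    alphas = np.linspace(-8.0, 8.0, 321)
    grid = np.linspace(-3.0, 3.0, 60001)
    dens = skewnorm.pdf(grid[None, :], alphas[:, None])
    return alphas, grid[np.argmax(dens, axis=1)]


def _skewnorm_mode_offset(alpha: float) -> float:
    """Mode of the standard skew-normal with shape ``alpha`` (no closed form);
    interpolated from a precomputed table (|error| < 1e-3)."""
    alphas, modes = _mode_offset_table()
    return float(np.interp(alpha, alphas, modes))


def _smooth_noise(shape: tuple[int, int], rng: np.random.Generator, sigma_cells: float) -> np.ndarray:
    """Unit-variance spatially smooth Gaussian field."""
    white = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(white, sigma=sigma_cells, mode="reflect")
    sd = smooth.std()
    return smooth / sd if sd > 0 else smooth


def generate_benthoscape(
    config: BenthoscapeConfig,
) -> tuple[RasterGrid, RasterGrid, CategoricalRaster]:
    """Generate the depth model, complexity field and substratum truth map.

    Depth increases from the shore (row 0, north) seaward, with a shallow
    embayment indenting the central shoreline; by construction each column is
    strictly increasing seaward when ``depth_noise`` is zero.  Structural
    complexity rises with depth (stronger hydrodynamics offshore) and maps to
    the substratum truth classes: soft, flat sediment at low complexity,
    algae-covered boulder fields at high complexity.
    """
    rng = np.random.default_rng(config.seed)
    rows, cols = config.grid_shape
    lo, hi = config.depth_range

    r = np.arange(rows, dtype=float)[:, None]
    c = np.arange(cols, dtype=float)[None, :]
    base = lo + (hi - lo) * (r / max(rows - 1, 1)) ** 1.15

    # Embayment: a smooth shoreline indentation that pulls near-shore depths
    # further below the embayment threshold; monotone along each column.
    c0 = 0.5 * (cols - 1)
    bump = np.exp(-((c - c0) ** 2) / (2 * (0.18 * cols) ** 2))
    decay = np.exp(-r / (0.25 * rows))
    depth = lo + (base - lo) * (1.0 - 0.55 * bump * decay)

    if config.depth_noise > 0:
        depth = depth + config.depth_noise * _smooth_noise((rows, cols), rng, 2.0)
    depth = np.clip(depth, lo, hi)

    z = (depth - lo) / (hi - lo)
    comp = 0.1 + 0.75 * z + 0.35 * _smooth_noise((rows, cols), rng, 3.0)
    comp = np.clip(comp, 0.0, 1.0)

    codes = np.digitize(comp, SUBSTRATUM_BREAKS)
    truth = CategoricalRaster(codes, SUBSTRATUM_LEGEND, cell_size=config.cell_size)
    return (
        RasterGrid(depth, cell_size=config.cell_size),
        RasterGrid(comp, cell_size=config.cell_size),
        truth,
    )


def benthic_pulse_params(complexity: float) -> tuple[float, float]:
    """Skew-normal shape and scale of the benthic pulse for a complexity score."""
    alpha = BENTHIC_ALPHA_MAX * (1.0 - 2.0 * complexity)
    omega = BENTHIC_OMEGA_FLAT_NS + complexity * (BENTHIC_OMEGA_COMPLEX_NS - BENTHIC_OMEGA_FLAT_NS)
    return alpha, omega


def simulate_waveform(
    depth: float,
    complexity: float,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
    dt: float = 1.0,
    reflectance_sd: float = 0.0,
    sounding_id: str = "",
    easting: float = 0.0,
    northing: float = 0.0,
) -> Waveform:
    """Simulate one green-channel return at the given depth and complexity.

    The noiseless trace is the sum of a Gaussian surface peak, an exponential
    water-column decay, a constant baseline and a skew-normal benthic pulse
    whose mode sits at ``SURFACE_TIME_NS + KAPPA_NS_PER_M * depth``.

    ``reflectance_sd`` is the log-scale spread of a per-sounding bottom
    reflectance factor multiplying the benthic amplitude: natural seabeds
    have patchy albedo, so the return's *amplitude* is a poor structural cue
    while its *shape* (spread, skew) tracks complexity.
    """
    if depth < 0:
        raise ValueError(f"depth must be non-negative, got {depth}")
    if not 0.0 <= complexity <= 1.0:
        raise ValueError(f"complexity must lie in [0, 1], got {complexity}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    t_benthic = SURFACE_TIME_NS + KAPPA_NS_PER_M * depth
    t_end = t_benthic + 45.0
    n = max(int(np.ceil(t_end / dt)) + 1, 50)
    t = dt * np.arange(n)

    surface = SURFACE_AMP * np.exp(-((t - SURFACE_TIME_NS) ** 2) / (2 * SURFACE_SIGMA_NS**2))
    past_surface = t > SURFACE_TIME_NS
    column = np.where(
        past_surface,
        COLUMN_AMP * np.exp(-COLUMN_DECAY_PER_NS * (t - SURFACE_TIME_NS)),
        0.0,
    )

    alpha, omega = benthic_pulse_params(complexity)
    loc = t_benthic - omega * _skewnorm_mode_offset(alpha)
    shape = skewnorm.pdf((t - loc) / omega, alpha)
    peak = skewnorm.pdf(_skewnorm_mode_offset(alpha), alpha)
    amp = BENTHIC_AMP * np.exp(-BENTHIC_ATTENUATION_PER_M * depth)
    if reflectance_sd > 0:
        amp *= float(rng.lognormal(0.0, reflectance_sd))
    benthic = amp * shape / peak

    trace = BASELINE_COUNTS + surface + column + benthic
    if noise_sd > 0:
        trace = trace + rng.normal(0.0, noise_sd, size=n)
    trace = np.clip(trace, 0.0, None)
    return Waveform(
        t0=0.0, dt=dt, intensities=trace,
        sounding_id=sounding_id, easting=easting, northing=northing,
    )


def sample_stations(
    depth: RasterGrid,
    complexity: RasterGrid,
    n_stations: int,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Place stations uniformly at random over the grid, one per cell.

    Mirrors a drop-camera survey spread across the whole area without any a
    priori substratum stratification.  Returns a table with station_id,
    easting/northing, cell row/col and the true depth and complexity.
    """
    rows, cols = depth.shape
    n_cells = rows * cols
    if n_stations > n_cells:
        raise ConfigurationError(f"n_stations={n_stations} exceeds {n_cells} grid cells")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    flat = rng.choice(n_cells, size=n_stations, replace=False)
    rr, cc = np.unravel_index(flat, (rows, cols))
    centers = np.array([depth.cell_center(int(i), int(j)) for i, j in zip(rr, cc)])
    return pd.DataFrame(
        {
            "station_id": [f"st{i:03d}" for i in range(n_stations)],
            "easting": centers[:, 0],
            "northing": centers[:, 1],
            "row": rr.astype(int),
            "col": cc.astype(int),
            "depth": depth.values[rr, cc],
            "complexity": complexity.values[rr, cc],
        }
    )


def _suitability(depth: np.ndarray, complexity: np.ndarray, config: BenthoscapeConfig,
                 rng: np.random.Generator) -> np.ndarray:
    lo, hi = config.depth_range
    z = (np.asarray(depth) - lo) / (hi - lo)
    u = config.depth_effect * z + config.complexity_effect * np.asarray(complexity)
    u = u / max(config.depth_effect + config.complexity_effect, 1e-12)
    if config.suitability_noise > 0:
        u = u + rng.normal(0.0, config.suitability_noise, size=np.shape(u))
    return np.clip(u, 0.0, 1.0)


def _quantize_percent(shares: np.ndarray, total: int) -> np.ndarray:
    """Largest-remainder rounding of fractional shares to integer percents."""
    if total <= 0 or shares.sum() <= 0:
        return np.zeros_like(shares, dtype=int)
    raw = shares / shares.sum() * total
    out = np.floor(raw).astype(int)
    rem = raw - out
    short = int(total - out.sum())
    if short > 0:
        order = np.argsort(-rem)
        out[order[:short]] += 1
    return out


def generate_quadrats(stations: pd.DataFrame, config: BenthoscapeConfig,
                      seed: int | np.random.Generator | None = None) -> pd.DataFrame:
    """Score a 100-cell percent-cover quadrat at every station.

    Occurrence of each biotic variable follows a logistic response to a
    habitat-suitability score combining depth and structural complexity;
    covers are allocated with a geometric dominance profile that flattens
    (greater evenness) as suitability rises, so Simpson diversity increases
    with both depth and complexity by construction.  Abiotic covers fill the
    residual image area in proportions tied to the station's substratum.
    All covers are integer percents (the 100-square scoring grid).
    """
    if seed is None:
        seed = config.seed + 1
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_sp = len(config.species_pool)
    u = _suitability(stations["depth"].to_numpy(), stations["complexity"].to_numpy(), config, rng)

    records = np.zeros((len(stations), n_sp + 4), dtype=int)
    centers = np.linspace(0.0, 1.0, n_sp)
    step = 100.0 / config.grid_cells_per_quadrat

    for i, ui in enumerate(u):
        # Logistic occurrence along the suitability gradient: species whose
        # preference centre lies below the local suitability are present.
        p_occ = 1.0 / (1.0 + np.exp(-10.0 * (ui - centers + 0.05)))
        if config.suitability_noise > 0:
            present = rng.random(n_sp) < p_occ
            if not present.any():
                present[int(np.argmax(p_occ))] = True
        else:
            present = p_occ > 0.5
        idx = np.flatnonzero(present)
        order = idx[np.argsort(-p_occ[idx])]

        total_biotic = int(round(np.clip(10.0 + 80.0 * ui, 0.0, 95.0)))
        ratio = 0.15 + 0.85 * ui  # dominance profile: steep at low suitability
        shares = ratio ** np.arange(order.size, dtype=float)
        if config.cover_noise > 0:
            conc = shares / max(config.cover_noise, 1e-9)
            shares = rng.dirichlet(np.maximum(conc, 1e-3))
        covers = _quantize_percent(shares, int(round(total_biotic / step)))
        records[i, order] = covers * int(step)

        if config.layered_cover:
            # Canopy layering: understorey taxa re-counted under macroalgae.
            canopy = rng.random(order.size) < 0.3 * ui
            records[i, order] += (records[i, order] * canopy * rng.uniform(0.5, 1.0)).astype(int)

        residual = max(config.grid_cells_per_quadrat - int(covers.sum()), 0)
        sub = int(stations.iloc[i].get("substratum", min(3, int(ui * 4))))
        w_ab = np.full(4, 0.1)
        w_ab[sub] = 0.7
        records[i, n_sp:] = _quantize_percent(w_ab, residual) * int(step)

    columns = list(config.species_pool) + list(config.abiotic_pool)
    out = pd.DataFrame(records, columns=columns)
    out.insert(0, "station_id", stations["station_id"].to_numpy())
    return out
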