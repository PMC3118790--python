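"""Survey configuration and shared physical constants."""

from __future__ import annotations

from dataclasses import dataclass, asdict

#: Two-way travel time of the 532 nm pulse per metre of water depth, in ns.
#: Light travels at ~0.225 m/ns in seawater; a pulse crossing d metres of
#: water and back spends 2d / 0.225 ~= 8.9 d ns below the surface.  The same
#: constant is used by the simulator (to place the benthic return) and by any
#: consumer converting travel time back to depth.
KAPPA_NS_PER_M: float = 8.9

#: The twelve biotic cover variables scored on each quadrat photograph.
BIOTIC_POOL: tuple[str, ...] = (
    "Crustacea",
    "Echinoidea",
    "Annelida",
    "Gastropoda",
    "Asteroidea",
    "Dead shells",
    "Fucus spp.",
    "Zostera marina",
    "Chondrus crispus",
    "Laminaria spp.",
    "Chorda tomentosa",
    "Polysiphonia spp.",
)

#: The four abiotic (grain-size / substratum) cover variables.
ABIOTIC_POOL: tuple[str, ...] = (
    "Boulders",
    "Cobbles",
    "Pebbles",
    "Fine sand",
)


class ConfigurationError(ValueError):
    """Raised when a survey configuration violates its invariants."""


@dataclass
class BenthoscapeConfig:
    """Parameters of a synthetic nearshore survey.

    The defaults emulate the study conditions of the analysis the package
    reimplements: a 2 m gridded depth model between 2 and 16 m with a
    shallow embayment, 300 photo-quadrat stations of 0.16 m2 scored on a
    100-cell grid over 12 biotic and 4 abiotic variables.
    """

    grid_shape: tuple[int, int] = (60, 80)
    cell_size: float = 2.0
    depth_range: tuple[float, float] = (2.0, 16.0)
    embayment_depth_threshold: float = 6.25
    n_stations: int = 300
    quadrat_area: float = 0.16
    grid_cells_per_quadrat: int = 100
    species_pool: tuple[str, ...] = BIOTIC_POOL
    abiotic_pool: tuple[str, ...] = ABIOTIC_POOL

    # Ecological effect sizes: weights of the (normalized) depth and
    # structural-complexity gradients in the habitat-suitability score that
    # drives richness, abundance and evenness of the simulated quadrats.
    depth_effect: float = 0.5
    complexity_effect: float = 0.5

    # Noise levels.
    suitability_noise: float = 0.08   # sd of noise added to the suitability score
    cover_noise: float = 0.25         # Dirichlet-style jitter of cover allocation
    waveform_noise_sd: float = 0.6    # additive photo-count noise on waveforms
    reflectance_sd: float = 0.6       # log-scale spread of bottom reflectance
    depth_noise: float = 0.15         # small-scale bathymetric roughness, metres

    #: When True, biotic covers may sum above 100% (layered canopies).
    layered_cover: bool = False

    seed: int = 0

    def __post_init__(self) -> None:
        rows, cols = self.grid_shape
        if rows <= 0 or cols <= 0:
            raise ConfigurationError(f"grid_shape must be positive, got {self.grid_shape}")
        lo, hi = self.depth_range
        if not (0 < lo < hi):
            raise ConfigurationError(f"depth_range must be positive and increasing, got {self.depth_range}")
        if self.n_stations < 1:
            raise ConfigurationError("n_stations must be >= 1")
        if len(self.species_pool) != 12:
            raise ConfigurationError("species_pool must have exactly 12 entries")
        if len(self.abiotic_pool) != 4:
            raise ConfigurationError("abiotic_pool must have exactly 4 entries")
        if self.cell_size <= 0:
            raise ConfigurationError("cell_size must be positive")
        if self.quadrat_area <= 0:
            raise ConfigurationError("quadrat_area must be positive")
        if self.grid_cells_per_quadrat < 1:
            raise ConfigurationError("grid_cells_per_quadrat must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        d["depth_range"] = list(self.depth_range)
        d["species_pool"] = list(self.species_pool)
        d["abiotic_pool"] = list(self.abiotic_pool)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "BenthoscapeConfig":
        d = dict(d)
        for key in ("grid_shape", "depth_range", "species_pool", "abiotic_pool"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)
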