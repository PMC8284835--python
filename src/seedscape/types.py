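"""Core data containers shared across the pipeline.

The study design these containers describe: forest patches embedded in a
human-modified tropical landscape, each sampled with N small (1 m^2) seedling
plots; a classified land-cover raster around the patches; and the derived
tables (diversity records, landscape-metric records, scale profiles, model
rankings) that the statistical stages exchange.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Land-cover class codes. Code order follows the classification legend:
#: 1 old-growth forest, 2 secondary forest, 3 floodplain, 4 arboreal crop,
#: 5 cattle pasture, 6 anthropogenic, 7 water.
CLASS_CODES = (1, 2, 3, 4, 5, 6, 7)
CLASS_NAMES = {
    1: "old_growth_forest",
    2: "secondary_forest",
    3: "floodplain",
    4: "arboreal_crop",
    5: "cattle_pasture",
    6: "anthropogenic",
    7: "water",
}

#: Habitat-quality ranking on a seven-point scale (1 = lowest suitability,
#: 7 = highest). Water ranks lowest, old-growth forest highest.
DEFAULT_QUALITY_RANKING = {1: 7, 2: 6, 3: 5, 4: 4, 5: 3, 6: 2, 7: 1}

#: Buffer radii (metres) of the multi-scale assessment: 300..1500 by 100.
DEFAULT_RADII = tuple(range(300, 1600, 100))

#: Class-level landscape metrics computed per buffer.
METRIC_NAMES = ("FC", "SF", "PD", "AI", "PI", "EC")


class SeedscapeError(Exception):
    """Base class for package errors."""


class EmptyCommunityError(SeedscapeError):
    """A community with no individuals/species where one is required."""


class EmptyPlotError(SeedscapeError):
    """A plot with zero individuals; relative abundances are undefined."""


class UnsupportedOrderError(SeedscapeError):
    """Diversity order q outside the supported set {0, 1, 2}."""


class DegeneratePredictorError(SeedscapeError):
    """A regression predictor constant on some calibration split."""


class UndefinedR2Error(SeedscapeError):
    """R^2 undefined because the response has zero variance."""


class ConstraintError(SeedscapeError):
    """Spatial placement constraints cannot be satisfied."""


class BufferError(SeedscapeError):
    """A circular buffer does not fit inside the raster."""


class ConfigError(SeedscapeError):
    """Invalid run or simulation configuration."""


@dataclass(frozen=True)
class LandCoverRaster:
    """Classified land-cover grid.

    Parameters
    ----------
    grid : 2-D integer array of class codes in 1..7, row 0 = northernmost row.
    cell_size : metres per (square) cell edge.
    origin : planar (x, y) of the lower-left corner, metres.
    """

    grid: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid)
        if grid.ndim != 2 or grid.size == 0:
            raise ConfigError("raster grid must be a non-empty 2-D array")
        if self.cell_size <= 0:
            raise ConfigError("cell_size must be positive")
        codes = np.unique(grid)
        if codes.min() < 1 or codes.max() > 7:
            raise ConfigError("raster codes must lie in 1..7")
        object.__setattr__(self, "grid", grid.astype(np.int16, copy=False))

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    @property
    def width_m(self) -> float:
        return self.grid.shape[1] * self.cell_size

    @property
    def height_m(self) -> float:
        return self.grid.shape[0] * self.cell_size

    def cell_centre(self, row: int, col: int) -> tuple[float, float]:
        """Planar coordinates of a cell centre (row 0 is the top row)."""
        x0, y0 = self.origin
        nrows = self.grid.shape[0]
        x = x0 + (col + 0.5) * self.cell_size
        y = y0 + (nrows - row - 0.5) * self.cell_size
        return x, y


@dataclass(frozen=True)
class CommunityBlock:
    """One patch's plots-by-species abundance matrix plus species metadata."""

    patch_id: str
    abundance: np.ndarray  # N plots x S species, non-negative integers
    species_labels: tuple[str, ...]
    dispersal: np.ndarray  # S booleans, True = animal-dispersed
    centre: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        ab = np.asarray(self.abundance)
        if ab.ndim != 2 or ab.shape[0] < 1 or ab.shape[1] < 1:
            raise ConfigError("abundance must be an N x S matrix, N,S >= 1")
        if (ab < 0).any():
            raise ConfigError("abundances must be non-negative")
        if ab.sum() == 0:
            raise EmptyCommunityError(f"patch {self.patch_id}: no individuals")
        disp = np.asarray(self.dispersal, dtype=bool)
        if disp.shape != (ab.shape[1],):
            raise ConfigError("dispersal flags must have one entry per species")
        if len(self.species_labels) != ab.shape[1]:
            raise ConfigError("species_labels must have one entry per species")
        object.__setattr__(self, "abundance", ab.astype(np.int64, copy=False))
        object.__setattr__(self, "dispersal", disp)
        object.__setattr__(self, "species_labels", tuple(self.species_labels))

    @property
    def n_plots(self) -> int:
        return self.abundance.shape[0]

    @property
    def n_species(self) -> int:
        return self.abundance.shape[1]

    def pooled_counts(self) -> np.ndarray:
        """Per-species counts pooled over all plots."""
        return self.abundance.sum(axis=0)


@dataclass(frozen=True)
class DiversityRecord:
    """Hill-number decomposition of one patch at one order q."""

    patch_id: str
    q: int
    gamma: float
    alpha: float
    beta: float
    n_plots: int


@dataclass(frozen=True)
class CoverageRecord:
    """Chao–Shen sample-coverage estimate for one patch's pooled sample."""

    patch_id: str
    coverage: float
    n: int
    f1: int
    f2: int


@dataclass(frozen=True)
class MetricRecord:
    """One class-level landscape metric at one radius around one patch."""

    patch_id: str
    radius_m: float
    metric: str
    value: float  # NaN encodes "missing" (e.g. PI with < 2 patches)


@dataclass
class ScaleProfile:
    """Cross-validated fit of one predictor to one response across radii."""

    response: str
    predictor: str
    r2cv: dict[float, float]  # radius -> R^2_CV (NaN if that radius invalid)
    n_effective: dict[float, int]  # radius -> patches used
    selected_radius: float
    n: int

    def valid_radii(self) -> list[float]:
        return [r for r, v in self.r2cv.items() if np.isfinite(v)]


@dataclass
class BootstrapScaleResult:
    """Bootstrap distribution of the selected scale of effect."""

    response: str
    predictor: str
    counts: dict[float, int]
    B: int
    mean_radius: float
    sd_radius: float
    seed: int

    @property
    def modal_radius(self) -> float:
        best = max(self.counts.values())
        return min(r for r, c in self.counts.items() if c == best)


@dataclass
class CandidateModel:
    """One candidate in the all-subsets AICc ranking."""

    terms: tuple[str, ...]
    k: int = 0
    loglik: float = float("nan")
    aicc: float = float("nan")
    delta: float = float("nan")
    weight: float = float("nan")
    coef: dict[str, float] = field(default_factory=dict)
    se: dict[str, float] = field(default_factory=dict)
    best_supported: bool = False  # delta AICc < 2


@dataclass(frozen=True)
class AveragedEstimate:
    """Model-averaged coefficient with unconditional SE and importance."""

    term: str
    coefficient: float
    use: float
    importance: float
    influential: bool


@dataclass(frozen=True)
class GlobalModelSpec:
    """A response with its predictor terms fixed at selected radii."""

    response: str
    terms: tuple[tuple[str, float], ...]  # (metric name, radius_m)

    def term_names(self) -> tuple[str, ...]:
        return tuple(f"{m}_{int(r)}" for m, r in self.terms)
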