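"""Geometric-constraint null model for range-limit shifts on bounded gradients.

On a gradient surveyed between ``min`` and ``max`` elevation, an observed
shift ``d`` can only be seen from initial upper limits ``e`` with
``min <= e + d <= max``: large upward shifts are observable only from low
initial limits and vice versa. Combined with regression toward the mean,
this makes a negative shift-vs-initial-limit relationship the default
expectation even for purely random shifts. The null model therefore keeps
each species' observed (shift, weight) pair and re-places it at a random
initial elevation drawn uniformly (with replacement) from a candidate vector
truncated to the feasible set. Each of ``n_boot`` replicates is refitted
with the same weighted regression as the observed data; pointwise quantiles
of the replicate fitted values on a fixed elevation grid form the null
envelope, and observed fitted values outside it indicate elevation-dependent
shifts beyond the geometric constraint.

Candidate vectors come in three variants: the surveyed transect elevations
(~60 per region; the default), a 200-point equally spaced grid (less
conservative, narrower envelopes) and the species' own observed initial
limits (more conservative, wider envelopes).
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np

from .limits import SpeciesRangeRecord
from .survey import SurveyDesign
from .wls import WeightedFit, batch_fitted_values, weighted_least_squares

VARIANTS = ("surveyed", "grid200", "observed_initials")


@dataclass(frozen=True)
class NullConfig:
    """Settings of one null-model run."""

    variant: str = "surveyed"
    n_boot: int = 10_000
    confidence: float = 0.95
    seed: int = 0
    bounds: tuple[float, float] | None = None  # default: the region's gradient bounds
    grid_points: int = 100  # evaluation grid for fitted values

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; use one of {VARIANTS}")
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if not 0.0 < self.confidence < 1.0:
            raise ValueError("confidence must lie in (0, 1)")


@dataclass
class NullEnvelope:
    """Pointwise null bounds on regression fitted values."""

    grid: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    mean_expected: np.ndarray
    slopes: np.ndarray = field(repr=False)  # per-replicate slope
    config: NullConfig | None = None

    def __post_init__(self) -> None:
        if np.any(self.lower > self.upper + 1e-12):
            raise ValueError("envelope lower bound exceeds upper bound")

    @property
    def mean_slope(self) -> float:
        return float(np.mean(self.slopes))


@dataclass
class NullComparison:
    """Observed regression vs null envelope on the shared grid."""

    prop_above: float
    prop_below: float
    significant: bool
    above_ranges: list[tuple[float, float]]
    below_ranges: list[tuple[float, float]]


def region_rng(seed: int, region: str) -> np.random.Generator:
    """Reproducible per-region RNG substream.

    Derived from (master seed, CRC32 of the region name), so adding or
    removing one region never changes another region's draws.
    """
    return np.random.default_rng([int(seed), zlib.crc32(region.encode("utf8"))])


def candidate_elevations(
    config: NullConfig,
    design: SurveyDesign | None,
    records: list[SpeciesRangeRecord],
    region: str | None = None,
) -> np.ndarray:
    """The candidate vector of initial elevations for one region."""
    region = region or (records[0].region if records else None)
    if config.variant == "surveyed":
        if design is None:
            raise ValueError("variant 'surveyed' needs a SurveyDesign")
        return design[region].elevations
    bounds = config.bounds or (design[region].bounds if design is not None else None)
    if config.variant == "grid200":
        if bounds is None:
            raise ValueError("variant 'grid200' needs gradient bounds")
        return np.linspace(bounds[0], bounds[1], 200)
    # observed_initials
    return np.array([r.limit_t1 for r in records], dtype=float)


def truncate_candidates(candidates, shift: float, bounds: tuple[float, float]) -> np.ndarray:
    """Feasible initial elevations for one shift: min <= e + shift <= max.

    Upward shifts truncate the top of the candidate vector (e <= max - shift),
    downward shifts the bottom (e >= min - shift, i.e. min + |shift|).
    """
    lo, hi = bounds
    if not lo < hi:
        raise ValueError(f"invalid bounds {bounds}")
    arr = np.asarray(candidates, dtype=float)
    out = arr[(arr + shift >= lo - 1e-9) & (arr + shift <= hi + 1e-9)]
    if out.size == 0:
        raise ValueError(
            f"no feasible initial elevation for shift {shift} within bounds {bounds}"
        )
    return out


def resample_placements(
    records: list[SpeciesRangeRecord],
    candidates,
    bounds: tuple[float, float],
    rng: np.random.Generator,
    size: int = 1,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Randomize initial elevations, keeping each (shift, weight) pair intact.

    Returns ``(initials, shifts, weights)`` with ``initials`` of shape
    (n_species, size): one column per replicate, drawn uniformly with
    replacement from each species' truncated candidate set.
    """
    shifts = np.array([r.shift for r in records])
    weights = np.array([r.weight for r in records], dtype=float)
    initials = np.empty((len(records), size))
    for i, d in enumerate(shifts):
        feasible = truncate_candidates(candidates, d, bounds)
        initials[i] = feasible[rng.integers(0, feasible.size, size=size)]
    return initials, shifts, weights


def build_envelope(
    records: list[SpeciesRangeRecord],
    config: NullConfig,
    design: SurveyDesign | None = None,
    region: str | None = None,
    rng: np.random.Generator | None = None,
) -> NullEnvelope:
    """Null envelope of weighted-regression fitted values for one region."""
    if len(records) < 3:
        raise ValueError("build_envelope needs at least three species")
    if config.n_boot < 100:
        warnings.warn(
            f"n_boot={config.n_boot} gives unstable envelope quantiles", RuntimeWarning,
            stacklevel=2,
        )
    region = region or records[0].region
    bounds = config.bounds or (design[region].bounds if design is not None else None)
    if bounds is None:
        raise ValueError("gradient bounds required (config.bounds or a SurveyDesign)")
    if rng is None:
        rng = region_rng(config.seed, region)

    candidates = candidate_elevations(config, design, records, region)
    initials, shifts, weights = resample_placements(
        records, candidates, bounds, rng, size=config.n_boot
    )
    grid = np.linspace(bounds[0], bounds[1], config.grid_points)
    fitted, slopes = batch_fitted_values(initials, shifts, weights, grid)
    alpha = 1.0 - config.confidence
    lower = np.quantile(fitted, alpha / 2, axis=1)
    upper = np.quantile(fitted, 1.0 - alpha / 2, axis=1)
    return NullEnvelope(
        grid=grid,
        lower=lower,
        upper=upper,
        mean_expected=fitted.mean(axis=1),
        slopes=slopes,
        config=config,
    )


def _ranges(grid: np.ndarray, mask: np.ndarray) -> list[tuple[float, float]]:
    """Contiguous grid intervals where ``mask`` holds."""
    ranges = []
    start = None
    for i, m in enumerate(mask):
        if m and start is None:
            start = i
        elif not m and start is not None:
            ranges.append((float(grid[start]), float(grid[i - 1])))
            start = None
    if start is not None:
        ranges.append((float(grid[start]), float(grid[-1])))
    return ranges


def compare_to_null(observed_fit: WeightedFit, envelope: NullEnvelope) -> NullComparison:
    """Fractions of the observed regression line outside the null envelope.

    Any non-zero fraction flags a significant deviation from the null (the
    original decision rule). The comparison is pointwise on the shared grid,
    hence anticonservative as a familywise test — interpret the exceedance
    ranges alongside the flag.
    """
    observed = observed_fit.predict(envelope.grid)
    above = observed > envelope.upper
    below = observed < envelope.lower
    return NullComparison(
        prop_above=float(above.mean()),
        prop_below=float(below.mean()),
        significant=bool(above.any() or below.any()),
        above_ranges=_ranges(envelope.grid, above),
        below_ranges=_ranges(envelope.grid, below),
    )


def observed_fit_for_region(records: list[SpeciesRangeRecord]) -> WeightedFit:
    """The observed weighted regression of shift on initial limit."""
    x = np.array([r.limit_t1 for r in records])
    y = np.array([r.shift for r in records])
    w = np.array([r.weight for r in records], dtype=float)
    return weighted_least_squares(x, y, w, with_slope=True)
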