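"""Upper elevational range limits, their shifts between surveys, and
within-region elevation standardization.

A species' upper limit in one survey wave is the 90th percentile of the
elevations of its occupied transects (linear interpolation between order
statistics). The percentile tracks the highest occurrence when a species is
scarce but damps single outlier occurrences when it is common, making limit
shifts conservative. Shifts are last-survey limit minus first-survey limit
(positive = upslope) and may be annualized by the survey interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .survey import PresenceTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SpeciesRangeRecord:
    """Upper-limit shift of one species in one region between two surveys.

    ``weight`` is the species' total frequency of occurrence (occupied
    transects) across the first and last survey; shift regressions weight
    observations by it, on the premise that limits of common species are less
    outlier-driven than those of rare species.
    """

    species: str
    region: str
    limit_t1: float
    limit_tlast: float
    shift: float
    annual_shift: float
    freq_t1: int
    freq_tlast: int
    weight: int

    def __post_init__(self) -> None:
        if abs(self.shift - (self.limit_tlast - self.limit_t1)) > 1e-9:
            raise ValueError("shift must equal limit_tlast - limit_t1")
        if self.weight != self.freq_t1 + self.freq_tlast or self.weight < 2:
            raise ValueError("weight must be freq_t1 + freq_tlast >= 2")


def upper_limit(occupied_elevations, q: float = 0.9) -> float:
    """Upper range limit: interpolated ``q``-quantile of occupied elevations.

    Uses linear interpolation between order statistics (R type-7 / numpy
    ``linear``); with a single occupied transect the limit is that elevation.
    """
    arr = np.asarray(occupied_elevations, dtype=float)
    if arr.size == 0:
        raise ValueError("upper_limit needs at least one occupied elevation")
    if not np.all(np.isfinite(arr)):
        raise ValueError("occupied elevations must be finite")
    return float(np.quantile(arr, q, method="linear"))


def compute_shifts(
    first: PresenceTable,
    last: PresenceTable,
    interval_years: float,
    q: float = 0.9,
) -> list[SpeciesRangeRecord]:
    """Upper-limit shifts for species present in both the first and last survey.

    Species absent in either wave cannot have a shift and are omitted (logged).
    """
    if first.region != last.region:
        raise ValueError(f"region mismatch: {first.region!r} vs {last.region!r}")
    if interval_years <= 0:
        raise ValueError("interval_years must be positive")

    sp_first, sp_last = set(first.species), set(last.species)
    shared = sorted(sp_first & sp_last)
    skipped = sorted(sp_first ^ sp_last)
    if skipped:
        logger.info(
            "%s: %d species present in only one of the surveys omitted from shift analysis",
            first.region,
            len(skipped),
        )

    records = []
    for sp in shared:
        lim1 = upper_limit(first.occupied_elevations(sp), q=q)
        lim2 = upper_limit(last.occupied_elevations(sp), q=q)
        f1, f2 = first.frequency(sp), last.frequency(sp)
        records.append(
            SpeciesRangeRecord(
                species=sp,
                region=first.region,
                limit_t1=lim1,
                limit_tlast=lim2,
                shift=lim2 - lim1,
                annual_shift=(lim2 - lim1) / interval_years,
                freq_t1=f1,
                freq_tlast=f2,
                weight=f1 + f2,
            )
        )
    return records


def records_frame(records) -> pd.DataFrame:
    """Tabulate range records (the per-species supplementary-table shape)."""
    return pd.DataFrame(
        [
            {
                "region": r.region,
                "species": r.species,
                "limit_t1": r.limit_t1,
                "limit_tlast": r.limit_tlast,
                "shift": r.shift,
                "annual_shift": r.annual_shift,
                "freq_t1": r.freq_t1,
                "freq_tlast": r.freq_tlast,
                "weight": r.weight,
            }
            for r in records
        ]
    )


@dataclass(frozen=True)
class ElevationStandardizer:
    """Within-region centring/scaling of elevations (mean 0, s.d. 1).

    Puts regions with very different gradient extents on a common scale for
    cross-region models.
    """

    region: str
    center: float
    scale: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.scale) and self.scale > 0):
            raise ValueError(f"scale must be positive, got {self.scale}")

    def transform(self, x) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.center) / self.scale

    def inverse(self, z) -> np.ndarray:
        return np.asarray(z, dtype=float) * self.scale + self.center


def standardize(values, region: str) -> tuple[np.ndarray, ElevationStandardizer]:
    """Centre and scale ``values`` (sample s.d., ddof=1) within a region."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("standardize needs at least two values")
    sd = float(np.std(arr, ddof=1))
    if sd == 0.0:
        raise ValueError(f"zero variance in region {region!r}: cannot standardize")
    std = ElevationStandardizer(region=region, center=float(np.mean(arr)), scale=sd)
    return std.transform(arr), std
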