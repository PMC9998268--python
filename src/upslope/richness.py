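"""Regional non-native species richness per survey wave and its trend.

Richness is counted per region and survey year from the singleton-filtered
presence tables; the trend over years-since-first-survey (0, 5, 10) is
tested with a random-intercept mixed model against its intercept-only null
via a likelihood ratio test, and the same on percentage change in richness
with the fixed intercept constrained to zero (percent change is structurally
zero in the first survey year).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import lmm


@dataclass(frozen=True)
class RichnessRecord:
    region: str
    year_since_first: int
    richness: int
    percent_change: float

    def __post_init__(self) -> None:
        if self.richness < 0:
            raise ValueError("richness must be non-negative")
        if self.year_since_first == 0 and self.percent_change != 0.0:
            raise ValueError("percent change must be zero in the first survey year")


@dataclass
class TrendTest:
    """Slope of a mixed-model richness trend with its likelihood-ratio test."""

    slope: float
    se: float
    chi2: float
    p: float
    n: int
    n_regions: int
    region_variance: float
    residual_variance: float
    singular: bool  # random-intercept variance estimated at the boundary


def richness_table(tables) -> list[RichnessRecord]:
    """Richness and percent change per region and survey wave.

    ``tables`` maps (region, year) -> PresenceTable (already filtered). Years
    are re-expressed as years since each region's first survey.
    """
    regions = sorted({region for region, _ in tables})
    out: list[RichnessRecord] = []
    for region in regions:
        years = sorted(year for reg, year in tables if reg == region)
        if len(years) < 2:
            raise ValueError(f"region {region!r} has a single survey wave; no trend defined")
        base = None
        for year in years:
            richness = len(tables[(region, year)].species)
            if base is None:
                base = richness
            if base == 0:
                raise ValueError(f"region {region!r} has zero richness in its first survey")
            pct = 100.0 * (richness - base) / base
            out.append(
                RichnessRecord(
                    region=region,
                    year_since_first=year - years[0],
                    richness=richness,
                    percent_change=pct if year != years[0] else 0.0,
                )
            )
    return out


def richness_frame(records: list[RichnessRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "region": r.region,
                "year_since_first": r.year_since_first,
                "richness": r.richness,
                "percent_change": r.percent_change,
            }
            for r in records
        ]
    )


def _trend(records: list[RichnessRecord], response: str, zero_intercept: bool) -> TrendTest:
    df = richness_frame(records)
    if df["region"].nunique() < 2:
        raise ValueError("trend tests need at least two regions")
    if (df.groupby("region")["year_since_first"].nunique() < 2).any():
        raise ValueError("every region needs at least two survey waves")
    y = df[response].to_numpy(dtype=float)
    year = df["year_since_first"].to_numpy(dtype=float)
    groups = df["region"].to_numpy()

    if zero_intercept:
        X_full, X_null = year[:, None], None
        slope_idx = 0
    else:
        X_full = np.column_stack([np.ones(len(df)), year])
        X_null = np.ones((len(df), 1))
        slope_idx = 1

    reml_fit = lmm.fit_random_intercept(y, X_full, groups, reml=True)
    ml_full = lmm.fit_random_intercept(y, X_full, groups, reml=False)
    ml_null = lmm.fit_random_intercept(y, X_null, groups, reml=False)
    chi2, _, p = lmm.likelihood_ratio_test(ml_full, ml_null)
    return TrendTest(
        slope=float(reml_fit.beta[slope_idx]),
        se=float(reml_fit.se[slope_idx]),
        chi2=chi2,
        p=p,
        n=reml_fit.n,
        n_regions=reml_fit.n_groups,
        region_variance=reml_fit.tau2,
        residual_variance=reml_fit.sigma2,
        singular=reml_fit.tau2 == 0.0,
    )


def richness_trend_test(records: list[RichnessRecord]) -> TrendTest:
    """Trend in richness (species/year): slope, s.e. and ML likelihood-ratio test."""
    return _trend(records, "richness", zero_intercept=False)


def percent_trend_test(records: list[RichnessRecord]) -> TrendTest:
    """Trend in percent change of richness (%/year), fixed intercept set to zero."""
    return _trend(records, "percent_change", zero_intercept=True)
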