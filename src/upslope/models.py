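"""Frequency-weighted regressions of upper range-limit shifts.

Per region: intercept-only weighted fits (grand mean shift), shift-vs-initial-
elevation slope fits, and elevation-corrected mean shifts (the fit evaluated
at the gradient median, so a positive value means upslope shifts across most
of the gradient). Across regions: random-intercept mixed models on
within-region standardized limits.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import lmm
from .limits import SpeciesRangeRecord, records_frame
from .wls import WeightedFit, weighted_least_squares

logger = logging.getLogger(__name__)


@dataclass
class MixedFit:
    """Cross-region mixed-model summary for one fixed-effect coefficient."""

    estimate: float
    se: float
    t: float
    df: float  # Satterthwaite-style approximate denominator df
    p: float
    region_variance: float
    residual_variance: float
    n: int
    n_regions: int
    slope: float | None = None  # set for elevation-dependence models
    slope_se: float | None = None
    slope_t: float | None = None
    slope_df: float | None = None
    slope_p: float | None = None
    f_statistic: float | None = None
    fit: object = field(default=None, repr=False)


def _arrays(records: list[SpeciesRangeRecord], annualize: bool):
    shifts = np.array([r.annual_shift if annualize else r.shift for r in records])
    x = np.array([r.limit_t1 for r in records])
    w = np.array([r.weight for r in records], dtype=float)
    return x, shifts, w


def mean_shift(
    records: list[SpeciesRangeRecord],
    annualize: bool = False,
    confidence: float = 0.95,
) -> tuple[float, tuple[float, float], WeightedFit]:
    """Grand mean shift of one region: intercept-only weighted fit with CI.

    The estimate is the frequency-weighted mean of the species' shifts (in
    meters, or meters/year when ``annualize``); the CI is the t-based
    confidence interval on the intercept.
    """
    if len(records) < 2:
        raise ValueError("mean_shift needs at least two species")
    x, y, w = _arrays(records, annualize)
    fit = weighted_least_squares(x, y, w, with_slope=False)
    est, lo, hi = fit.predict_interval(0.0, confidence)
    return float(est[0]), (float(lo[0]), float(hi[0])), fit


def elevation_corrected_shift(
    records: list[SpeciesRangeRecord],
    x_eval: float,
    bounds: tuple[float, float] | None = None,
    annualize: bool = False,
    confidence: float = 0.95,
) -> tuple[float, tuple[float, float], WeightedFit]:
    """Mean shift corrected for elevation dependence.

    Fits shift ~ initial limit (weighted) within one region and predicts the
    mean shift at ``x_eval`` — by default callers pass the median elevation of
    the region's surveyed gradient. A value significantly above zero indicates
    upslope shifts across most of the gradient.
    """
    if len(records) < 3:
        raise ValueError("elevation_corrected_shift needs at least three species")
    if bounds is not None and not (bounds[0] <= x_eval <= bounds[1]):
        warnings.warn(
            f"x_eval {x_eval} outside gradient bounds {bounds}", RuntimeWarning, stacklevel=2
        )
    x, y, w = _arrays(records, annualize)
    fit = weighted_least_squares(x, y, w, with_slope=True)
    est, lo, hi = fit.predict_interval(x_eval, confidence)
    return float(est[0]), (float(lo[0]), float(hi[0])), fit


def _standardized_frame(records: list[SpeciesRangeRecord], standardizers=None) -> pd.DataFrame:
    """Shift table with limits standardized within region.

    ``standardizers`` maps region -> ElevationStandardizer (fitted on the
    surveyed gradient); without one, moments of the species' own initial
    limits are used.
    """
    df = records_frame(records)
    out = []
    for region, sub in df.groupby("region"):
        sub = sub.copy()
        if standardizers and region in standardizers:
            std = standardizers[region]
            center, scale = std.center, std.scale
        else:
            center = sub["limit_t1"].mean()
            scale = sub["limit_t1"].std(ddof=1)
            if not np.isfinite(scale) or scale == 0:
                raise ValueError(f"cannot standardize region {region!r}: zero variance")
        sub["z_limit_t1"] = (sub["limit_t1"] - center) / scale
        sub["z_shift"] = sub["shift"] / scale
        out.append(sub)
    return pd.concat(out, ignore_index=True)


def cross_region_mean_shift(
    records: list[SpeciesRangeRecord],
    standardized: bool = True,
    standardizers=None,
) -> MixedFit:
    """Overall shift across regions: weighted intercept-only LMM, region random.

    With standardization the response is shift / region scale, making regions
    with very different gradient extents comparable. Degenerates to the
    weighted mean for a single region (with a warning).
    """
    df = (
        _standardized_frame(records, standardizers)
        if standardized
        else records_frame(records).assign(z_shift=lambda d: d["shift"])
    )
    regions = df["region"].unique()
    if len(regions) < 2:
        warnings.warn(
            "single region: cross_region_mean_shift falls back to the weighted mean",
            RuntimeWarning,
            stacklevel=2,
        )
        est, (lo, hi), fit = mean_shift(records)
        scale = 1.0
        if standardized:
            region = records[0].region
            if standardizers and region in standardizers:
                scale = standardizers[region].scale
            else:
                scale = float(np.std([r.limit_t1 for r in records], ddof=1)) or 1.0
        return MixedFit(
            estimate=est / scale,
            se=fit.se_intercept / scale,
            t=est / fit.se_intercept if fit.se_intercept else np.nan,
            df=float(fit.df_resid),
            p=np.nan,
            region_variance=0.0,
            residual_variance=fit.sigma2 / scale**2,
            n=fit.n,
            n_regions=1,
            fit=fit,
        )

    y = df["z_shift"].to_numpy()
    X = np.ones((len(df), 1))
    fit = lmm.fit_random_intercept(
        y, X, df["region"].to_numpy(), weights=df["weight"].to_numpy(), reml=True,
        names=["intercept"],
    )
    row = fit.summary_row(0)
    return MixedFit(
        estimate=row["estimate"],
        se=row["se"],
        t=row["t"],
        df=row["df"],
        p=row["p"],
        region_variance=fit.tau2,
        residual_variance=fit.sigma2,
        n=fit.n,
        n_regions=fit.n_groups,
        fit=fit,
    )


def elevation_dependence(
    records: list[SpeciesRangeRecord],
    standardizers=None,
    min_species: int = 3,
) -> tuple[MixedFit, pd.DataFrame]:
    """Cross-region elevation dependence of shifts plus per-region slope fits.

    The mixed model regresses shift on the initial limit (both standardized
    within region), weighted by frequency, with a region random intercept; a
    negative slope means larger upslope shifts for species starting lower.
    Per-region weighted (and unweighted, for comparison) slope fits are
    returned as a table; regions below ``min_species`` are skipped and listed.
    """
    df = _standardized_frame(records, standardizers)
    regions = df["region"].unique()
    if len(regions) < 2:
        raise ValueError("elevation_dependence needs at least two regions")

    y = df["z_shift"].to_numpy()
    X = np.column_stack([np.ones(len(df)), df["z_limit_t1"].to_numpy()])
    fit = lmm.fit_random_intercept(
        y, X, df["region"].to_numpy(), weights=df["weight"].to_numpy(), reml=True,
        names=["intercept", "z_limit_t1"],
    )
    irow, srow = fit.summary_row(0), fit.summary_row(1)
    mixed = MixedFit(
        estimate=irow["estimate"],
        se=irow["se"],
        t=irow["t"],
        df=irow["df"],
        p=irow["p"],
        region_variance=fit.tau2,
        residual_variance=fit.sigma2,
        n=fit.n,
        n_regions=fit.n_groups,
        slope=srow["estimate"],
        slope_se=srow["se"],
        slope_t=srow["t"],
        slope_df=srow["df"],
        slope_p=srow["p"],
        f_statistic=srow["t"] ** 2,
        fit=fit,
    )

    rows = []
    by_region: dict[str, list[SpeciesRangeRecord]] = {}
    for r in records:
        by_region.setdefault(r.region, []).append(r)
    for region in sorted(by_region):
        recs = by_region[region]
        if len(recs) < min_species:
            logger.warning("region %s skipped: only %d species (< %d)", region, len(recs), min_species)
            rows.append({"region": region, "n": len(recs), "skipped": True})
            continue
        x, yv, w = _arrays(recs, annualize=False)
        wfit = weighted_least_squares(x, yv, w, with_slope=True)
        ufit = weighted_least_squares(x, yv, None, with_slope=True)
        from scipy import stats as _st

        t_w = wfit.slope / wfit.se_slope if wfit.se_slope > 0 else np.inf
        rows.append(
            {
                "region": region,
                "n": len(recs),
                "skipped": False,
                "slope": wfit.slope,
                "slope_se": wfit.se_slope,
                "slope_p": 2 * _st.t.sf(abs(t_w), wfit.df_resid),
                "slope_unweighted": ufit.slope,
                "intercept": wfit.intercept,
            }
        )
    return mixed, pd.DataFrame(rows)
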