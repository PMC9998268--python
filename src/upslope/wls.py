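"""Closed-form weighted least squares for shift-vs-elevation regressions.

The fit minimizes sum(w_i * (y_i - a - b x_i)^2) via the weighted normal
equations. It is deliberately a small closed-form implementation: the null
model refits the same two-parameter regression tens of thousands of times
per region, which :func:`batch_fitted_values` vectorizes across replicates.
Standard errors, residual variance and confidence intervals follow the usual
linear-model conventions (variance estimate RSS_w / (n - p), t-based CIs on
the mean response), so with all weights equal the result coincides with
ordinary least squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats


@dataclass
class WeightedFit:
    """A fitted weighted linear regression y ~ a + b*x (or intercept-only)."""

    intercept: float
    slope: float | None  # None for intercept-only fits
    se_intercept: float
    se_slope: float | None
    sigma2: float  # weighted residual variance RSS_w / (n - p)
    n: int
    x: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)
    weights: np.ndarray = field(repr=False)
    cov: np.ndarray = field(repr=False)  # covariance of (intercept[, slope])

    @property
    def df_resid(self) -> int:
        return self.n - (1 if self.slope is None else 2)

    @property
    def fitted(self) -> np.ndarray:
        return self.predict(self.x)

    def predict(self, x0) -> np.ndarray:
        x0 = np.asarray(x0, dtype=float)
        if self.slope is None:
            return np.full_like(x0, self.intercept)
        return self.intercept + self.slope * x0

    def predict_interval(self, x0, confidence: float = 0.95):
        """Mean-response estimate with pointwise t-based confidence bounds."""
        x0 = np.atleast_1d(np.asarray(x0, dtype=float))
        est = self.predict(x0)
        if self.slope is None:
            var = np.full_like(x0, self.cov[0, 0])
        else:
            # var(a + b x0) = var(a) + x0^2 var(b) + 2 x0 cov(a, b)
            var = self.cov[0, 0] + x0**2 * self.cov[1, 1] + 2 * x0 * self.cov[0, 1]
        se = np.sqrt(np.maximum(var, 0.0))
        tcrit = stats.t.ppf(0.5 + confidence / 2, self.df_resid)
        return est, est - tcrit * se, est + tcrit * se


def weighted_least_squares(x, y, w=None, with_slope: bool = True) -> WeightedFit:
    """Fit y ~ a (+ b*x) by weighted least squares (closed form).

    ``with_slope=False`` gives the intercept-only model whose intercept is the
    weighted mean of ``y`` — the per-region "grand mean shift" model.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float) if x is not None else np.zeros_like(y)
    n = y.size
    if x.size != n:
        raise ValueError("x and y must have equal length")
    w = np.ones(n) if w is None else np.asarray(w, dtype=float)
    if w.size != n:
        raise ValueError("weights must match data length")
    if np.any(w <= 0) or not np.all(np.isfinite(w)):
        raise ValueError("weights must be positive and finite")

    p = 2 if with_slope else 1
    if n < p + 1:
        raise ValueError(f"need at least {p + 1} observations, got {n}")

    sw = w.sum()
    if with_slope:
        xbar = (w * x).sum() / sw
        sxx = (w * (x - xbar) ** 2).sum()
        if sxx <= 0:
            raise ValueError("degenerate predictor: all x equal")
        ybar = (w * y).sum() / sw
        slope = (w * (x - xbar) * (y - ybar)).sum() / sxx
        intercept = ybar - slope * xbar
        resid = y - intercept - slope * x
        sigma2 = (w * resid**2).sum() / (n - 2)
        # (X' W X)^{-1} for X = [1, x]
        cov = sigma2 * np.array(
            [[1.0 / sw + xbar**2 / sxx, -xbar / sxx], [-xbar / sxx, 1.0 / sxx]]
        )
        return WeightedFit(
            intercept=float(intercept),
            slope=float(slope),
            se_intercept=float(np.sqrt(cov[0, 0])),
            se_slope=float(np.sqrt(cov[1, 1])),
            sigma2=float(sigma2),
            n=n,
            x=x,
            y=y,
            weights=w,
            cov=cov,
        )

    intercept = (w * y).sum() / sw
    resid = y - intercept
    sigma2 = (w * resid**2).sum() / (n - 1)
    cov = np.array([[sigma2 / sw]])
    return WeightedFit(
        intercept=float(intercept),
        slope=None,
        se_intercept=float(np.sqrt(cov[0, 0])),
        se_slope=None,
        sigma2=float(sigma2),
        n=n,
        x=x,
        y=y,
        weights=w,
        cov=cov,
    )


def batch_fitted_values(x: np.ndarray, y: np.ndarray, w: np.ndarray, grid: np.ndarray):
    """Fitted values of many weighted regressions evaluated on a common grid.

    ``x`` has shape (n_obs, n_fits): each column is one replicate's predictor
    vector; ``y`` and ``w`` (shape (n_obs,)) are shared across replicates, as
    in the null model where only initial elevations are randomized. Returns
    ``(fitted, slopes)`` with ``fitted`` of shape (len(grid), n_fits).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)[:, None]
    w = np.asarray(w, dtype=float)[:, None]
    sw = w.sum()
    swx = (w * x).sum(axis=0)
    swy = float((w * y).sum())
    swxx = (w * x * x).sum(axis=0)
    swxy = (w * x * y).sum(axis=0)
    denom = sw * swxx - swx**2
    slopes = (sw * swxy - swx * swy) / denom
    intercepts = (swy - slopes * swx) / sw
    fitted = intercepts[None, :] + np.asarray(grid, dtype=float)[:, None] * slopes[None, :]
    return fitted, slopes
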