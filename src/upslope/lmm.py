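"""Random-intercept linear mixed models with case weights.

Model: y = X beta + b[group] + e, with b_g ~ N(0, tau^2) and
e_i ~ N(0, sigma^2 / w_i). The weights act on the residual variance (the
convention of R's ``lmer(weights=...)``), which is how shift regressions
down-weight rare species. Estimation profiles beta and sigma^2 out of the
(restricted) likelihood and optimizes the single variance ratio
lambda = tau^2/sigma^2 numerically; every per-group solve uses the
Sherman-Morrison identity on diag(1/w) + lambda * 11', so fits are O(n).

REML is used for reported estimates, plain ML when nested models are
compared by likelihood ratio. Degrees of freedom for t tests are
Satterthwaite approximations obtained from the finite-difference information
matrix of the restricted likelihood in (sigma^2, tau^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = ["LMMFit", "fit_random_intercept", "likelihood_ratio_test"]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class LMMFit:
    """A fitted random-intercept model."""

    beta: np.ndarray
    se: np.ndarray
    sigma2: float  # residual variance (for unit weight)
    tau2: float  # between-group (random intercept) variance
    loglik: float  # maximized log-likelihood (restricted if reml)
    reml: bool
    df: np.ndarray  # Satterthwaite df per coefficient
    n: int
    n_groups: int
    names: list[str] = field(default_factory=list)

    @property
    def tvalues(self) -> np.ndarray:
        return self.beta / self.se

    @property
    def pvalues(self) -> np.ndarray:
        return 2.0 * stats.t.sf(np.abs(self.tvalues), self.df)

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        tcrit = stats.t.ppf(1.0 - alpha / 2.0, self.df)
        return np.column_stack([self.beta - tcrit * self.se, self.beta + tcrit * self.se])

    def summary_row(self, j: int = 0) -> dict:
        return {
            "estimate": float(self.beta[j]),
            "se": float(self.se[j]),
            "t": float(self.tvalues[j]),
            "df": float(self.df[j]),
            "p": float(self.pvalues[j]),
            "sigma2": self.sigma2,
            "tau2": self.tau2,
        }


def _split_groups(X, y, w, groups):
    order = np.argsort(groups, kind="stable")
    Xo, yo, wo, go = X[order], y[order], w[order], np.asarray(groups)[order]
    _, starts = np.unique(go, return_index=True)
    bounds = list(starts) + [len(yo)]
    return [
        (Xo[bounds[i] : bounds[i + 1]], yo[bounds[i] : bounds[i + 1]], wo[bounds[i] : bounds[i + 1]])
        for i in range(len(bounds) - 1)
    ]


def _profiled_pieces(blocks, lam):
    """Per-group GLS accumulators for V* = diag(1/w) + lam * 11'.

    Returns (A, c, yty, logdet) with A = sum X'V*^-1 X, c = sum X'V*^-1 y,
    yty = sum y'V*^-1 y and logdet = sum log|V*_g|.
    """
    p = blocks[0][0].shape[1]
    A = np.zeros((p, p))
    c = np.zeros(p)
    yty = 0.0
    logdet = 0.0
    for Xg, yg, wg in blocks:
        s = wg.sum()
        shrink = lam / (1.0 + lam * s)
        Xw = Xg * wg[:, None]
        yw = yg * wg
        xs = Xw.sum(axis=0)
        ys = yw.sum()
        A += Xg.T @ Xw - shrink * np.outer(xs, xs)
        c += Xg.T @ yw - shrink * xs * ys
        yty += yg @ yw - shrink * ys * ys
        logdet += np.log1p(lam * s) - np.log(wg).sum()
    return A, c, yty, logdet


def _profile_neg2ll(lam, blocks, n, p, reml):
    A, c, yty, logdet = _profiled_pieces(blocks, lam)
    if p:
        try:
            beta = np.linalg.solve(A, c)
        except np.linalg.LinAlgError:
            return np.inf, None, None
        rss = yty - c @ beta
    else:
        beta = np.zeros(0)
        rss = yty
    rss = max(rss, 1e-300)
    if reml:
        dof = n - p
        sigma2 = rss / dof
        # -2rll = (n-p) log sigma2 + log|V*| + log|A| + (n-p) + (n-p) log 2pi,
        # with A = X' V*^{-1} X (the -p log sigma2 of log|X'V^{-1}X| cancels
        # against the n log sigma2 of log|V|)
        crit = dof * (_LOG_2PI + np.log(sigma2)) + logdet + dof
        if p:
            sign, ld = np.linalg.slogdet(A)
            if sign <= 0:
                return np.inf, None, None
            crit += ld
    else:
        sigma2 = rss / n
        crit = n * (_LOG_2PI + np.log(sigma2)) + logdet + n
    return crit, beta, sigma2


def _neg2ll_full(theta, blocks, n, p, reml):
    """-2 (restricted) log-likelihood at explicit (sigma2, tau2)."""
    sigma2, tau2 = theta
    if sigma2 <= 0 or tau2 < 0:
        return np.inf
    lam = tau2 / sigma2
    A, c, yty, logdet = _profiled_pieces(blocks, lam)
    if p:
        try:
            beta = np.linalg.solve(A, c)
        except np.linalg.LinAlgError:
            return np.inf
        rss = yty - c @ beta
    else:
        rss = yty
    crit = n * np.log(sigma2) + logdet + rss / sigma2 + n * _LOG_2PI
    if reml and p:
        sign, ld = np.linalg.slogdet(A / sigma2)
        if sign <= 0:
            return np.inf
        crit += ld - p * _LOG_2PI
    elif reml:
        pass
    return crit


def fit_random_intercept(
    y,
    X,
    groups,
    weights=None,
    reml: bool = True,
    names: list[str] | None = None,
) -> LMMFit:
    """Fit the weighted random-intercept model.

    Parameters
    ----------
    y, X:
        Response (n,) and fixed-effects design (n, p); ``X`` may have zero
        columns for a model with no fixed part (used as the null model of the
        zero-intercept percent-change trend test).
    groups:
        Group label per observation (the region).
    weights:
        Positive case weights; residual variance for observation i is
        ``sigma2 / weights[i]``.
    reml:
        Restricted (default) vs full maximum likelihood.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    X = np.zeros((n, 0)) if X is None else np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    p = X.shape[1]
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    groups = np.asarray(groups)
    if len(groups) != n or X.shape[0] != n or w.size != n:
        raise ValueError("y, X, groups and weights must have matching length")
    if n <= p:
        raise ValueError("more parameters than observations")

    blocks = _split_groups(X, y, w, groups)

    # profile over lambda = tau2/sigma2 on a log grid, then polish
    def crit(loglam):
        return _profile_neg2ll(np.exp(loglam), blocks, n, p, reml)[0]

    grid = np.linspace(-12.0, 8.0, 41)
    vals = [crit(g) for g in grid]
    best = int(np.argmin(vals))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        crit, bounds=(lo, hi), method="bounded", options={"xatol": 1e-10, "maxiter": 500}
    )
    lam = float(np.exp(res.x))
    c_lam, _, _ = _profile_neg2ll(lam, blocks, n, p, reml)
    c_zero, _, _ = _profile_neg2ll(0.0, blocks, n, p, reml)
    if c_zero <= c_lam:
        lam = 0.0

    crit_val, beta, sigma2 = _profile_neg2ll(lam, blocks, n, p, reml)
    tau2 = lam * sigma2
    A, _, _, _ = _profiled_pieces(blocks, lam)
    if p:
        cov_beta = sigma2 * np.linalg.inv(A)
        se = np.sqrt(np.diag(cov_beta))
        df = _satterthwaite_df(blocks, n, p, sigma2, tau2, cov_beta)
    else:
        se = np.zeros(0)
        df = np.zeros(0)

    return LMMFit(
        beta=np.asarray(beta, dtype=float),
        se=se,
        sigma2=float(sigma2),
        tau2=float(tau2),
        loglik=-0.5 * float(crit_val),
        reml=reml,
        df=df,
        n=n,
        n_groups=len(blocks),
        names=list(names or [f"x{j}" for j in range(p)]),
    )


def _coef_var(blocks, p, sigma2, tau2):
    """diag of cov(beta) = sigma2 * (sum X' V*^-1 X)^-1 at (sigma2, tau2)."""
    lam = tau2 / sigma2
    A, _, _, _ = _profiled_pieces(blocks, lam)
    return np.diag(sigma2 * np.linalg.inv(A))


def _satterthwaite_df(blocks, n, p, sigma2, tau2, cov_beta):
    """Satterthwaite df per coefficient from the REML information matrix.

    df_j = 2 f_j^2 / (g_j' Vtheta g_j), where f_j = var(beta_j) as a function
    of theta = (sigma2, tau2), g_j its gradient and Vtheta the inverse
    observed information of the restricted likelihood. Falls back to the
    residual df when the information matrix is not usable (e.g. tau2 on the
    boundary).
    """
    resid_df = float(max(n - p, 1))
    theta = np.array([sigma2, max(tau2, 0.0)])
    steps = np.maximum(1e-4 * np.maximum(theta, sigma2 * 1e-3), 1e-12)
    try:
        hess = np.zeros((2, 2))
        f0 = _neg2ll_full(theta, blocks, n, p, reml=True)
        for i in range(2):
            for j in range(i, 2):
                ei = np.zeros(2)
                ej = np.zeros(2)
                ei[i] = steps[i]
                ej[j] = steps[j]
                fpp = _neg2ll_full(theta + ei + ej, blocks, n, p, True)
                fpm = _neg2ll_full(theta + ei - ej, blocks, n, p, True)
                fmp = _neg2ll_full(theta - ei + ej, blocks, n, p, True)
                fmm = _neg2ll_full(theta - ei - ej, blocks, n, p, True)
                if not np.all(np.isfinite([fpp, fpm, fmp, fmm, f0])):
                    raise FloatingPointError
                hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4 * steps[i] * steps[j])
        # information of the loglik is hess/2; Vtheta = 2 * hess^{-1}
        vtheta = 2.0 * np.linalg.inv(hess)
        df = np.empty(p)
        for jcoef in range(p):
            g = np.zeros(2)
            for ith in range(2):
                e = np.zeros(2)
                e[ith] = steps[ith]
                vp = _coef_var(blocks, p, *(theta + e))[jcoef]
                vm = _coef_var(blocks, p, *np.maximum(theta - e, [1e-300, 0.0]))[jcoef]
                g[ith] = (vp - vm) / (2 * steps[ith])
            denom = float(g @ vtheta @ g)
            fj = float(cov_beta[jcoef, jcoef])
            if denom <= 0 or not np.isfinite(denom):
                df[jcoef] = resid_df
            else:
                df[jcoef] = np.clip(2.0 * fj**2 / denom, 1.0, resid_df)
        return df
    except (np.linalg.LinAlgError, FloatingPointError, ZeroDivisionError):
        return np.full(p, resid_df)


def likelihood_ratio_test(fit_full: LMMFit, fit_null: LMMFit) -> tuple[float, int, float]:
    """1-d.f.-per-parameter LRT between nested ML fits: (chi2, df, p)."""
    if fit_full.reml or fit_null.reml:
        raise ValueError("likelihood ratio tests require ML fits (reml=False)")
    df = len(fit_full.beta) - len(fit_null.beta)
    if df <= 0:
        raise ValueError("fit_full must have more fixed-effect parameters than fit_null")
    chi2 = max(2.0 * (fit_full.loglik - fit_null.loglik), 0.0)
    return chi2, df, float(stats.chi2.sf(chi2, df))
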