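"""Per-probe linear mixed model: fixed effects plus one random intercept.

The EWAS fits hundreds of thousands of tiny models of the form

    y = X b + Z u + e,   u ~ N(0, sigma_u^2 I) per group,  e ~ N(0, sigma_e^2 I)

with a handful of fixed effects and a single grouping factor (the array
chip).  This module implements the restricted-maximum-likelihood (REML)
fit directly, profiling the likelihood over the variance ratio
lambda = sigma_u^2 / sigma_e^2.  Because Z Z' depends only on the grouping
structure, its eigendecomposition is computed once per design and reused
across probes: each candidate lambda then costs one weighted least-squares
solve in the rotated basis.  At lambda = 0 the fit reduces exactly to
ordinary least squares, and Wald tests use a t reference with n - p
residual degrees of freedom so that limit reproduces the OLS t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = ["RandomInterceptModel", "MixedFitResult"]

_LOG_LAMBDA_BOUNDS = (-12.0, 10.0)


@dataclass
class MixedFitResult:
    """Result of one per-probe fit."""

    beta: np.ndarray  # fixed-effect estimates
    se: np.ndarray  # standard errors
    df: int  # residual degrees of freedom (n - p)
    sigma2: float  # residual variance estimate
    lambda_: float  # variance ratio sigma_u^2 / sigma_e^2
    ok: bool
    flag: str = ""

    def wald_p(self, index: int) -> float:
        """Two-sided Wald p-value for coefficient ``index`` (t, df = n - p)."""
        if not self.ok or self.se[index] <= 0:
            return np.nan
        t = self.beta[index] / self.se[index]
        return 2.0 * stats.t.sf(abs(t), self.df)


class RandomInterceptModel:
    """REML machinery for a fixed design matrix and grouping factor.

    Construct once per (design, missingness pattern); call :meth:`fit` per
    response vector.
    """

    def __init__(self, X: np.ndarray, groups: np.ndarray):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        self.n, self.p = X.shape
        if self.n < self.p + 2:
            raise ValueError("need at least p + 2 observations")
        if np.linalg.matrix_rank(X) < self.p:
            raise ValueError("singular fixed-effect design")
        _, codes = np.unique(np.asarray(groups), return_inverse=True)
        if len(codes) != self.n:
            raise ValueError("groups must align with rows of X")
        ZZt = (codes[:, None] == codes[None, :]).astype(float)
        d, Q = np.linalg.eigh(ZZt)
        self.d = np.clip(d, 0.0, None)
        self.Q = Q
        self.Xs = Q.T @ X

    def _gls(self, lam: float, ys: np.ndarray):
        w = 1.0 / (1.0 + lam * self.d)
        Xw = self.Xs * w[:, None]
        XtWX = self.Xs.T @ Xw
        XtWy = Xw.T @ ys
        beta = np.linalg.solve(XtWX, XtWy)
        resid = ys - self.Xs @ beta
        rss = float(np.sum(w * resid**2))
        return beta, rss, XtWX, w

    def _neg2_reml(self, lam: float, ys: np.ndarray) -> float:
        beta, rss, XtWX, _ = self._gls(lam, ys)
        dfr = self.n - self.p
        sigma2 = rss / dfr
        if sigma2 <= 0:
            return np.inf
        sign, logdet = np.linalg.slogdet(XtWX)
        if sign <= 0:
            return np.inf
        return dfr * np.log(sigma2) + float(np.sum(np.log1p(lam * self.d))) + logdet

    def fit(self, y: np.ndarray, free_variance: bool = True) -> MixedFitResult:
        """REML fit of one response; ``free_variance=False`` constrains the
        random-intercept variance to zero (exact OLS)."""
        y = np.asarray(y, dtype=float)
        if y.shape != (self.n,):
            raise ValueError("response length mismatch")
        if not np.all(np.isfinite(y)):
            raise ValueError("response contains non-finite values; drop missing samples first")
        if np.ptp(y) == 0.0:
            return MixedFitResult(
                beta=np.full(self.p, np.nan),
                se=np.full(self.p, np.nan),
                df=self.n - self.p,
                sigma2=0.0,
                lambda_=0.0,
                ok=False,
                flag="constant_response",
            )
        ys = self.Q.T @ y
        lam = 0.0
        if free_variance:
            res = optimize.minimize_scalar(
                lambda t: self._neg2_reml(np.exp(t), ys),
                bounds=_LOG_LAMBDA_BOUNDS,
                method="bounded",
                options={"xatol": 1e-6},
            )
            if res.success and self._neg2_reml(np.exp(res.x), ys) < self._neg2_reml(0.0, ys):
                lam = float(np.exp(res.x))
                if lam < 1e-10:
                    lam = 0.0
        beta, rss, XtWX, _ = self._gls(lam, ys)
        dfr = self.n - self.p
        sigma2 = rss / dfr
        cov = sigma2 * np.linalg.inv(XtWX)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        return MixedFitResult(
            beta=beta, se=se, df=dfr, sigma2=sigma2, lambda_=lam, ok=True
        )
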