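"""Additive genotype-phenotype model and the monotone bin transform.

The additive (non-epistatic) model regresses the measured expression bin y
on the 3L mutation indicators by ordinary least squares.  Because the bins
are a nonlinear readout of expression (logarithmic gates plus a background
fluorescence floor), y is replaced by a monotone non-decreasing transform
g(y), defined only at the K bin values and pinned at the endpoints
g(1) = 1, g(K) = K to fix its scale.  g is chosen to maximize the R^2 of
the additive fit and is then frozen for all higher-order models, so that
epistatic terms cannot absorb any average nonlinearity of the readout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, sparse


@dataclass
class AdditiveModel:
    alpha: float
    beta: np.ndarray


@dataclass
class FitSummary:
    r_squared: float
    residual_variance: float
    n_observations: int


@dataclass
class BinTransform:
    """The monotone function g evaluated at the K bin values."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) < 2:
            raise ValueError("a bin transform needs K >= 2 values")
        if np.any(np.diff(self.values) < -1e-12):
            raise ValueError("bin transform must be non-decreasing")

    @property
    def K(self) -> int:
        return len(self.values)

    @classmethod
    def identity(cls, K: int) -> "BinTransform":
        return cls(np.arange(1, K + 1, dtype=float))

    def __call__(self, bins: np.ndarray) -> np.ndarray:
        return transform_response(bins, self)


def transform_response(bins: np.ndarray, g: BinTransform) -> np.ndarray:
    """Element-wise lookup g(y) for integer bins 1..K."""
    bins = np.asarray(bins)
    if bins.min() < 1 or bins.max() > g.K:
        raise ValueError(f"bin labels outside 1..{g.K}")
    return g.values[bins - 1]


def fit_additive_ols(X, response: np.ndarray) -> tuple[AdditiveModel, FitSummary]:
    """OLS fit of response on the order-1 design matrix (intercept fitted separately).

    Solves the normal equations through the pseudo-inverse of the augmented
    Gram matrix, which yields the minimum-norm solution on rank-deficient
    designs.  A zero-variance response is fitted as a pure intercept with
    the convention R^2 = 0.
    """
    y = np.asarray(response, dtype=float)
    n = X.shape[0]
    if n == 0:
        raise ValueError("empty design matrix")
    if len(y) != n:
        raise ValueError("response length does not match design matrix")

    # augmented Gram system for [alpha; beta]
    if sparse.issparse(X):
        Xt1 = np.asarray(X.sum(axis=0)).ravel()
        G = np.empty((X.shape[1] + 1, X.shape[1] + 1))
        G[0, 0] = n
        G[0, 1:] = Xt1
        G[1:, 0] = Xt1
        G[1:, 1:] = (X.T @ X).toarray()
        b = np.concatenate([[y.sum()], X.T @ y])
    else:
        A = np.column_stack([np.ones(n), np.asarray(X, dtype=float)])
        G = A.T @ A
        b = A.T @ y
    theta, *_ = np.linalg.lstsq(G, b, rcond=None)
    alpha, beta = float(theta[0]), theta[1:]

    fitted = alpha + (X @ beta)
    resid = y - fitted
    sse = float(resid @ resid)
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 0.0 if sst == 0.0 else 1.0 - sse / sst
    return AdditiveModel(alpha, beta), FitSummary(r2, sse / n, n)


def _bin_stats(bins: np.ndarray, fitted: np.ndarray, K: int):
    """Per-bin count, sum of fitted values and sum of squared fitted values."""
    counts = np.bincount(bins - 1, minlength=K).astype(float)
    s = np.bincount(bins - 1, weights=fitted, minlength=K)
    q = float(fitted @ fitted)
    return counts, s, q


def _best_g_given_fit(
    bins: np.ndarray, fitted: np.ndarray, K: int, g0: np.ndarray
) -> np.ndarray:
    """Maximize R^2 over the K-2 interior g values, coefficients held fixed.

    With the fit fixed, both the residual sum of squares and the total sum
    of squares of g(y) are quadratics in the K bin values, so
    R^2(g) = 1 - SSE(g)/SST(g) has a cheap closed form; it is maximized
    under the monotonicity chain and the pinned endpoints with SLSQP
    starting from the current g (the incumbent is feasible, so the result
    can only improve).
    """
    n = len(bins)
    counts, s, q = _bin_stats(bins, fitted, K)

    def full_g(free: np.ndarray) -> np.ndarray:
        return np.concatenate([[g0[0]], free, [g0[-1]]])

    def neg_r2(free: np.ndarray) -> float:
        g = full_g(free)
        sse = float(counts @ g**2 - 2 * s @ g + q)
        mean = float(counts @ g) / n
        sst = float(counts @ g**2) - n * mean**2
        if sst <= 0:
            return 1.0
        return sse / sst - 1.0  # = -(R^2)

    x0 = g0[1:-1]
    if len(x0) == 0:
        return g0.copy()
    # monotone chain including the pinned endpoints
    cons = [
        {
            "type": "ineq",
            "fun": lambda f, k=k: (full_g(f)[k + 1] - full_g(f)[k]),
        }
        for k in range(K - 1)
    ]
    res = optimize.minimize(
        neg_r2,
        x0,
        method="SLSQP",
        constraints=cons,
        options={"maxiter": 200, "ftol": 1e-12},
    )
    if not res.success or neg_r2(res.x) > neg_r2(x0):
        return g0.copy()
    g = full_g(res.x)
    # clean numerical violations of monotonicity
    g = np.maximum.accumulate(g)
    g[-1] = g0[-1]
    return g


def optimize_bin_transform(
    X,
    bins: np.ndarray,
    init: BinTransform | None = None,
    K: int | None = None,
    max_rounds: int = 100,
    tol: float = 1e-6,
) -> tuple[BinTransform, AdditiveModel, FitSummary]:
    """Alternating optimization of the bin transform g and the OLS coefficients.

    Rounds alternate (a) OLS for the coefficients given g with (b) the
    exact R^2-maximizing monotone g given the fit, until the R^2 gain
    drops below ``tol`` or ``max_rounds`` is reached.  Both half-steps are
    non-decreasing in R^2 and the iteration starts at ``init`` (identity
    by default), so the returned R^2 is never below the plain-OLS R^2.
    """
    bins = np.asarray(bins, dtype=int)
    if K is None:
        K = int(bins.max()) if init is None else init.K
    if K < 2:
        raise ValueError("K must be >= 2")
    present = np.unique(bins)
    missing = sorted(set(range(1, K + 1)) - set(present.tolist()))
    if missing:
        raise ValueError(f"bin levels absent from data: {missing}")

    g = (init or BinTransform.identity(K)).values.copy()
    best = None
    prev_r2 = -np.inf
    for _ in range(max_rounds):
        gy = g[bins - 1]
        model, summary = fit_additive_ols(X, gy)
        if best is None or summary.r_squared > best[2].r_squared:
            best = (g.copy(), model, summary)
        if summary.r_squared - prev_r2 < tol:
            break
        prev_r2 = summary.r_squared
        fitted = model.alpha + X @ model.beta
        g = _best_g_given_fit(bins, fitted, K, g)

    g_best, model, _ = best
    # report the summary for the best g after a final refit
    gy = g_best[bins - 1]
    model, summary = fit_additive_ols(X, gy)
    return BinTransform(g_best), model, summary
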