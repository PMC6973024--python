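"""Between-study variance estimation for the normal-normal random-effects model.

Under the model ``yi ~ N(x_i' beta, vi + tau2)`` the weights used for pooling
are ``wi* = 1/(vi + tau2)``, so everything downstream depends on an estimate
of tau2. Two estimators are provided:

* REML (the default throughout the package): tau2 maximizing the restricted
  log-likelihood, profiled over the fixed effects;
* DerSimonian-Laird: the method-of-moments estimator built from the
  generalized Q statistic with fixed-effect weights ``1/vi``.

Both truncate negative solutions at exactly zero. For an intercept-only
analysis pass ``X=None``; for meta-regression pass the full design matrix
(tau2 is then the *residual* between-study variance).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .exceptions import DegreesOfFreedomError, InvalidInputError

__all__ = ["Tau2Estimate", "reml_tau2", "dersimonian_laird_tau2", "restricted_loglik"]

_REML_TOL = 1e-8
_REML_MAXITER = 200


@dataclass(frozen=True)
class Tau2Estimate:
    """A between-study variance estimate plus how it was obtained."""

    tau2: float
    estimator: str  # "REML", "DL" or "fixed"
    converged: bool = True
    iterations: int = 0

    def __post_init__(self) -> None:
        if self.tau2 < 0 or not np.isfinite(self.tau2):
            raise InvalidInputError(f"tau2 must be finite and >= 0, got {self.tau2}")


def _validate(y: np.ndarray, v: np.ndarray, X: np.ndarray) -> None:
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(v))):
        raise InvalidInputError("non-finite yi or vi")
    if np.any(v <= 0):
        raise InvalidInputError("all sampling variances must be > 0")
    n, p = X.shape
    if n <= p:
        raise DegreesOfFreedomError(f"need more studies than coefficients (n={n}, p={p})")


def _as_design(X, n: int) -> np.ndarray:
    if X is None:
        return np.ones((n, 1))
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X


def restricted_loglik(tau2: float, y, v, X=None) -> float:
    """Restricted log-likelihood of tau2 (up to an additive constant).

    -2 llR = sum log(vi + tau2) + log det(X' W X) + r' W r, with
    W = diag(1/(vi + tau2)) and r the weighted-least-squares residuals at
    this tau2.
    """
    y = np.asarray(y, dtype=float)
    v = np.asarray(v, dtype=float)
    X = _as_design(X, y.size)
    w = 1.0 / (v + tau2)
    xtwx = X.T @ (w[:, None] * X)
    beta = np.linalg.solve(xtwx, X.T @ (w * y))
    r = y - X @ beta
    sign, logdet = np.linalg.slogdet(xtwx)
    return -0.5 * (np.sum(np.log(v + tau2)) + logdet + np.sum(w * r * r))


def _reml_nll_grid_intercept(tau2_grid: np.ndarray, y: np.ndarray, v: np.ndarray) -> np.ndarray:
    """-2 llR on a grid of tau2 values, closed form for the intercept-only design."""
    w = 1.0 / (v[None, :] + tau2_grid[:, None])
    sw = w.sum(axis=1)
    swy = (w * y).sum(axis=1)
    swyy = (w * y * y).sum(axis=1)
    return np.log(v[None, :] + tau2_grid[:, None]).sum(axis=1) + np.log(sw) + swyy - swy**2 / sw


def reml_tau2(y, v, X=None) -> Tau2Estimate:
    """REML estimate of the (residual) between-study variance.

    The restricted log-likelihood is bracketed on a coarse grid over
    [0, B] with B = 10*(max yi - min yi)^2 + max vi, then refined by bounded
    scalar maximization (tolerance 1e-8, at most 200 iterations). The
    boundary tau2 = 0 is checked explicitly and negative solutions cannot
    occur by construction.
    """
    y = np.asarray(y, dtype=float)
    v = np.asarray(v, dtype=float)
    X = _as_design(X, y.size)
    _validate(y, v, X)

    upper = 10.0 * float(np.ptp(y)) ** 2 + float(np.max(v))
    upper = max(upper, 10.0 * float(np.max(v)))

    grid = np.linspace(0.0, upper, 65)
    intercept_only = X.shape[1] == 1 and np.all(X == X[0, 0])
    if intercept_only:
        nll = _reml_nll_grid_intercept(grid, y, v)
    else:
        nll = np.array([-2.0 * restricted_loglik(t, y, v, X) for t in grid])
    i = int(np.argmin(nll))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid.size - 1)]

    res = minimize_scalar(
        lambda t: -2.0 * restricted_loglik(t, y, v, X),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": _REML_TOL, "maxiter": _REML_MAXITER},
    )
    tau2, best, nit = float(res.x), float(res.fun), int(res.nfev)
    # the optimizer cannot land exactly on the boundary; prefer 0 if at least as good
    if -2.0 * restricted_loglik(0.0, y, v, X) <= best:
        tau2 = 0.0
    return Tau2Estimate(tau2=max(tau2, 0.0), estimator="REML", converged=bool(res.success), iterations=nit)


def dersimonian_laird_tau2(y, v, X=None) -> Tau2Estimate:
    """DerSimonian-Laird moment estimate of the (residual) between-study variance.

    With fixed-effect weights W = diag(1/vi), Q = r' W r for the WLS residuals
    r, and tau2_DL = max(0, (Q - (n - p)) / tr(P)) where
    P = W - W X (X' W X)^-1 X' W.
    """
    y = np.asarray(y, dtype=float)
    v = np.asarray(v, dtype=float)
    X = _as_design(X, y.size)
    _validate(y, v, X)
    n, p = X.shape

    w = 1.0 / v
    xtwx = X.T @ (w[:, None] * X)
    beta = np.linalg.solve(xtwx, X.T @ (w * y))
    r = y - X @ beta
    q = float(np.sum(w * r * r))
    wx = w[:, None] * X
    trace_p = float(np.sum(w) - np.trace(np.linalg.solve(xtwx, wx.T @ wx)))
    tau2 = max(0.0, (q - (n - p)) / trace_p)
    return Tau2Estimate(tau2=tau2, estimator="DL", converged=True, iterations=0)


def estimate_tau2(y, v, X=None, method="reml") -> Tau2Estimate:
    """Dispatch on a method name: ``"reml"``, ``"dl"``, or a fixed value.

    Fixed values may be given as a float or as a string ``"fixed:<value>"``.
    """
    if isinstance(method, Tau2Estimate):
        return method
    if isinstance(method, (int, float)):
        return Tau2Estimate(tau2=float(method), estimator="fixed")
    name = str(method).lower()
    if name == "reml":
        return reml_tau2(y, v, X)
    if name == "dl":
        return dersimonian_laird_tau2(y, v, X)
    if name.startswith("fixed:"):
        return Tau2Estimate(tau2=float(name.split(":", 1)[1]), estimator="fixed")
    raise InvalidInputError(f"unknown tau2 method {method!r}")
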