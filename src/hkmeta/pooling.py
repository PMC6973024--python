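"""Intercept-only random-effects meta-analysis: pooling and inference.

The pooled estimate is the inverse-variance weighted mean with weights
``wi* = 1/(vi + tau2)``. Two inference methods share that point estimate:

* conventional: variance ``V = 1/sum(wi*)`` treated as known, normal pivot;
* Hartung-Knapp: variance ``V_HK = H*2 * V`` with the scale factor
  ``H*2 = sum wi*(yi - mu)^2 / (n - 1)`` (a weighted mean squared error) and
  a t pivot on n - 1 degrees of freedom.

The Hartung-Knapp interval can be narrower than the conventional one when
``H*2`` is small; the ``constraint`` option bounds the scale factor below by
1 (``"unit"``) or by ``(z_{a/2}/t_{n-1,a/2})^2`` (``"zt"``). The latter makes
the reported interval exactly the wider of the two methods' intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .effects import EffectEstimate
from .exceptions import InsufficientDataError, InvalidInputError
from .heterogeneity import Tau2Estimate

__all__ = [
    "PooledFit",
    "InferenceResult",
    "fit_random_effects",
    "conventional_inference",
    "hk_scale_factor",
    "hk_inference",
]

CONSTRAINTS = ("none", "unit", "zt")


def as_arrays(data) -> tuple[np.ndarray, np.ndarray]:
    """Coerce a list of EffectEstimate, a (y, v) pair, or a DataFrame to arrays."""
    if hasattr(data, "columns"):  # DataFrame-like
        return np.asarray(data["yi"], float), np.asarray(data["vi"], float)
    if len(data) and isinstance(data[0], EffectEstimate):
        return (
            np.array([e.yi for e in data], float),
            np.array([e.vi for e in data], float),
        )
    y, v = data
    return np.asarray(y, float), np.asarray(v, float)


@dataclass(frozen=True)
class PooledFit:
    """An intercept-only random-effects fit: weights, pooled mean, conventional variance."""

    weights: np.ndarray
    mu_hat: float
    V: float
    tau2: Tau2Estimate
    n: int
    yi: np.ndarray

    @property
    def se(self) -> float:
        return math.sqrt(self.V)


@dataclass(frozen=True)
class InferenceResult:
    """A point estimate with its test and confidence interval.

    ``df`` is None for the normal reference, otherwise the t degrees of
    freedom. ``scale_factor`` is the multiplier actually applied to the
    conventional variance (1 for the conventional method, the possibly
    constrained H*2 for Hartung-Knapp). ``degenerate`` flags a zero-width
    interval arising from H*2 = 0.
    """

    estimate: float
    se: float
    statistic: float
    df: int | None
    p: float
    ci_lower: float
    ci_upper: float
    alpha: float
    method: str
    scale_factor: float
    degenerate: bool = False
    term: str = "mu"

    @property
    def width(self) -> float:
        return self.ci_upper - self.ci_lower


def fit_random_effects(data, tau2: Tau2Estimate) -> PooledFit:
    """Pool effect estimates with inverse-variance weights 1/(vi + tau2)."""
    y, v = as_arrays(data)
    if y.size < 2:
        raise InsufficientDataError(f"need at least 2 studies, got {y.size}")
    if np.any(v <= 0) or not np.all(np.isfinite(v)):
        raise InvalidInputError("all sampling variances must be finite and > 0")
    w = 1.0 / (v + tau2.tau2)
    sw = float(w.sum())
    mu = float((w * y).sum() / sw)
    return PooledFit(weights=w, mu_hat=mu, V=1.0 / sw, tau2=tau2, n=int(y.size), yi=y)


def conventional_inference(fit: PooledFit, alpha: float = 0.05) -> InferenceResult:
    """Normal-pivot inference treating all variances as known."""
    _check_alpha(alpha)
    se = fit.se
    z = fit.mu_hat / se
    zq = stats.norm.ppf(1.0 - alpha / 2.0)
    return InferenceResult(
        estimate=fit.mu_hat,
        se=se,
        statistic=z,
        df=None,
        p=float(2.0 * stats.norm.sf(abs(z))),
        ci_lower=fit.mu_hat - zq * se,
        ci_upper=fit.mu_hat + zq * se,
        alpha=alpha,
        method="conventional",
        scale_factor=1.0,
    )


def hk_scale_factor(fit: PooledFit) -> float:
    """The Hartung-Knapp variance scale H*2 = sum wi*(yi - mu)^2 / (n - 1).

    Zero exactly when every yi equals the pooled mean. With tau2 = 0 this is
    the Higgins-Thompson H^2 = Q/(n-1) heterogeneity statistic.
    """
    if fit.n < 2:
        raise InsufficientDataError("H*2 needs at least 2 studies")
    r = fit.yi - fit.mu_hat
    return float((fit.weights * r * r).sum() / (fit.n - 1))


def constrained_scale(h2: float, df: int, alpha: float, constraint: str) -> float:
    """Apply the requested lower bound to the HK scale factor H*2."""
    if constraint == "none":
        return h2
    if constraint == "unit":
        return max(h2, 1.0)
    if constraint == "zt":
        z = stats.norm.ppf(1.0 - alpha / 2.0)
        t = stats.t.ppf(1.0 - alpha / 2.0, df)
        return max(h2, (z / t) ** 2)
    raise InvalidInputError(f"unknown constraint {constraint!r}; choose from {CONSTRAINTS}")


def hk_inference(fit: PooledFit, alpha: float = 0.05, constraint: str = "none") -> InferenceResult:
    """Hartung-Knapp inference: scaled variance, t pivot with n - 1 df.

    If H*2 = 0 under ``constraint="none"`` the interval collapses to a point;
    the result is returned with ``degenerate=True`` rather than raising, so
    simulation loops survive.
    """
    _check_alpha(alpha)
    if fit.n < 2:
        raise InsufficientDataError("Hartung-Knapp inference needs at least 2 studies")
    df = fit.n - 1
    h2 = hk_scale_factor(fit)
    scale = constrained_scale(h2, df, alpha, constraint)
    se = math.sqrt(scale * fit.V)
    method = {"none": "hk", "unit": "hk_unit", "zt": "hk_zt"}[constraint]
    if se == 0.0:
        return InferenceResult(
            estimate=fit.mu_hat,
            se=0.0,
            statistic=math.nan,
            df=df,
            p=math.nan,
            ci_lower=fit.mu_hat,
            ci_upper=fit.mu_hat,
            alpha=alpha,
            method=method,
            scale_factor=scale,
            degenerate=True,
        )
    t = fit.mu_hat / se
    tq = stats.t.ppf(1.0 - alpha / 2.0, df)
    return InferenceResult(
        estimate=fit.mu_hat,
        se=se,
        statistic=t,
        df=df,
        p=float(2.0 * stats.t.sf(abs(t), df)),
        ci_lower=fit.mu_hat - tq * se,
        ci_upper=fit.mu_hat + tq * se,
        alpha=alpha,
        method=method,
        scale_factor=scale,
    )


def _check_alpha(alpha: float) -> None:
    if not (0.0 < alpha < 1.0):
        raise InvalidInputError(f"alpha must be in (0, 1), got {alpha}")
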