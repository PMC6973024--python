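"""Random-effects meta-regression as weighted least squares.

A random-effects meta-regression with weights ``wi* = 1/(vi + tau2)`` is a
WLS regression ``y = X beta + e``. Two assumptions about the error variances
give the two inference methods:

* variances known (``Var(e_i) = vi + tau2``): normal reference,
  ``Var(beta) = (X'WX)^-1`` — the conventional method;
* variances known up to a proportionality constant k
  (``Var(e_i) = k (vi + tau2)``): ``Var(beta) = k_hat (X'WX)^-1`` with
  ``k_hat`` the weighted mean squared error ``e'We/(n-p)``, t reference with
  n - p degrees of freedom — the Hartung-Knapp method.

The two routes share the coefficient estimates (the constant cancels from
the normal equations); ``k_hat`` is identically the Hartung-Knapp scale
factor H*2, generalized by replacing the pooled mean with fitted values.
``equivalence_report`` checks this equivalence numerically by diffing the
meta-analytic formulas against a generic WLS fit from statsmodels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .exceptions import (
    DegreesOfFreedomError,
    InvalidInputError,
    SingularDesignError,
)
from .heterogeneity import Tau2Estimate, estimate_tau2
from .pooling import InferenceResult, as_arrays, constrained_scale

__all__ = [
    "DesignMatrix",
    "RegressionFit",
    "EquivalenceReport",
    "build_design",
    "fit_wls",
    "metareg_inference",
    "equivalence_report",
]

_RANK_RTOL = 1e-10


@dataclass(frozen=True)
class DesignMatrix:
    """An n x p design with a leading intercept column and coefficient labels."""

    X: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        X = self.X
        if X.ndim != 2 or X.shape[1] != len(self.labels):
            raise InvalidInputError("design matrix shape does not match labels")
        sv = np.linalg.svd(X, compute_uv=False)
        if sv[-1] <= _RANK_RTOL * sv[0]:
            raise SingularDesignError(
                f"design matrix is rank deficient (singular values {sv})"
            )


def build_design(covariates=None, labels=None, n: int | None = None) -> DesignMatrix:
    """Assemble [1 | covariates] with labels ('intercept', ...).

    ``covariates`` is an n x q array (or None for intercept-only, in which
    case ``n`` is required). Categorical moderators must already be coded as
    0/1 dummy columns.
    """
    if covariates is None:
        if n is None:
            raise InvalidInputError("need n for an intercept-only design")
        return DesignMatrix(np.ones((n, 1)), ("intercept",))
    Z = np.asarray(covariates, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    if labels is None:
        labels = tuple(f"x{j + 1}" for j in range(Z.shape[1]))
    X = np.column_stack([np.ones(Z.shape[0]), Z])
    return DesignMatrix(X, ("intercept", *labels))


@dataclass(frozen=True)
class RegressionFit:
    """A weighted least squares fit with the proportionality-constant estimate.

    ``cov_unscaled`` is (X'WX)^-1, the coefficient covariance under known
    variances; multiplying it by ``k_hat`` gives the covariance under the
    proportional-variance model (the Hartung-Knapp scaling).
    """

    beta: np.ndarray
    cov_unscaled: np.ndarray
    k_hat: float
    fitted: np.ndarray
    residuals: np.ndarray
    df: int
    labels: tuple[str, ...]
    tau2: Tau2Estimate | None = None
    weights: np.ndarray = field(default=None, repr=False)


def fit_wls(y, design: DesignMatrix, weights) -> RegressionFit:
    """Weighted least squares: beta = (X'WX)^-1 X'Wy, k_hat = e'We/(n-p).

    The coefficient estimates are invariant to rescaling all weights by a
    positive constant; only ``cov_unscaled`` changes.
    """
    y = np.asarray(y, dtype=float)
    w = np.asarray(weights, dtype=float)
    X = design.X
    n, p = X.shape
    if np.any(w <= 0) or not np.all(np.isfinite(w)):
        raise InvalidInputError("weights must be finite and > 0")
    if n <= p:
        raise DegreesOfFreedomError(f"n={n} studies cannot identify p={p} coefficients")

    xtwx = X.T @ (w[:, None] * X)
    cov_unscaled = np.linalg.inv(xtwx)
    beta = cov_unscaled @ (X.T @ (w * y))
    fitted = X @ beta
    resid = y - fitted
    k_hat = float((w * resid * resid).sum() / (n - p))
    return RegressionFit(
        beta=beta,
        cov_unscaled=cov_unscaled,
        k_hat=k_hat,
        fitted=fitted,
        residuals=resid,
        df=n - p,
        labels=design.labels,
        weights=w,
    )


def metareg_inference(
    fit: RegressionFit,
    method: str = "hk",
    alpha: float = 0.05,
    constraint: str = "none",
) -> list[InferenceResult]:
    """Per-coefficient tests and confidence intervals.

    ``method="conventional"`` uses SEs from (X'WX)^-1 and the normal
    reference; ``method="hk"`` scales by k_hat (= H*2, optionally
    constrained) and uses t with n - p degrees of freedom. The HK and
    conventional SEs differ by exactly sqrt(k_hat) for every coefficient.
    """
    if method not in ("conventional", "hk"):
        raise InvalidInputError(f"unknown inference method {method!r}")
    if not (0.0 < alpha < 1.0):
        raise InvalidInputError(f"alpha must be in (0, 1), got {alpha}")
    base_se = np.sqrt(np.diag(fit.cov_unscaled))
    results: list[InferenceResult] = []
    if method == "conventional":
        zq = stats.norm.ppf(1.0 - alpha / 2.0)
        for j, label in enumerate(fit.labels):
            b, se = float(fit.beta[j]), float(base_se[j])
            z = b / se
            results.append(
                InferenceResult(
                    estimate=b, se=se, statistic=z, df=None,
                    p=float(2.0 * stats.norm.sf(abs(z))),
                    ci_lower=b - zq * se, ci_upper=b + zq * se,
                    alpha=alpha, method="conventional", scale_factor=1.0,
                    term=label,
                )
            )
        return results

    scale = constrained_scale(fit.k_hat, fit.df, alpha, constraint)
    name = {"none": "hk", "unit": "hk_unit", "zt": "hk_zt"}[constraint]
    tq = stats.t.ppf(1.0 - alpha / 2.0, fit.df)
    for j, label in enumerate(fit.labels):
        b = float(fit.beta[j])
        se = float(math.sqrt(scale) * base_se[j])
        if se == 0.0:
            results.append(
                InferenceResult(
                    estimate=b, se=0.0, statistic=math.nan, df=fit.df, p=math.nan,
                    ci_lower=b, ci_upper=b, alpha=alpha, method=name,
                    scale_factor=scale, degenerate=True, term=label,
                )
            )
            continue
        t = b / se
        results.append(
            InferenceResult(
                estimate=b, se=se, statistic=t, df=fit.df,
                p=float(2.0 * stats.t.sf(abs(t), fit.df)),
                ci_lower=b - tq * se, ci_upper=b + tq * se,
                alpha=alpha, method=name, scale_factor=scale, term=label,
            )
        )
    return results


@dataclass(frozen=True)
class EquivalenceReport:
    """Maximum absolute discrepancies between the two computational routes."""

    discrepancies: dict[str, float]
    tolerance: float

    @property
    def passed(self) -> bool:
        return all(d <= self.tolerance for d in self.discrepancies.values())


def equivalence_report(
    data,
    covariates=None,
    alpha: float = 0.05,
    tolerance: float = 1e-8,
    tau2_method="reml",
) -> EquivalenceReport:
    """Diff the meta-analytic formulas against a generic WLS fit.

    Route one is this package's meta-analysis/meta-regression machinery;
    route two fits the same weighted regression with statsmodels ``WLS``,
    whose default scale estimate is exactly the proportionality constant
    k_hat (its summary is the proportional-variance model; dividing its SEs
    by sqrt(k_hat) recovers the known-variance model). The report records the
    largest absolute difference per reported quantity; this is an algebraic
    identity, so the default tolerance is tight.
    """
    import statsmodels.api as sm

    y, v = as_arrays(data)
    design = build_design(covariates, n=y.size)
    tau2 = estimate_tau2(y, v, design.X, tau2_method)
    w = 1.0 / (v + tau2.tau2)

    fit = fit_wls(y, design, w)
    conv = metareg_inference(fit, "conventional", alpha)
    hk = metareg_inference(fit, "hk", alpha)

    res = sm.WLS(y, design.X, weights=w).fit()
    k_sm = float(res.scale)
    se_prop = np.asarray(res.bse)
    se_known = se_prop / math.sqrt(k_sm)
    z_stat = np.asarray(res.params) / se_known
    zq = stats.norm.ppf(1.0 - alpha / 2.0)
    ci_prop = np.asarray(res.conf_int(alpha))
    ci_known = np.column_stack(
        [np.asarray(res.params) - zq * se_known, np.asarray(res.params) + zq * se_known]
    )

    def gap(a, b):
        return float(np.max(np.abs(np.asarray(a) - np.asarray(b))))

    disc = {
        "estimates": gap([r.estimate for r in conv], res.params),
        "k_hat": abs(fit.k_hat - k_sm),
        "se_conventional": gap([r.se for r in conv], se_known),
        "se_hk": gap([r.se for r in hk], se_prop),
        "stat_conventional": gap([r.statistic for r in conv], z_stat),
        "stat_hk": gap([r.statistic for r in hk], res.tvalues),
        "p_conventional": gap([r.p for r in conv], 2.0 * stats.norm.sf(np.abs(z_stat))),
        "p_hk": gap([r.p for r in hk], res.pvalues),
        "ci_conventional": gap([[r.ci_lower, r.ci_upper] for r in conv], ci_known),
        "ci_hk": gap([[r.ci_lower, r.ci_upper] for r in hk], ci_prop),
    }
    return EquivalenceReport(discrepancies=disc, tolerance=tolerance)
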