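"""Model/Results interface for random-effects meta-analysis and meta-regression.

``RandomEffectsMeta`` is constructed from per-study effect sizes ``yi`` and
sampling variances ``vi`` (plus optional moderator columns) and ``fit()``
returns a ``RandomEffectsMetaResults`` carrying the coefficient estimates,
both the conventional (normal-pivot, variances known) and the Hartung-Knapp
(t-pivot, variances known up to a proportionality constant) inference, the
REML or DerSimonian-Laird between-study variance, and the scale factor
H*2 = k_hat.

    >>> model = RandomEffectsMeta.from_dataframe(df)      # columns yi, vi
    >>> res = model.fit()                                  # REML tau2
    >>> print(res.summary())

With no moderators this is a meta-analysis of the average effect; with
moderators it is a meta-regression and tau2 is the residual between-study
variance estimated under the full covariate model.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .exceptions import InsufficientDataError
from .heterogeneity import Tau2Estimate, estimate_tau2
from .pooling import InferenceResult
from .wls import DesignMatrix, RegressionFit, build_design, fit_wls, metareg_inference

__all__ = ["RandomEffectsMeta", "RandomEffectsMetaResults"]


class RandomEffectsMeta:
    """Random-effects meta-analysis / meta-regression model.

    Parameters
    ----------
    yi, vi : array-like
        Effect estimates and their within-study sampling variances.
    covariates : array-like, optional
        n x q moderator values; an intercept column is always prepended.
        Categorical moderators must be pre-coded as 0/1 dummies.
    labels : sequence of str, optional
        Names for the moderator columns.
    """

    def __init__(self, yi, vi, covariates=None, labels=None):
        self.yi = np.asarray(yi, dtype=float)
        self.vi = np.asarray(vi, dtype=float)
        if self.yi.size < 2:
            raise InsufficientDataError("need at least 2 studies")
        if covariates is None:
            self.design: DesignMatrix = build_design(n=self.yi.size)
        else:
            self.design = build_design(covariates, labels=labels)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, yi: str = "yi", vi: str = "vi", covariates=()):
        """Build a model from a DataFrame with effect-size and moderator columns."""
        cov = df[list(covariates)].to_numpy(float) if covariates else None
        return cls(df[yi], df[vi], covariates=cov, labels=tuple(covariates))

    @property
    def nobs(self) -> int:
        return int(self.yi.size)

    def fit(self, tau2="reml", alpha: float = 0.05, constraint: str = "none"):
        """Estimate tau2, fit the weighted regression, and prepare inference.

        ``tau2`` is ``"reml"`` (default), ``"dl"``, a fixed float, or an
        existing :class:`Tau2Estimate`. ``constraint`` bounds the
        Hartung-Knapp scale factor from below (``"none"``, ``"unit"``,
        ``"zt"``).
        """
        t2 = estimate_tau2(self.yi, self.vi, self.design.X, tau2)
        w = 1.0 / (self.vi + t2.tau2)
        reg = fit_wls(self.yi, self.design, w)
        reg = dataclasses.replace(reg, tau2=t2)
        return RandomEffectsMetaResults(self, reg, t2, alpha=alpha, constraint=constraint)


class RandomEffectsMetaResults:
    """Results of a random-effects meta-analysis/meta-regression fit."""

    def __init__(self, model, reg: RegressionFit, tau2: Tau2Estimate, alpha=0.05, constraint="none"):
        self.model = model
        self.reg = reg
        self.tau2 = tau2
        self.alpha = alpha
        self.constraint = constraint

    # -- statsmodels-flavoured accessors ------------------------------------
    @property
    def params(self) -> np.ndarray:
        return self.reg.beta

    @property
    def k_hat(self) -> float:
        """Proportionality constant = Hartung-Knapp scale factor H*2."""
        return self.reg.k_hat

    @property
    def df_resid(self) -> int:
        return self.reg.df

    @property
    def nobs(self) -> int:
        return self.model.nobs

    def inference(self, method: str = "hk", alpha=None, constraint=None) -> list[InferenceResult]:
        """Per-coefficient inference under the requested method."""
        return metareg_inference(
            self.reg,
            method=method,
            alpha=self.alpha if alpha is None else alpha,
            constraint=self.constraint if constraint is None else constraint,
        )

    def conf_int(self, method: str = "hk", alpha=None) -> np.ndarray:
        rows = self.inference(method, alpha=alpha)
        return np.array([[r.ci_lower, r.ci_upper] for r in rows])

    def to_frame(self) -> pd.DataFrame:
        """Both methods' inference as a tidy table (one row per method x term)."""
        rows = []
        for method in ("conventional", "hk"):
            for r in self.inference(method):
                rows.append(
                    {
                        "method": r.method,
                        "term": r.term,
                        "estimate": r.estimate,
                        "se": r.se,
                        "statistic": r.statistic,
                        "df": r.df,
                        "p": r.p,
                        "ci_lower": r.ci_lower,
                        "ci_upper": r.ci_upper,
                        "tau2": self.tau2.tau2,
                        "k_hat": 1.0 if r.method == "conventional" else r.scale_factor,
                        "degenerate": r.degenerate,
                    }
                )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Aligned-text summary mirroring the conventional-vs-HK comparison."""
        level = 100 * (1 - self.alpha)
        lines = [
            "Random-effects meta-" + ("regression" if len(self.reg.labels) > 1 else "analysis"),
            f"n = {self.nobs} studies, tau2 ({self.tau2.estimator}) = {self.tau2.tau2:.3f}, "
            f"k_hat = H*2 = {self.k_hat:.3f}",
            "",
            f"{'method':<14}{'term':<12}{'estimate':>9}{'se':>8}{'stat':>8}"
            f"{'p':>8}  {int(level)}% CI",
        ]
        for method in ("conventional", "hk"):
            for r in self.inference(method):
                stat = "z" if r.df is None else "t"
                lines.append(
                    f"{r.method:<14}{r.term:<12}{r.estimate:>9.3f}{r.se:>8.3f}"
                    f"{r.statistic:>8.3f}{r.p:>8.3f}  ({r.ci_lower:.3f}; {r.ci_upper:.3f}) [{stat}]"
                )
        if self.constraint != "none":
            lines.append(f"(Hartung-Knapp scale constrained: {self.constraint})")
        return "\n".join(lines)
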