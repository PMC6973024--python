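"""Effect-size computation for meta-analysis inputs.

Converts raw per-study summaries into an effect estimate ``yi`` and its
within-study sampling variance ``vi`` on an analysis scale:

* standardized mean differences (Cohen's *d* with group sizes) are converted
  to Hedges' *g* using the exact small-sample bias correction based on the
  ratio of gamma functions, rather than the common ``1 - 3/(4m - 1)``
  approximation;
* 2x2 frequency tables (events/non-events by group) are converted to log odds
  ratios with the reciprocal-cell-count variance, applying a 0.5 continuity
  correction to all four cells of any table that contains a zero.

A negative log odds ratio means the event was rarer in the first (treated)
group, i.e. a protective treatment effect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd
from scipy.special import gammaln

from .exceptions import InvalidInputError

__all__ = [
    "TwoGroupSummary",
    "FourfoldTable",
    "EffectEstimate",
    "exact_correction_factor",
    "hedges_g",
    "log_odds_ratio",
    "read_two_group_csv",
    "read_fourfold_csv",
    "write_effects_csv",
]


@dataclass(frozen=True)
class TwoGroupSummary:
    """Cohen's d with the two group sample sizes."""

    d: float
    n1: int
    n2: int

    def __post_init__(self) -> None:
        if self.n1 < 2 or self.n2 < 2:
            raise InvalidInputError(
                f"group sizes must be >= 2, got n1={self.n1}, n2={self.n2}"
            )
        if not math.isfinite(self.d):
            raise InvalidInputError(f"d must be finite, got {self.d}")


@dataclass(frozen=True)
class FourfoldTable:
    """2x2 table of counts: (a, b) = events/non-events in group 1, (c, d) in group 2."""

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise InvalidInputError(f"cell {name} must be a nonnegative count, got {v}")

    def transposed_groups(self) -> "FourfoldTable":
        """Swap the two groups (rows), which negates the log odds ratio."""
        return FourfoldTable(self.c, self.d, self.a, self.b)


@dataclass(frozen=True)
class EffectEstimate:
    """One study's effect size ``yi`` and sampling variance ``vi``."""

    yi: float
    vi: float
    scale: str = "raw"

    def __post_init__(self) -> None:
        if not (math.isfinite(self.yi) and math.isfinite(self.vi)):
            raise InvalidInputError(f"non-finite effect estimate ({self.yi}, {self.vi})")
        if self.vi <= 0:
            raise InvalidInputError(f"sampling variance must be > 0, got {self.vi}")


def exact_correction_factor(df: int) -> float:
    """Exact small-sample correction factor J(m) for standardized mean differences.

    J(m) = Gamma(m/2) / (sqrt(m/2) * Gamma((m-1)/2)) with m the degrees of
    freedom of the pooled standard deviation. Computed through log-gamma
    differences so it is stable for large m. J is in (0, 1), increases with
    m, and tends to 1; the familiar approximation is 1 - 3/(4m - 1).

    Parameters
    ----------
    df : int
        Degrees of freedom, m >= 2 (for two groups, m = n1 + n2 - 2).
    """
    if df < 2:
        raise InvalidInputError(f"correction factor needs df >= 2, got {df}")
    m = float(df)
    if m >= 2000.0:
        # the log-gamma difference loses ~1e-9 absolute accuracy for huge m
        # (cancellation of two large values), swamping the true increments;
        # the asymptotic series for Gamma(x+1/2)/Gamma(x) is exact to ~1e-15 here
        x = (m - 1.0) / 2.0
        series = 1.0 - 1.0 / (8 * x) + 1.0 / (128 * x * x) + 5.0 / (1024 * x**3)
        return math.sqrt((m - 1.0) / m) * series
    return math.exp(gammaln(m / 2.0) - gammaln((m - 1.0) / 2.0) - 0.5 * math.log(m / 2.0))


def hedges_g(summary: TwoGroupSummary) -> EffectEstimate:
    """Convert Cohen's d to Hedges' g with the exact bias correction.

    var(d) = (n1+n2)/(n1*n2) + d^2 / (2*(n1+n2)); g = J*d; var(g) = J^2*var(d),
    with J = exact_correction_factor(n1 + n2 - 2).
    """
    n1, n2, d = summary.n1, summary.n2, summary.d
    j = exact_correction_factor(n1 + n2 - 2)
    var_d = (n1 + n2) / (n1 * n2) + d * d / (2.0 * (n1 + n2))
    return EffectEstimate(yi=j * d, vi=j * j * var_d, scale="hedges_g")


def log_odds_ratio(table: FourfoldTable, correction: str = "add_half_if_zero") -> EffectEstimate:
    """Log odds ratio and its variance from a 2x2 table.

    yi = ln(a*d / (b*c)); vi = 1/a + 1/b + 1/c + 1/d. With
    ``correction="add_half_if_zero"`` (default), 0.5 is added to all four
    cells of a table containing any zero; ``correction="none"`` applies no
    correction and rejects zero cells.
    """
    cells = [table.a, table.b, table.c, table.d]
    if correction == "add_half_if_zero":
        if any(c == 0 for c in cells):
            cells = [c + 0.5 for c in cells]
    elif correction != "none":
        raise InvalidInputError(f"unknown continuity correction {correction!r}")
    a, b, c, d = cells
    if min(a, b, c, d) <= 0:
        raise InvalidInputError(
            f"2x2 table has an empty cell after continuity correction: {cells}"
        )
    yi = math.log(a * d / (b * c))
    vi = 1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d
    return EffectEstimate(yi=yi, vi=vi, scale="log_or")


# ---------------------------------------------------------------------------
# CSV helpers


def read_two_group_csv(path) -> pd.DataFrame:
    """Read study, d, n1, n2 rows and return study, yi, vi, scale."""
    df = pd.read_csv(path)
    _require_columns(df, ["study", "d", "n1", "n2"], path)
    rows = [
        hedges_g(TwoGroupSummary(d=float(r.d), n1=int(r.n1), n2=int(r.n2)))
        for r in df.itertuples()
    ]
    return _effects_frame(df["study"], rows)


def read_fourfold_csv(path) -> pd.DataFrame:
    """Read study, a, b, c, d rows and return study, yi, vi, scale."""
    df = pd.read_csv(path)
    _require_columns(df, ["study", "a", "b", "c", "d"], path)
    rows = [
        log_odds_ratio(FourfoldTable(float(r.a), float(r.b), float(r.c), float(r.d)))
        for r in df.itertuples()
    ]
    return _effects_frame(df["study"], rows)


def write_effects_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise InvalidInputError(f"{path}: missing column(s) {missing}")


def _effects_frame(studies, effects) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "study": list(studies),
            "yi": [e.yi for e in effects],
            "vi": [e.vi for e in effects],
            "scale": [e.scale for e in effects],
        }
    )
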