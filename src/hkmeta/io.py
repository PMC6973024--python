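"""Strict readers and writers for per-study tabular data and fitted results.

The reader accepts three input kinds: precomputed effects (``yi``, ``vi``),
two-group standardized mean differences (``d``, ``n1``, ``n2``) and 2x2
tables (``a``..``d``); the latter two are converted on ingestion via
:mod:`hkmeta.effects`. Validation is strict — no silent coercion or row
dropping; every rejection names the offending row and column.

Results serialize to JSON and TSV at full floating precision (numbers are
rounded only in the human-readable text view, to 3 decimals).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import pandas as pd

from .effects import FourfoldTable, TwoGroupSummary, hedges_g, log_odds_ratio
from .exceptions import InvalidInputError

log = logging.getLogger("hkmeta")

__all__ = ["StudyRecord", "Dataset", "read_dataset", "write_results"]

_KIND_COLUMNS = {
    "effects": ["study", "yi", "vi"],
    "two_group": ["study", "d", "n1", "n2"],
    "fourfold": ["study", "a", "b", "c", "d"],
}


@dataclass(frozen=True)
class StudyRecord:
    study: str
    yi: float
    vi: float
    covariates: dict = field(default_factory=dict)


@dataclass(frozen=True)
class Dataset:
    records: list
    source: str = ""
    scale: str = "raw"

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise InvalidInputError(f"{self.source}: need at least 2 studies")
        ids = [r.study for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise InvalidInputError(f"{self.source}: duplicate study id(s) {dup}")
        keys = {tuple(sorted(r.covariates)) for r in self.records}
        if len(keys) > 1:
            raise InvalidInputError(f"{self.source}: records carry differing covariate keys")

    @property
    def covariate_names(self) -> tuple:
        return tuple(sorted(self.records[0].covariates))

    def to_frame(self) -> pd.DataFrame:
        rows = [{"study": r.study, "yi": r.yi, "vi": r.vi, **r.covariates} for r in self.records]
        return pd.DataFrame(rows)

    def arrays(self, covariates=None):
        """(y, v, Z) numpy views; Z is None when no covariates requested."""
        df = self.to_frame()
        names = list(covariates) if covariates else []
        for c in names:
            if c not in df.columns:
                raise InvalidInputError(f"unknown covariate column {c!r}")
        Z = df[names].to_numpy(float) if names else None
        return df["yi"].to_numpy(float), df["vi"].to_numpy(float), Z


def _cell(df_row, col, row_ix, path):
    raw = df_row[col]
    try:
        val = float(raw)
    except (TypeError, ValueError):
        raise InvalidInputError(f"{path}: row {row_ix}, column {col!r}: non-numeric value {raw!r}")
    if isinstance(raw, float) and math.isnan(raw):
        raise InvalidInputError(f"{path}: row {row_ix}, column {col!r}: missing value")
    if not math.isfinite(val):
        raise InvalidInputError(f"{path}: row {row_ix}, column {col!r}: non-finite value {raw!r}")
    return val


def read_dataset(path, kind: str = "effects", covariates=()) -> Dataset:
    """Read a per-study CSV/TSV, converting raw summaries to effect sizes.

    ``covariates`` names extra numeric columns (already dummy-coded for
    categorical moderators) to carry along for meta-regression.
    """
    if kind not in _KIND_COLUMNS:
        raise InvalidInputError(f"unknown input kind {kind!r}; choose from {sorted(_KIND_COLUMNS)}")
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, dtype=object)
    required = _KIND_COLUMNS[kind] + list(covariates)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InvalidInputError(f"{path}: missing column(s) {missing}")

    records, scale = [], "raw"
    for ix, row in df.iterrows():
        study = row["study"]
        if study is None or (isinstance(study, float) and math.isnan(study)):
            raise InvalidInputError(f"{path}: row {ix}: missing study id")
        cov = {c: _cell(row, c, ix, path) for c in covariates}
        if kind == "effects":
            yi = _cell(row, "yi", ix, path)
            vi = _cell(row, "vi", ix, path)
            if vi <= 0:
                raise InvalidInputError(f"{path}: row {ix}, column 'vi': must be > 0, got {vi}")
            scale = str(row["scale"]) if "scale" in df.columns else "raw"
        elif kind == "two_group":
            est = hedges_g(
                TwoGroupSummary(
                    d=_cell(row, "d", ix, path),
                    n1=int(_cell(row, "n1", ix, path)),
                    n2=int(_cell(row, "n2", ix, path)),
                )
            )
            yi, vi, scale = est.yi, est.vi, est.scale
        else:
            est = log_odds_ratio(
                FourfoldTable(*(_cell(row, c, ix, path) for c in "abcd"))
            )
            yi, vi, scale = est.yi, est.vi, est.scale
        records.append(StudyRecord(study=str(study), yi=yi, vi=vi, covariates=cov))
    log.info("read %d studies from %s (kind=%s, scale=%s)", len(records), path, kind, scale)
    return Dataset(records=records, source=str(path), scale=scale)


def write_results(results_frame: pd.DataFrame, path=None, format: str = "json"):
    """Serialize a results table; returns the serialized text.

    JSON keeps full floating precision, so parsing it back reproduces every
    numeric field bit-exactly. The text format rounds to 3 decimals.
    """
    if format == "json":
        # json.dumps uses Python's shortest round-tripping float repr, so a
        # parse of the report reproduces every numeric field bit-exactly
        def _tojson(obj):
            if hasattr(obj, "item"):  # numpy scalar
                return obj.item()
            return str(obj)

        text = json.dumps(results_frame.to_dict(orient="records"), indent=1, default=_tojson)
    elif format == "tsv":
        text = results_frame.to_csv(sep="\t", index=False, float_format="%.17g")
    elif format == "text":
        with pd.option_context("display.float_format", lambda x: f"{x:.3f}"):
            text = results_frame.to_string(index=False)
    else:
        raise InvalidInputError(f"unknown output format {format!r}")
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def results_roundtrip(text: str) -> pd.DataFrame:
    """Parse a JSON report written by :func:`write_results`."""
    return pd.DataFrame(json.loads(text))
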