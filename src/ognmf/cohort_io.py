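"""Cohort table I/O and invertible encoding into a non-negative feature matrix.

A screening cohort is a table of patient records with mixed-type clinical
features — binary status markers (SSN enrolment, gender, hepatitis-B
serology), one categorical demographic (race), and continuous laboratory
values — with arbitrary missingness.  For matrix factorization the table is
encoded into a non-negative target matrix ``X`` together with a binary
observation mask ``M``; the encoding stores enough per-column metadata to be
inverted exactly on every observed cell.

Encoding conventions (the source data's own numeric codebook is not public,
so these are declared conventions):

* binary features map to ``{1, 2}`` — strictly positive, so multiplicative
  NMF updates cannot permanently zero a factor entry;
* race maps to consecutive positive integers ``1..3``;
* continuous labs are min-max scaled to ``[0, 1]`` over their observed
  entries (z-scores would violate non-negativity);
* unobserved cells hold the column's observed mean as a finite placeholder —
  the masked objective never reads them.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FEATURES",
    "CONTINUOUS_FEATURES",
    "FeatureSpec",
    "default_codebook",
    "PatientRecord",
    "CohortTable",
    "ColumnScaling",
    "FeatureMatrix",
    "read_cohort_csv",
    "write_cohort_csv",
    "encode_features",
    "decode_column",
]

#: Canonical feature order.  The account number is an opaque identifier and is
#: excluded from the encoded matrix by default (see :func:`encode_features`).
FEATURES: tuple[str, ...] = (
    "ssn_status",
    "account_number",
    "gender",
    "age",
    "race",
    "tsh",
    "psa",
    "hbsab",
    "hbsag",
    "glu",
    "chol",
    "tg",
    "hdl",
    "ldl",
    "chol_hdl",
)

CONTINUOUS_FEATURES: tuple[str, ...] = (
    "age", "tsh", "psa", "glu", "chol", "tg", "hdl", "ldl", "chol_hdl",
)

#: CSV header spelling for each feature (matching is case-insensitive).
CSV_COLUMNS: Mapping[str, str] = {
    "ssn_status": "SSN",
    "account_number": "ACCOUNT",
    "gender": "GENDER",
    "age": "AGE",
    "race": "RACE",
    "tsh": "TSH",
    "psa": "PSA",
    "hbsab": "HBsAb",
    "hbsag": "HBsAg",
    "glu": "GLU",
    "chol": "CHOL",
    "tg": "TG",
    "hdl": "HDL",
    "ldl": "LDL",
    "chol_hdl": "CHOL_HDL",
}

_UNITS: Mapping[str, str] = {
    "age": "years", "tsh": "mIU/L", "psa": "ng/mL", "glu": "mg/dL",
    "chol": "mg/dL", "tg": "mg/dL", "hdl": "mg/dL", "ldl": "mg/dL",
    "chol_hdl": "ratio",
}


@dataclass(frozen=True)
class FeatureSpec:
    """Kind, units and (for discrete features) the level -> code map."""

    kind: str  # "binary" | "categorical" | "continuous" | "identifier"
    units: str = ""
    levels: Mapping[str, int] | None = None


def default_codebook() -> dict[str, FeatureSpec]:
    """The declared codebook: feature name -> :class:`FeatureSpec`."""
    cb: dict[str, FeatureSpec] = {
        "ssn_status": FeatureSpec("binary", levels={"SSN-": 1, "SSN+": 2}),
        "account_number": FeatureSpec("identifier"),
        "gender": FeatureSpec("binary", levels={"M": 1, "F": 2}),
        "race": FeatureSpec(
            "categorical",
            levels={"chinese_american": 1, "other_asian_american": 2, "other": 3},
        ),
        "hbsab": FeatureSpec("binary", levels={"neg": 1, "pos": 2}),
        "hbsag": FeatureSpec("binary", levels={"neg": 1, "pos": 2}),
    }
    for name in CONTINUOUS_FEATURES:
        cb[name] = FeatureSpec("continuous", units=_UNITS[name])
    return cb


@dataclass
class PatientRecord:
    """One screening participant; any field may be ``None`` (missing)."""

    ssn_status: str | None = None
    account_number: str | None = None
    gender: str | None = None
    age: float | None = None
    race: str | None = None
    tsh: float | None = None
    psa: float | None = None
    hbsab: str | None = None
    hbsag: str | None = None
    glu: float | None = None
    chol: float | None = None
    tg: float | None = None
    hdl: float | None = None
    ldl: float | None = None
    chol_hdl: float | None = None

    def get(self, feature: str):
        return getattr(self, feature)

    def n_observed(self) -> int:
        return sum(self.get(f) is not None for f in FEATURES)


@dataclass
class CohortTable:
    """Ordered patient records plus the codebook that interprets them."""

    records: list[PatientRecord]
    codebook: dict[str, FeatureSpec] = field(default_factory=default_codebook)

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other) -> bool:
        if not isinstance(other, CohortTable):
            return NotImplemented
        return self.records == other.records and self.codebook == other.codebook

    def column(self, feature: str) -> list:
        if feature not in FEATURES:
            raise KeyError(f"unknown feature {feature!r}")
        return [r.get(feature) for r in self.records]

    def validate(self, ratio_rtol: float = 0.05) -> list[str]:
        """Check record-level invariants; returns a list of flag messages.

        Negative lab values raise (they are physically impossible); a
        CHOL/HDL ratio inconsistent with the recorded CHOL and HDL beyond
        ``ratio_rtol`` relative tolerance is flagged, never auto-corrected.
        """
        flags: list[str] = []
        for i, r in enumerate(self.records):
            for name in CONTINUOUS_FEATURES:
                v = r.get(name)
                if v is not None and v < 0:
                    raise ValueError(
                        f"record {i}: negative value {v} for {name}"
                    )
            for name in ("ssn_status", "gender", "race", "hbsab", "hbsag"):
                v = r.get(name)
                spec = self.codebook[name]
                if v is not None and spec.levels and v not in spec.levels:
                    raise ValueError(
                        f"record {i}: unknown level {v!r} for {name}"
                    )
            if r.chol is not None and r.hdl is not None and r.chol_hdl is not None:
                if r.hdl > 0:
                    implied = r.chol / r.hdl
                    if abs(r.chol_hdl - implied) > ratio_rtol * implied:
                        flags.append(
                            f"record {i}: chol_hdl={r.chol_hdl:g} disagrees with "
                            f"chol/hdl={implied:g} beyond {ratio_rtol:.0%}"
                        )
        return flags


# ---------------------------------------------------------------------------
# CSV I/O


def _parse_cell(feature: str, raw, spec: FeatureSpec, row_idx: int):
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return None
    text = str(raw).strip()
    if text == "":
        return None
    if spec.kind == "continuous":
        try:
            return float(text)
        except ValueError:
            raise ValueError(
                f"malformed row {row_idx}: non-numeric value {text!r} "
                f"for column {CSV_COLUMNS[feature]}"
            ) from None
    if spec.kind == "identifier":
        return text
    if spec.levels is not None and text not in spec.levels:
        raise ValueError(
            f"malformed row {row_idx}: unknown level {text!r} "
            f"for column {CSV_COLUMNS[feature]}"
        )
    return text


def read_cohort_csv(
    path: str | Path,
    codebook: Mapping[str, FeatureSpec] | None = None,
) -> CohortTable:
    """Read a cohort CSV into a :class:`CohortTable`.

    The header must consist of (a subset of) the recognized clinical columns;
    an unknown column is rejected by name.  Empty cells become missing
    sentinels (``None``); row order is preserved.
    """
    codebook = dict(codebook) if codebook is not None else default_codebook()
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    lower_to_feature = {v.lower(): k for k, v in CSV_COLUMNS.items()}
    col_map: dict[str, str] = {}
    for col in df.columns:
        feat = lower_to_feature.get(col.strip().lower())
        if feat is None:
            raise ValueError(f"unknown column {col!r} in {path}")
        col_map[col] = feat

    records: list[PatientRecord] = []
    for i, (_, row) in enumerate(df.iterrows()):
        rec = PatientRecord()
        for col, feat in col_map.items():
            setattr(rec, feat, _parse_cell(feat, row[col], codebook[feat], i))
        records.append(rec)
    cohort = CohortTable(records, codebook)
    flags = cohort.validate()
    for msg in flags:
        warnings.warn(msg, stacklevel=2)
    return cohort


def write_cohort_csv(cohort: CohortTable, path: str | Path) -> None:
    """Write a cohort to CSV (inverse of :func:`read_cohort_csv`).

    Missing values become empty cells; an empty cohort yields a header-only
    file.
    """
    rows = []
    for r in cohort.records:
        row = {}
        for feat in FEATURES:
            v = r.get(feat)
            if v is None:
                row[CSV_COLUMNS[feat]] = ""
            elif cohort.codebook[feat].kind == "continuous":
                row[CSV_COLUMNS[feat]] = repr(float(v))
            else:
                row[CSV_COLUMNS[feat]] = str(v)
        rows.append(row)
    df = pd.DataFrame(rows, columns=[CSV_COLUMNS[f] for f in FEATURES])
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Encoding


@dataclass(frozen=True)
class ColumnScaling:
    """Inverse-map metadata for one encoded column.

    Continuous columns store the observed ``lo``/``hi`` of the affine
    min-max map ``encoded = (value - lo) / (hi - lo)``; discrete columns
    store the level -> code map instead.
    """

    kind: str
    lo: float = 0.0
    hi: float = 1.0
    levels: Mapping[str, int] | None = None

    def encode(self, value: float) -> float:
        if self.kind != "continuous":
            raise ValueError("encode() is defined for continuous columns only")
        if self.hi == self.lo:
            return 0.0
        return (value - self.lo) / (self.hi - self.lo)

    def decode(self, encoded: float | np.ndarray) -> float | np.ndarray:
        if self.kind != "continuous":
            raise ValueError("decode() is defined for continuous columns only")
        clipped = np.maximum(encoded, 0.0)
        return np.maximum(self.lo + (self.hi - self.lo) * clipped, 0.0)


@dataclass
class FeatureMatrix:
    """Non-negative target matrix with observation mask and scaling metadata.

    ``X[i, j]`` is meaningful only where ``M[i, j] == 1``; masked cells hold
    the column's observed mean as a placeholder.
    """

    X: np.ndarray
    M: np.ndarray
    columns: list[str]
    scaling: dict[str, ColumnScaling]

    def column_index(self, feature: str) -> int:
        try:
            return self.columns.index(feature)
        except ValueError:
            raise KeyError(f"column {feature!r} not in feature matrix") from None

    def copy(self) -> "FeatureMatrix":
        return FeatureMatrix(
            self.X.copy(), self.M.copy(), list(self.columns), dict(self.scaling)
        )


def encode_features(
    cohort: CohortTable, include_account: bool = False
) -> FeatureMatrix:
    """Encode a cohort into a non-negative matrix ``X`` with mask ``M``.

    Binary features map to {1, 2}, race to consecutive positive integers,
    continuous labs min-max to [0, 1] over observed entries.  The account
    number is an identifier with no plausible signal and is excluded unless
    ``include_account`` is set, in which case it is factorized to consecutive
    positive integers in order of first appearance.

    Raises if the cohort is empty or any encoded column is entirely missing
    (its scaling would be undefined).
    """
    if len(cohort) == 0:
        raise ValueError("cannot encode an empty cohort")
    columns = [
        f for f in FEATURES if include_account or f != "account_number"
    ]
    n, p = len(cohort), len(columns)
    X = np.zeros((n, p))
    M = np.zeros((n, p))
    scaling: dict[str, ColumnScaling] = {}

    for j, feat in enumerate(columns):
        spec = cohort.codebook[feat]
        values = cohort.column(feat)
        observed = [v for v in values if v is not None]
        if not observed:
            raise ValueError(
                f"column {feat!r} is entirely missing; scaling undefined"
            )
        if spec.kind == "continuous":
            lo = float(min(observed))
            hi = float(max(observed))
            sc = ColumnScaling("continuous", lo=lo, hi=hi)
            encoded = [None if v is None else sc.encode(float(v)) for v in values]
        elif spec.kind == "identifier":
            codes: dict[str, int] = {}
            for v in observed:
                codes.setdefault(v, len(codes) + 1)
            sc = ColumnScaling("identifier", levels=codes)
            encoded = [None if v is None else float(codes[v]) for v in values]
        else:
            assert spec.levels is not None
            sc = ColumnScaling(spec.kind, levels=dict(spec.levels))
            encoded = [
                None if v is None else float(spec.levels[v]) for v in values
            ]
        scaling[feat] = sc
        col = np.array([np.nan if e is None else e for e in encoded])
        obs = ~np.isnan(col)
        M[:, j] = obs
        mean = float(col[obs].mean())
        X[:, j] = np.where(obs, col, mean)

    return FeatureMatrix(X=X, M=M, columns=columns, scaling=scaling)


def decode_column(
    fm: FeatureMatrix, Xhat: np.ndarray, column: str
) -> np.ndarray:
    """Map a reconstruction's column back to clinical units.

    Applies the stored inverse affine map for a continuous column; values
    that undershoot the scaled range (e.g. a masked solver dipping slightly
    below 0) are clipped to the column's clinical floor.
    """
    j = fm.column_index(column)
    sc = fm.scaling[column]
    if sc.kind != "continuous":
        raise ValueError(f"column {column!r} is not continuous")
    Xhat = np.asarray(Xhat)
    if Xhat.shape != fm.X.shape:
        raise ValueError(
            f"Xhat shape {Xhat.shape} does not match feature matrix "
            f"shape {fm.X.shape}"
        )
    return sc.decode(Xhat[:, j])
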