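"""Expression-table I/O, replicate averaging and log-ratio normalization.

The analysis pipeline starts from a genes x conditions matrix of strictly
positive expression values.  Two preparation steps render it amenable to
threshold analysis:

1. replicate conditions are collapsed to their per-group *geometric mean*
   (averaging multiplicative noise out in log space), and
2. each gene row is divided by its geometric mean over the remaining
   conditions and log-compressed,

   ``r_ij = log(a_ij) - mean_j log(a_ij)``

so every gene row of the result is centred at zero: negative entries mean
under-expression relative to the gene's typical level, positive entries
over-expression, in log-ratio units of the chosen base.

Both steps are available as plain functions on :class:`ExpressionMatrix`
and as scikit-learn transformers (:class:`ReplicateGeometricMean`,
:class:`LogRatioNormalizer`) for pipeline composition.
"""

from __future__ import annotations

import csv
import logging
import math
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "ReplicateGeometricMean",
    "LogRatioNormalizer",
    "read_expression",
    "write_expression",
    "read_groups",
    "average_replicates",
    "normalize_log",
    "as_expression_matrix",
]

#: accepted spellings of logarithm bases
_LOG_BASES = {
    "e": math.e,
    "natural": math.e,
    "2": 2.0,
    "10": 10.0,
    2: 2.0,
    10: 10.0,
    math.e: math.e,
}


def _resolve_log_base(log_base) -> float:
    try:
        return _LOG_BASES[log_base]
    except (KeyError, TypeError):
        if isinstance(log_base, (int, float)) and log_base > 1:
            return float(log_base)
        raise ValueError(f"unsupported log base: {log_base!r}") from None


def _first_duplicate(ids: Iterable[str]):
    seen = set()
    for x in ids:
        if x in seen:
            return x
        seen.add(x)
    return None


class ExpressionMatrix:
    """A real-valued genes x conditions matrix with unique identifiers.

    Parameters
    ----------
    values : array-like of shape (m, n)
        Expression values; raw (positive) units before normalization,
        log-ratio units after.
    gene_ids, condition_ids : sequences of str
        Unique row and column identifiers, order preserved.
    log_base : float or None
        Base of the logarithm if the matrix holds log-ratio values,
        ``None`` for raw data.  Carried as provenance metadata.
    """

    def __init__(self, values, gene_ids, condition_ids, *, log_base=None):
        values = np.array(values, dtype=float)
        gene_ids = tuple(str(g) for g in gene_ids)
        condition_ids = tuple(str(c) for c in condition_ids)
        if values.ndim != 2:
            raise ValueError("expression values must form a 2-d matrix")
        if values.shape != (len(gene_ids), len(condition_ids)):
            raise ValueError(
                f"shape mismatch: values {values.shape} vs "
                f"{len(gene_ids)} genes x {len(condition_ids)} conditions"
            )
        dup = _first_duplicate(gene_ids)
        if dup is not None:
            raise ValueError(f"duplicate gene id: {dup!r}")
        dup = _first_duplicate(condition_ids)
        if dup is not None:
            raise ValueError(f"duplicate condition id: {dup!r}")
        if not np.all(np.isfinite(values)):
            i, j = map(int, np.argwhere(~np.isfinite(values))[0])
            raise ValueError(
                f"non-finite value at gene {gene_ids[i]!r}, "
                f"condition {condition_ids[j]!r}"
            )
        self.values = values
        self.gene_ids = gene_ids
        self.condition_ids = condition_ids
        self.log_base = log_base

    # -- basic container protocol -------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.gene_ids), columns=list(self.condition_ids)
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, *, log_base=None) -> "ExpressionMatrix":
        return cls(
            frame.to_numpy(dtype=float),
            [str(i) for i in frame.index],
            [str(c) for c in frame.columns],
            log_base=log_base,
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        m, n = self.shape
        units = "raw" if self.log_base is None else f"log-ratio (base {self.log_base:g})"
        return f"<ExpressionMatrix {m} genes x {n} conditions, {units}>"


def as_expression_matrix(X) -> ExpressionMatrix:
    """Coerce an array, DataFrame or ExpressionMatrix to ExpressionMatrix."""
    if isinstance(X, ExpressionMatrix):
        return X
    if isinstance(X, pd.DataFrame):
        return ExpressionMatrix.from_frame(X)
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a 2-d matrix")
    m, n = arr.shape
    return ExpressionMatrix(
        arr, [f"g{i + 1}" for i in range(m)], [f"c{j + 1}" for j in range(n)]
    )


def _require_positive(em: ExpressionMatrix) -> None:
    bad = np.argwhere(em.values <= 0)
    if bad.size:
        i, j = map(int, bad[0])
        raise ValueError(
            f"non-positive expression value {em.values[i, j]!r} at gene "
            f"{em.gene_ids[i]!r}, condition {em.condition_ids[j]!r}; geometric "
            "means and logarithms require strictly positive data"
        )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_DIALECTS = {"tsv": "\t", "csv": ","}


def read_expression(path, dialect: str = "tsv") -> ExpressionMatrix:
    """Read a delimited expression table.

    The first row is a header of condition ids (its first cell, naming the
    gene-id column, is ignored); the first column holds gene ids; every other
    cell must parse as a number with a ``.`` decimal separator.
    """
    try:
        sep = _DIALECTS[dialect]
    except KeyError:
        raise ValueError(f"unknown dialect {dialect!r}; expected 'tsv' or 'csv'")
    with open(path, "r", encoding="utf-8", newline="") as fh:
        rows = list(csv.reader(fh, delimiter=sep))
    rows = [r for r in rows if r]  # drop blank lines
    if not rows:
        raise ValueError(f"{path}: empty expression table")
    header = rows[0]
    condition_ids = [c.strip() for c in header[1:]]
    dup = _first_duplicate(condition_ids)
    if dup is not None:
        raise ValueError(f"{path}: duplicate condition id in header: {dup!r}")
    n = len(condition_ids)
    gene_ids: list[str] = []
    values = np.empty((len(rows) - 1, n), dtype=float)
    for r, row in enumerate(rows[1:], start=2):
        if len(row) != n + 1:
            raise ValueError(
                f"{path}: ragged row at line {r}: expected {n + 1} fields, "
                f"found {len(row)}"
            )
        gene_ids.append(row[0].strip())
        for j, cell in enumerate(row[1:]):
            try:
                values[r - 2, j] = float(cell)
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric cell {cell!r} at line {r} "
                    f"(gene {row[0].strip()!r}), column {condition_ids[j]!r}"
                ) from None
    dup = _first_duplicate(gene_ids)
    if dup is not None:
        raise ValueError(f"{path}: duplicate gene id: {dup!r}")
    return ExpressionMatrix(values, gene_ids, condition_ids)


def write_expression(
    em: ExpressionMatrix, path, dialect: str = "tsv", float_format: str = "%.12g"
) -> None:
    """Write an expression table readable back by :func:`read_expression`."""
    try:
        sep = _DIALECTS[dialect]
    except KeyError:
        raise ValueError(f"unknown dialect {dialect!r}; expected 'tsv' or 'csv'")
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=sep, lineterminator="\n")
        writer.writerow(["gene_id", *em.condition_ids])
        for g, row in zip(em.gene_ids, em.values):
            writer.writerow([g, *(float_format % v for v in row)])


def read_groups(path) -> dict[str, str]:
    """Read a two-column TSV mapping condition_id -> replicate-group label."""
    mapping: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(
                    f"{path}: line {lineno}: expected 'condition<TAB>group', "
                    f"got {line!r}"
                )
            cond, group = (p.strip() for p in parts)
            if cond in mapping:
                raise ValueError(f"{path}: condition {cond!r} mapped twice")
            mapping[cond] = group
    if not mapping:
        raise ValueError(f"{path}: empty replicate-group table")
    return mapping


# ---------------------------------------------------------------------------
# Core math (shared by functions and transformers)
# ---------------------------------------------------------------------------


def _group_order(condition_ids: Iterable[str], groups: Mapping[str, str]) -> list[str]:
    """Group labels in order of first appearance among the conditions."""
    order: list[str] = []
    for c in condition_ids:
        g = groups[c]
        if g not in order:
            order.append(g)
    return order


def _geomean_by_group(values: np.ndarray, condition_ids, groups) -> tuple[np.ndarray, list[str]]:
    # computed in log space: exp(mean(log x)) avoids overflow of the product
    labels = _group_order(condition_ids, groups)
    logs = np.log(values)
    out = np.empty((values.shape[0], len(labels)))
    for k, lab in enumerate(labels):
        cols = [j for j, c in enumerate(condition_ids) if groups[c] == lab]
        out[:, k] = np.exp(logs[:, cols].mean(axis=1))
    return out, labels


def _log_ratio(values: np.ndarray, base: float) -> np.ndarray:
    logs = np.log(values) / math.log(base)
    return logs - logs.mean(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------


def average_replicates(
    raw: ExpressionMatrix, groups: Mapping[str, str]
) -> ExpressionMatrix:
    """Collapse replicate conditions to their per-group geometric mean.

    Every condition of ``raw`` must be mapped by ``groups``; output columns
    follow the order of first appearance of each group label.  Singleton
    groups pass values through unchanged.
    """
    missing = [c for c in raw.condition_ids if c not in groups]
    if missing:
        raise ValueError(f"conditions missing from replicate groups: {missing}")
    _require_positive(raw)
    out, labels = _geomean_by_group(raw.values, raw.condition_ids, groups)
    return ExpressionMatrix(out, raw.gene_ids, labels, log_base=raw.log_base)


def normalize_log(
    avg: ExpressionMatrix, log_base="e", pseudocount: float = 0.0
) -> ExpressionMatrix:
    """Row-wise geometric-mean log normalization.

    Each entry becomes ``log_b(a_ij / geomean_j(a_i.))``; every output row
    sums to zero, and multiplying a raw row by a positive constant leaves
    its normalized row unchanged.  ``pseudocount`` (default 0, i.e. off)
    is added to every entry before taking logs; its use is logged because
    it changes the ratios.
    """
    base = _resolve_log_base(log_base)
    em = avg
    if pseudocount:
        if pseudocount < 0:
            raise ValueError("pseudocount must be nonnegative")
        logger.info("normalize_log: applying pseudocount %g", pseudocount)
        em = ExpressionMatrix(
            avg.values + pseudocount, avg.gene_ids, avg.condition_ids
        )
    _require_positive(em)
    r = _log_ratio(em.values, base)
    return ExpressionMatrix(r, em.gene_ids, em.condition_ids, log_base=base)


# ---------------------------------------------------------------------------
# scikit-learn transformers
# ---------------------------------------------------------------------------


class ReplicateGeometricMean(TransformerMixin, BaseEstimator):
    """Transformer collapsing replicate columns to geometric means.

    Parameters
    ----------
    groups : mapping or None
        Maps column name (DataFrame input) or column index (array input)
        to a replicate-group label.  ``None`` treats every column as its
        own group (identity).
    """

    def __init__(self, groups=None):
        self.groups = groups

    def fit(self, X, y=None):
        X = self._to_frame(X)
        groups = self._resolved_groups(X)
        missing = [c for c in X.columns if c not in groups]
        if missing:
            raise ValueError(f"conditions missing from replicate groups: {missing}")
        self.n_features_in_ = X.shape[1]
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.group_labels_ = _group_order(list(X.columns), groups)
        return self

    def transform(self, X):
        X = self._to_frame(X)
        em = ExpressionMatrix.from_frame(X)
        _require_positive(em)
        out, labels = _geomean_by_group(
            em.values, list(X.columns), self._resolved_groups(X)
        )
        return pd.DataFrame(out, index=X.index, columns=labels)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.group_labels_, dtype=object)

    def _to_frame(self, X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 2:
            raise ValueError("expected a 2-d matrix")
        return pd.DataFrame(arr, columns=list(range(arr.shape[1])))

    def _resolved_groups(self, X: pd.DataFrame) -> Mapping:
        if self.groups is None:
            return {c: c for c in X.columns}
        return self.groups


class LogRatioNormalizer(TransformerMixin, BaseEstimator):
    """Transformer applying row-wise geometric-mean log normalization."""

    def __init__(self, log_base="e", pseudocount: float = 0.0):
        self.log_base = log_base
        self.pseudocount = pseudocount

    def fit(self, X, y=None):
        arr = self._values(X)
        self.n_features_in_ = arr.shape[1]
        self.base_ = _resolve_log_base(self.log_base)
        return self

    def transform(self, X):
        base = _resolve_log_base(self.log_base)
        arr = self._values(X) + float(self.pseudocount)
        if np.any(arr <= 0):
            raise ValueError(
                "log-ratio normalization requires strictly positive values"
            )
        r = _log_ratio(arr, base)
        if isinstance(X, pd.DataFrame):
            return pd.DataFrame(r, index=X.index, columns=X.columns)
        return r

    @staticmethod
    def _values(X) -> np.ndarray:
        arr = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
        if arr.ndim != 2:
            raise ValueError("expected a 2-d matrix")
        return arr
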