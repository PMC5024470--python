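"""Threshold sweeps: from a real matrix to a sequence of concept lattices.

A normalized expression matrix is explored in two directions.  For
under-expression a threshold phi <= 0 marks cell (g, c) when X_gc <= phi;
for over-expression a threshold >= 0 marks it when X_gc >= phi.  The
concepts of the thresholded boolean context are exactly the
inclusion-maximal biclusters whose max-norm (under) or min-norm (over)
clears the threshold.  Sweeping the threshold over the values observed in
the data yields a nested sequence of contexts and hence a sequence of
lattices; the number of concepts per threshold traces a curve whose
sudden slope changes flag thresholds where the lattice reorganizes, and
the range of thresholds over which a given intent keeps a nonempty extent
measures the *persistence* (robustness) of that bicluster.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator, BiclusterMixin

from .context import (
    Concept,
    ConceptLattice,
    FormalContext,
    build_lattice,
    lattice_from_json,
    lattice_to_json,
)
from .expression import ExpressionMatrix, as_expression_matrix

__all__ = [
    "LatticeSequence",
    "PersistenceRecord",
    "KFCABiclusterer",
    "binarize_under",
    "binarize_over",
    "bicluster_norm",
    "threshold_grid",
    "sweep",
    "concept_count_curve",
    "slope_change_points",
    "persistence",
    "persistence_report",
    "sequence_to_json",
    "sequence_from_json",
]

_DIRECTIONS = ("under", "over")


def _check_direction(direction: str) -> str:
    if direction not in _DIRECTIONS:
        raise ValueError(f"direction must be one of {_DIRECTIONS}, got {direction!r}")
    return direction


@dataclass
class LatticeSequence:
    """Threshold-indexed sequence of lattices for one sweep direction."""

    direction: str
    thresholds: tuple[float, ...]
    lattices: dict[float, ConceptLattice]
    source: ExpressionMatrix | None = None

    def __post_init__(self):
        _check_direction(self.direction)
        ts = tuple(float(t) for t in self.thresholds)
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError("thresholds must be strictly increasing")
        self.thresholds = ts

    def __len__(self) -> int:
        return len(self.thresholds)

    def lattice_at(self, threshold: float) -> ConceptLattice:
        return self.lattices[float(threshold)]


@dataclass
class PersistenceRecord:
    """Presence of an intent across the sweep.

    ``interval``/``span`` are None when the intent never occurs; span is 0
    when it occurs at a single threshold.
    """

    intent: frozenset
    present_at: tuple[float, ...]
    interval: tuple[float, float] | None
    span: float | None


# ---------------------------------------------------------------------------
# Binarization and norms
# ---------------------------------------------------------------------------


def binarize_under(X, phi: float) -> FormalContext:
    """Boolean context marking cells with value <= phi (under-expression)."""
    em = as_expression_matrix(X)
    if phi > 0:
        warnings.warn(
            f"under-expression threshold {phi} is positive; "
            "under sweeps normally use thresholds <= 0",
            stacklevel=2,
        )
    return FormalContext(em.gene_ids, em.condition_ids, em.values <= phi)


def binarize_over(X, phi: float) -> FormalContext:
    """Boolean context marking cells with value >= phi (over-expression)."""
    em = as_expression_matrix(X)
    if phi < 0:
        warnings.warn(
            f"over-expression threshold {phi} is negative; "
            "over sweeps normally use thresholds >= 0",
            stacklevel=2,
        )
    return FormalContext(em.gene_ids, em.condition_ids, em.values >= phi)


def bicluster_norm(X, concept: Concept, direction: str) -> float:
    """Max (under) or min (over) entry of the bicluster's submatrix.

    Every non-degenerate concept of an under-phi (over-phi) context has
    norm <= phi (>= phi): the defining property of the thresholded
    bicluster families.
    """
    _check_direction(direction)
    em = as_expression_matrix(X)
    if not concept.extent or not concept.intent:
        raise ValueError("bicluster norm is undefined for an empty extent or intent")
    gi = [em.gene_ids.index(g) for g in sorted(concept.extent)]
    cj = [em.condition_ids.index(c) for c in sorted(concept.intent)]
    sub = em.values[np.ix_(gi, cj)]
    return float(sub.max() if direction == "under" else sub.min())


# ---------------------------------------------------------------------------
# Grids and sweeps
# ---------------------------------------------------------------------------


def threshold_grid(
    X, direction: str, max_points: int | None = None, include_zero: bool = False
) -> list[float]:
    """Observed matrix values on the sweep's side of zero, sorted ascending.

    With ``max_points`` the grid is decimated histogram-style: the in-range
    values are split into ``max_points`` equal-width bins and each nonempty
    bin contributes its value closest to the bin centre.  ``include_zero``
    appends a synthetic 0.0 threshold (the richest lattice of the sweep)
    even when 0 is not an observed value.
    """
    _check_direction(direction)
    em = as_expression_matrix(X)
    vals = np.unique(em.values)
    vals = vals[vals <= 0] if direction == "under" else vals[vals >= 0]
    grid = [float(v) for v in vals]
    if not grid:
        warnings.warn(
            f"no observed values on the {direction} side of 0; empty grid",
            stacklevel=2,
        )
        return [0.0] if include_zero else []
    if max_points is not None and max_points > 0 and len(grid) > max_points:
        lo, hi = grid[0], grid[-1]
        edges = np.linspace(lo, hi, max_points + 1)
        centers = (edges[:-1] + edges[1:]) / 2
        arr = np.asarray(grid)
        # right-closed last bin so the maximum lands in bin max_points-1
        bins = np.clip(np.searchsorted(edges, arr, side="right") - 1, 0, max_points - 1)
        keep = []
        for b in range(max_points):
            members = arr[bins == b]
            if members.size:
                keep.append(float(members[np.argmin(np.abs(members - centers[b]))]))
        grid = sorted(set(keep))
    if include_zero and 0.0 not in grid:
        grid.append(0.0)
        grid.sort()
    return grid


def sweep(X, direction: str, grid: Sequence[float]) -> LatticeSequence:
    """Build one lattice per grid threshold.

    Along an under sweep the incidence grows with the threshold (contexts
    are nested increasing); along an over sweep it shrinks.
    """
    _check_direction(direction)
    em = as_expression_matrix(X)
    grid = [float(t) for t in grid]
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("grid must be strictly increasing")
    binarize = binarize_under if direction == "under" else binarize_over
    lattices = {t: build_lattice(binarize(em, t)) for t in grid}
    return LatticeSequence(direction, tuple(grid), lattices, source=em)


def concept_count_curve(seq: LatticeSequence) -> list[tuple[float, int]]:
    """(threshold, number of concepts) pairs in grid order."""
    return [(t, len(seq.lattices[t])) for t in seq.thresholds]


def slope_change_points(curve: Sequence[tuple[float, int]], k: int) -> list[float]:
    """Thresholds where the count curve bends the most.

    Ranks interior grid points by the absolute second difference of the
    concept count with respect to grid index (largest first, ties broken
    toward the threshold nearer 0) and returns the top ``k``.
    """
    if len(curve) < 3:
        raise ValueError("slope-change detection needs a curve of >= 3 points")
    if k < 1:
        raise ValueError("k must be a positive integer")
    ts = [t for t, _ in curve]
    counts = [c for _, c in curve]
    scored = []
    for i in range(1, len(curve) - 1):
        d2 = counts[i + 1] - 2 * counts[i] + counts[i - 1]
        scored.append((-abs(d2), abs(ts[i]), ts[i]))
    scored.sort()
    return [t for _, _, t in scored[:k]]


def persistence(seq: LatticeSequence, intent: Iterable[str]) -> PersistenceRecord:
    """Range of thresholds over which a bicluster with this intent exists.

    Presence at a threshold means some concept of that lattice has exactly
    this intent and a nonempty extent.
    """
    intent = frozenset(intent)
    present = []
    for t in seq.thresholds:
        lat = seq.lattices[t]
        for c in lat.concepts:
            if c.intent == intent and c.extent:
                present.append(t)
                break
    if not present:
        return PersistenceRecord(intent, (), None, None)
    return PersistenceRecord(
        intent, tuple(present), (present[0], present[-1]), present[-1] - present[0]
    )


def persistence_report(seq: LatticeSequence) -> list[PersistenceRecord]:
    """Persistence of every intent occurring anywhere in the sweep.

    Sorted by descending span, then intent size, then lexicographically —
    the most robust biclusters first.
    """
    intents = set()
    for t in seq.thresholds:
        for c in seq.lattices[t].concepts:
            if c.extent:
                intents.add(c.intent)
    records = [persistence(seq, i) for i in intents]
    records.sort(key=lambda r: (-(r.span or 0.0), len(r.intent), sorted(r.intent)))
    return records


# ---------------------------------------------------------------------------
# JSON round-trip
# ---------------------------------------------------------------------------


def sequence_to_json(seq: LatticeSequence) -> dict:
    return {
        "direction": seq.direction,
        "thresholds": list(seq.thresholds),
        "lattices": {repr(t): lattice_to_json(seq.lattices[t]) for t in seq.thresholds},
    }


def sequence_from_json(d: dict) -> LatticeSequence:
    thresholds = tuple(float(t) for t in d["thresholds"])
    lattices = {
        float(t): lattice_from_json(lat) for t, lat in d["lattices"].items()
    }
    return LatticeSequence(d["direction"], thresholds, lattices)


# ---------------------------------------------------------------------------
# scikit-learn estimator
# ---------------------------------------------------------------------------


class KFCABiclusterer(BiclusterMixin, BaseEstimator):
    """Threshold-sweep lattice biclustering of a real-valued matrix.

    ``fit(X)`` runs a sweep in one direction (rows of X are genes/objects,
    columns conditions/attributes) and exposes the full sequence of
    lattices.  The sklearn bicluster interface (``rows_``, ``columns_``)
    reports the non-degenerate concepts of the *reference* lattice —
    by default the final threshold of the sweep, the closest to 0 for an
    under sweep.

    Parameters
    ----------
    direction : {"under", "over"}
        Sweep direction: thresholds <= 0 marking values below (under) or
        >= 0 marking values above (over).
    grid : "auto" or sequence of floats
        Thresholds to visit; "auto" uses the observed values on the
        relevant side of zero.
    max_points : int or None
        Histogram-style decimation of an auto grid.
    include_zero : bool
        Append a threshold at exactly 0 to an auto grid.
    reference_threshold : float or None
        Threshold whose lattice defines ``rows_``/``columns_``; None
        picks the grid value nearest 0.

    Attributes
    ----------
    sequence_ : LatticeSequence
    thresholds_ : tuple of float
    counts_ : list of (threshold, concept count)
    rows_, columns_ : bool arrays, one row per non-degenerate concept of
        the reference lattice.
    """

    def __init__(
        self,
        direction: str = "under",
        grid="auto",
        max_points: int | None = None,
        include_zero: bool = True,
        reference_threshold: float | None = None,
    ):
        self.direction = direction
        self.grid = grid
        self.max_points = max_points
        self.include_zero = include_zero
        self.reference_threshold = reference_threshold

    def fit(self, X, y=None):
        _check_direction(self.direction)
        em = as_expression_matrix(X)
        if isinstance(self.grid, str):
            if self.grid != "auto":
                raise ValueError(f"grid must be 'auto' or a sequence, got {self.grid!r}")
            grid = threshold_grid(
                em, self.direction, self.max_points, include_zero=self.include_zero
            )
        else:
            grid = sorted(float(t) for t in self.grid)
        if not grid:
            raise ValueError("empty threshold grid; nothing to sweep")
        self.n_features_in_ = em.shape[1]
        self.sequence_ = sweep(em, self.direction, grid)
        self.thresholds_ = self.sequence_.thresholds
        self.counts_ = concept_count_curve(self.sequence_)
        if self.reference_threshold is not None:
            ref = float(self.reference_threshold)
            if ref not in self.sequence_.lattices:
                raise ValueError(f"reference threshold {ref} not in the grid")
        else:
            ref = min(self.thresholds_, key=abs)
        self.reference_threshold_ = ref
        lat = self.sequence_.lattices[ref]
        gidx = {g: i for i, g in enumerate(em.gene_ids)}
        cidx = {c: j for j, c in enumerate(em.condition_ids)}
        keep = [c for c in lat.concepts if c.extent and c.intent]
        rows = np.zeros((len(keep), em.shape[0]), dtype=bool)
        cols = np.zeros((len(keep), em.shape[1]), dtype=bool)
        for b, c in enumerate(keep):
            rows[b, [gidx[g] for g in c.extent]] = True
            cols[b, [cidx[x] for x in c.intent]] = True
        self.rows_ = rows
        self.columns_ = cols
        return self
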