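"""Synthetic expression matrices with planted transcription modules.

The generator follows the additive transcription-module picture: a module
k couples a sparse set of genes (a boolean promoter vector, column of P)
with a sparse set of conditions (a boolean activity vector, column of A)
at a signed intensity level; the expression matrix is the sum of the
module outer products plus i.i.d. Gaussian noise,

    X = sum_k level_k * (P_.k outer A_.k) + Noise.

Negative levels plant under-expression modules, positive levels
over-expression, so the same generator grounds both sweep directions.
Cells covered by several modules carry the *sum* of their levels.  A
binary variant (counts of covering modules, levels ignored) is exposed as
well.  Recovery of a planted module by a sweep is scored by the best
Jaccard match over all concepts of all lattices.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np

from .expression import ExpressionMatrix
from .sweep import LatticeSequence

__all__ = [
    "ModulePlan",
    "RecoveryScore",
    "generate_plan",
    "generate_expression",
    "score_recovery",
]


@dataclass
class ModulePlan:
    """Planted-module ground truth: membership matrices, levels, noise."""

    m: int
    n: int
    p: int
    P: np.ndarray  # bool, m x p: gene membership per module
    A: np.ndarray  # bool, n x p: condition membership per module
    levels: np.ndarray  # float, p: signed module intensities
    noise_sd: float
    seed: int

    def __post_init__(self):
        self.P = np.asarray(self.P, dtype=bool)
        self.A = np.asarray(self.A, dtype=bool)
        self.levels = np.asarray(self.levels, dtype=float)
        if self.P.shape != (self.m, self.p) or self.A.shape != (self.n, self.p):
            raise ValueError("P/A shapes do not match (m, p)/(n, p)")
        if self.levels.shape != (self.p,):
            raise ValueError("levels must have one entry per module")
        if not np.all(np.isfinite(self.levels)):
            raise ValueError("levels must be finite")
        if self.p and (not self.P.any(axis=0).all() or not self.A.any(axis=0).all()):
            raise ValueError("every module must have nonempty gene and condition sets")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")

    def module_genes(self, k: int) -> frozenset:
        return frozenset(f"g{i + 1}" for i in np.flatnonzero(self.P[:, k]))

    def module_conditions(self, k: int) -> frozenset:
        return frozenset(f"c{j + 1}" for j in np.flatnonzero(self.A[:, k]))


@dataclass
class RecoveryScore:
    """Best concept match for one planted module over a whole sweep."""

    module: int
    jaccard: float  # product of extent and intent Jaccard (default metric)
    extent_jaccard: float
    intent_jaccard: float
    threshold: float


def generate_plan(
    m: int,
    n: int,
    p: int,
    sparsity: float,
    level_range: tuple[float, float],
    noise_sd: float,
    seed: int,
    disjoint: bool = False,
) -> ModulePlan:
    """Draw a seeded module plan.

    Each module activates ``ceil(sparsity * m)`` genes and
    ``ceil(sparsity * n)`` conditions, positions drawn without replacement
    (PCG64 generator, pinned via ``numpy.random.default_rng``); module
    levels are uniform over ``level_range``.  With ``disjoint=True``
    modules share no genes and no conditions (requires enough room), the
    regime in which swept lattices recover planted modules exactly.
    """
    if m < 1 or n < 1 or p < 1:
        raise ValueError("m, n, p must all be >= 1")
    if not 0 < sparsity < 1:
        raise ValueError("sparsity must lie strictly between 0 and 1")
    kg, kc = ceil(sparsity * m), ceil(sparsity * n)
    if kg == 0 or kc == 0:
        raise ValueError("sparsity too small: a module would be empty")
    rng = np.random.default_rng(seed)
    P = np.zeros((m, p), dtype=bool)
    A = np.zeros((n, p), dtype=bool)
    if disjoint:
        if p * kg > m or p * kc > n:
            raise ValueError(
                "disjoint modules do not fit: need "
                f"{p}x{kg} gene and {p}x{kc} condition slots in {m}x{n}"
            )
        gpool = rng.permutation(m)
        cpool = rng.permutation(n)
        for k in range(p):
            P[gpool[k * kg : (k + 1) * kg], k] = True
            A[cpool[k * kc : (k + 1) * kc], k] = True
    else:
        for k in range(p):
            P[rng.choice(m, size=kg, replace=False), k] = True
            A[rng.choice(n, size=kc, replace=False), k] = True
    lo, hi = level_range
    levels = rng.uniform(lo, hi, size=p)
    return ModulePlan(m, n, p, P, A, levels, float(noise_sd), int(seed))


def generate_expression(plan: ModulePlan, mode: str = "weighted") -> ExpressionMatrix:
    """Realize a plan as an expression matrix.

    ``mode="weighted"`` (default) sums level-weighted module blocks plus
    Gaussian noise; ``mode="binary"`` returns the count of modules
    covering each cell (levels and noise ignored) — the two generative
    conventions, aggregation of discretized activities vs. weighted
    factors, exposed side by side.
    """
    if mode == "binary":
        X = (plan.P.astype(int) @ plan.A.astype(int).T).astype(float)
    elif mode == "weighted":
        X = np.zeros((plan.m, plan.n))
        for k in range(plan.p):
            X += plan.levels[k] * np.outer(plan.P[:, k], plan.A[:, k])
        if plan.noise_sd > 0:
            # noise stream decoupled from the plan draw for reproducibility
            rng = np.random.default_rng([plan.seed, 1])
            X += rng.normal(0.0, plan.noise_sd, size=X.shape)
    else:
        raise ValueError(f"mode must be 'weighted' or 'binary', got {mode!r}")
    genes = [f"g{i + 1}" for i in range(plan.m)]
    conditions = [f"c{j + 1}" for j in range(plan.n)]
    return ExpressionMatrix(X, genes, conditions)


def _jaccard(a: frozenset, b: frozenset) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def score_recovery(
    plan: ModulePlan, seq: LatticeSequence, metric: str = "product"
) -> list[RecoveryScore]:
    """Best Jaccard match of each planted module over a swept sequence.

    The default metric multiplies extent- and intent-Jaccard (both sides
    must match); ``"min"`` and ``"mean"`` variants are available.
    """
    if not seq.thresholds:
        raise ValueError("empty lattice sequence")
    combine = {
        "product": lambda e, i: e * i,
        "min": min,
        "mean": lambda e, i: (e + i) / 2.0,
    }.get(metric)
    if combine is None:
        raise ValueError(f"unknown metric {metric!r}")
    scores = []
    for k in range(plan.p):
        genes, conds = plan.module_genes(k), plan.module_conditions(k)
        best = RecoveryScore(k, 0.0, 0.0, 0.0, seq.thresholds[0])
        for t in seq.thresholds:
            for c in seq.lattices[t].concepts:
                ej = _jaccard(frozenset(c.extent), genes)
                ij = _jaccard(frozenset(c.intent), conds)
                s = combine(ej, ij)
                if s > best.jaccard:
                    best = RecoveryScore(k, s, ej, ij, t)
        scores.append(best)
    return scores
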