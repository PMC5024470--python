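"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the library's enumeration/order code:
concepts by closing every subset with plain Python loops, covers by
boolean-matrix transitive reduction, so the fast paths are checked
against slow, obviously-correct ones.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pytest

from kfca.context import Concept, FormalContext

logging.getLogger("kfca").setLevel(logging.ERROR)  # silence degenerate-row notes


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------


def oracle_up(ctx: FormalContext, gene_set) -> frozenset:
    """Per-condition loop: conditions related to every gene of the set."""
    out = []
    for j, c in enumerate(ctx.conditions):
        if all(ctx.incidence[ctx.genes.index(g), j] for g in gene_set):
            out.append(c)
    return frozenset(out)


def oracle_down(ctx: FormalContext, condition_set) -> frozenset:
    out = []
    for i, g in enumerate(ctx.genes):
        if all(ctx.incidence[i, ctx.conditions.index(c)] for c in condition_set):
            out.append(g)
    return frozenset(out)


def oracle_concepts(ctx: FormalContext, dimension: str = "conditions") -> set[Concept]:
    """All concepts by closing every subset of one universe."""
    out = set()
    if dimension == "conditions":
        for r in range(len(ctx.conditions) + 1):
            for y in itertools.combinations(ctx.conditions, r):
                a = oracle_down(ctx, y)
                out.add(Concept(a, oracle_up(ctx, a)))
    elif dimension == "genes":
        for r in range(len(ctx.genes) + 1):
            for x in itertools.combinations(ctx.genes, r):
                b = oracle_up(ctx, x)
                out.add(Concept(oracle_down(ctx, b), b))
    else:
        raise ValueError(dimension)
    return out


def oracle_covers(concepts) -> set[tuple[int, int]]:
    """Transitive reduction of <= via boolean matrix composition.

    (i, j) is a cover iff i < j and there is no k with i < k < j.
    """
    concepts = list(concepts)
    nc = len(concepts)
    le = np.zeros((nc, nc), dtype=bool)
    for i, ci in enumerate(concepts):
        for j, cj in enumerate(concepts):
            le[i, j] = ci.extent <= cj.extent
    strict = le & ~np.eye(nc, dtype=bool)
    via = (strict.astype(int) @ strict.astype(int)) > 0
    covers = strict & ~via
    return {(i, j) for i, j in zip(*np.nonzero(covers))}


def random_context(seed: int, m: int, n: int, density: float = 0.5) -> FormalContext:
    rng = np.random.default_rng(seed)
    inc = rng.random((m, n)) < density
    return FormalContext(
        [f"g{i + 1}" for i in range(m)], [f"c{j + 1}" for j in range(n)], inc
    )


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def fig1_context() -> FormalContext:
    """A small boolean table with three parallel sublattices.

    Its lattice has seven concepts; ({g6},{c5,c6}) and ({g4,g5,g6},{c5})
    are concepts with ({g6},{c5,c6}) below the other.  g3 is marked under
    no condition and c3 marks no gene (degenerate labels).
    """
    genes = [f"g{i}" for i in range(1, 7)]
    conditions = [f"c{j}" for j in range(1, 7)]
    rows = [
        "100000",  # g1: c1
        "010000",  # g2: c2
        "000000",  # g3: nothing
        "000010",  # g4: c5
        "000110",  # g5: c4, c5
        "000011",  # g6: c5, c6
    ]
    inc = np.array([[ch == "1" for ch in row] for row in rows])
    return FormalContext(genes, conditions, inc)


@pytest.fixture()
def small_matrix():
    """The 3x3 real matrix used for hand-checked binarizations."""
    from kfca.expression import ExpressionMatrix

    return ExpressionMatrix(
        [[-2, 1, -1], [0, -3, 2], [-1, -1, -1]],
        ["g1", "g2", "g3"],
        ["c1", "c2", "c3"],
    )
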