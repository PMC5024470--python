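"""Formal contexts, concepts and concept lattices.

A *formal context* is a triple (G, C, I): a set of genes (objects), a set
of conditions (attributes) and a boolean incidence relation "gene g is
marked under condition c".  The polar (Galois) operators

    up(x)   = { c | every g in x is marked under c }
    down(y) = { g | g is marked under every c in y }

pair a gene set with the conditions they all share, and dually.  A
*formal concept* is a pair (extent, intent) that the polars map onto each
other; equivalently an inclusion-maximal all-ones submatrix of I, i.e. a
bicluster.  Concepts ordered by extent inclusion form a complete lattice,
built here with its Hasse cover relation and *reduced labeling*: each gene
labels the smallest concept containing it, each condition the largest, so
an extent is recovered as the union of gene labels from a node downward
and an intent as the union of condition labels upward.

Enumeration uses NextClosure over the condition dimension (conditions are
few in expression data), producing concepts in lectic order; a brute-force
closure-of-all-subsets oracle is kept in the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "FormalContext",
    "Concept",
    "ConceptLattice",
    "leq",
    "enumerate_concepts",
    "build_lattice",
    "reduced_labeling",
    "parallel_sublattices",
    "read_cxt",
    "write_cxt",
    "context_to_json",
    "context_from_json",
    "lattice_to_json",
    "lattice_from_json",
    "contranominal",
]


@dataclass(frozen=True)
class Concept:
    """A bicluster: gene set (extent) and condition set (intent).

    Within one context the extent determines the intent and vice versa,
    so equality on the pair coincides with extensional equality.
    """

    extent: frozenset
    intent: frozenset

    def __le__(self, other: "Concept") -> bool:
        return self.extent <= other.extent


def leq(c1: Concept, c2: Concept) -> bool:
    """Concept order: c1 <= c2 iff extent(c1) is included in extent(c2)."""
    return c1.extent <= c2.extent


class FormalContext:
    """Boolean incidence over ordered gene and condition universes."""

    def __init__(self, genes: Sequence[str], conditions: Sequence[str], incidence):
        self.genes = tuple(str(g) for g in genes)
        self.conditions = tuple(str(c) for c in conditions)
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene ids in context")
        if len(set(self.conditions)) != len(self.conditions):
            raise ValueError("duplicate condition ids in context")
        inc = np.array(incidence, dtype=bool)
        if inc.shape != (len(self.genes), len(self.conditions)):
            raise ValueError(
                f"incidence shape {inc.shape} does not match "
                f"{len(self.genes)} genes x {len(self.conditions)} conditions"
            )
        self.incidence = inc
        self._g_index = {g: i for i, g in enumerate(self.genes)}
        self._c_index = {c: j for j, c in enumerate(self.conditions)}

    @property
    def shape(self) -> tuple[int, int]:
        return self.incidence.shape

    # -- index/mask helpers -------------------------------------------

    def _gene_mask(self, gene_set: Iterable[str]) -> np.ndarray:
        mask = np.zeros(len(self.genes), dtype=bool)
        for g in gene_set:
            try:
                mask[self._g_index[g]] = True
            except KeyError:
                raise KeyError(f"unknown gene id: {g!r}") from None
        return mask

    def _condition_mask(self, condition_set: Iterable[str]) -> np.ndarray:
        mask = np.zeros(len(self.conditions), dtype=bool)
        for c in condition_set:
            try:
                mask[self._c_index[c]] = True
            except KeyError:
                raise KeyError(f"unknown condition id: {c!r}") from None
        return mask

    def _up_mask(self, gmask: np.ndarray) -> np.ndarray:
        if gmask.any():
            return self.incidence[gmask].all(axis=0)
        return np.ones(len(self.conditions), dtype=bool)

    def _down_mask(self, cmask: np.ndarray) -> np.ndarray:
        if cmask.any():
            return self.incidence[:, cmask].all(axis=1)
        return np.ones(len(self.genes), dtype=bool)

    def _genes_of(self, gmask: np.ndarray) -> frozenset:
        return frozenset(g for g, m in zip(self.genes, gmask) if m)

    def _conditions_of(self, cmask: np.ndarray) -> frozenset:
        return frozenset(c for c, m in zip(self.conditions, cmask) if m)

    # -- polar operators ----------------------------------------------

    def up(self, gene_set: Iterable[str]) -> frozenset:
        """Conditions shared by every gene of ``gene_set`` (all of C if empty)."""
        return self._conditions_of(self._up_mask(self._gene_mask(gene_set)))

    def down(self, condition_set: Iterable[str]) -> frozenset:
        """Genes marked under every condition of ``condition_set``."""
        return self._genes_of(self._down_mask(self._condition_mask(condition_set)))

    def close_extent(self, gene_set: Iterable[str]) -> Concept:
        """Smallest concept whose extent contains ``gene_set``."""
        b = self._up_mask(self._gene_mask(gene_set))
        a = self._down_mask(b)
        return Concept(self._genes_of(a), self._conditions_of(b))

    def close_intent(self, condition_set: Iterable[str]) -> Concept:
        """Largest concept whose intent contains ``condition_set``."""
        a = self._down_mask(self._condition_mask(condition_set))
        b = self._up_mask(a)
        return Concept(self._genes_of(a), self._conditions_of(b))


# ---------------------------------------------------------------------------
# Enumeration (NextClosure over the condition dimension)
# ---------------------------------------------------------------------------


def _closure_cmask(ctx: FormalContext, cmask: np.ndarray) -> np.ndarray:
    return ctx._up_mask(ctx._down_mask(cmask))


def _next_intent(ctx: FormalContext, intent: np.ndarray) -> np.ndarray | None:
    """Lectically next closed intent after ``intent``, or None when done."""
    n = len(ctx.conditions)
    b = intent.copy()
    for i in range(n - 1, -1, -1):
        if b[i]:
            b[i] = False
        else:
            cand = b.copy()
            cand[i] = True
            closed = _closure_cmask(ctx, cand)
            # canonicity: no new element below i
            if not (closed[:i] & ~b[:i]).any():
                return closed
    return None


def _intent_masks(ctx: FormalContext) -> list[np.ndarray]:
    cur = _closure_cmask(ctx, np.zeros(len(ctx.conditions), dtype=bool))
    masks = [cur]
    while True:
        cur = _next_intent(ctx, cur)
        if cur is None:
            break
        masks.append(cur)
    return masks


def enumerate_concepts(ctx: FormalContext) -> list[Concept]:
    """All formal concepts of ``ctx`` in canonical order.

    Canonical order is (intent size, lexicographic intent index tuple);
    the result always contains the top (maximal extent) and bottom
    (maximal intent) concepts and no duplicates.
    """
    masks = _intent_masks(ctx)
    masks.sort(key=lambda m: (int(m.sum()), tuple(np.flatnonzero(m))))
    out = []
    for cm in masks:
        a = ctx._down_mask(cm)
        out.append(Concept(ctx._genes_of(a), ctx._conditions_of(cm)))
    return out


# ---------------------------------------------------------------------------
# Lattice
# ---------------------------------------------------------------------------


@dataclass
class ConceptLattice:
    """A concept set with Hasse covers, top/bottom and reduced labels.

    ``covers`` holds index pairs ``(lo, hi)`` with concept ``lo`` covered
    by (immediately below) concept ``hi``.  ``own_genes[i]`` are the genes
    whose smallest containing concept is ``i``; ``own_conditions[i]`` the
    conditions whose largest containing concept is ``i``.
    """

    concepts: tuple[Concept, ...]
    covers: tuple[tuple[int, int], ...]
    top: int
    bottom: int
    own_genes: tuple[frozenset, ...]
    own_conditions: tuple[frozenset, ...]
    _index: dict = field(default=None, repr=False, compare=False)

    def __len__(self) -> int:
        return len(self.concepts)

    def index_of(self, concept: Concept) -> int:
        if self._index is None:
            self._index = {c.extent: i for i, c in enumerate(self.concepts)}
        return self._index[concept.extent]

    def cover_graph(self) -> nx.DiGraph:
        """Directed Hasse diagram, edges pointing upward (lo -> hi)."""
        g = nx.DiGraph()
        g.add_nodes_from(range(len(self.concepts)))
        g.add_edges_from(self.covers)
        return g

    def downset(self, i: int) -> set[int]:
        """Indices of all concepts <= concept i (including i)."""
        g = self.cover_graph().reverse(copy=False)
        return {i} | nx.descendants(g, i)

    def upset(self, i: int) -> set[int]:
        """Indices of all concepts >= concept i (including i)."""
        return {i} | nx.descendants(self.cover_graph(), i)

    def meet(self, i: int, j: int) -> int:
        """Index of the greatest lower bound of concepts i and j."""
        common = self.downset(i) & self.downset(j)
        return max(common, key=lambda k: len(self.concepts[k].extent))

    def join(self, i: int, j: int) -> int:
        common = self.upset(i) & self.upset(j)
        return max(common, key=lambda k: len(self.concepts[k].intent))


def _extent_bitset(concept: Concept, g_index: dict) -> int:
    bits = 0
    for g in concept.extent:
        bits |= 1 << g_index[g]
    return bits


def build_lattice(ctx: FormalContext) -> ConceptLattice:
    """Enumerate concepts and assemble order, covers and reduced labels."""
    concepts = enumerate_concepts(ctx)
    nconc = len(concepts)
    g_index, c_index = ctx._g_index, ctx._c_index
    ext_bits = [_extent_bitset(c, g_index) for c in concepts]
    sizes = [len(c.extent) for c in concepts]

    # covers: process candidate supersets by ascending extent size; a
    # superset is a cover unless it lies above an already-found cover
    order_by_size = sorted(range(nconc), key=lambda i: sizes[i])
    covers: list[tuple[int, int]] = []
    for i in range(nconc):
        ei = ext_bits[i]
        chosen: list[int] = []
        for j in order_by_size:
            if sizes[j] <= sizes[i] or (ei & ext_bits[j]) != ei or j == i:
                continue
            if any((ext_bits[k] & ext_bits[j]) == ext_bits[k] for k in chosen):
                continue
            chosen.append(j)
        covers.extend((i, j) for j in sorted(chosen))

    top = max(range(nconc), key=lambda i: sizes[i])
    bottom = max(range(nconc), key=lambda i: len(concepts[i].intent))

    # reduced labeling via object/attribute concepts: up({g}) is just g's
    # incidence row (already closed), down({c}) the column, so genes group
    # by row pattern and conditions by column pattern
    by_intent = {c.intent: i for i, c in enumerate(concepts)}
    by_extent = {c.extent: i for i, c in enumerate(concepts)}
    own_genes = [set() for _ in range(nconc)]
    own_conditions = [set() for _ in range(nconc)]
    empty_rows = 0
    for g in ctx.genes:
        row = ctx.incidence[ctx._g_index[g]]
        if not row.any():
            empty_rows += 1
        own_genes[by_intent[ctx._conditions_of(row)]].add(g)
    empty_cols = 0
    for c in ctx.conditions:
        col = ctx.incidence[:, ctx._c_index[c]]
        if not col.any():
            empty_cols += 1
        own_conditions[by_extent[ctx._genes_of(col)]].add(c)
    if empty_rows:
        logger.warning(
            "%d gene(s) are marked under no condition; they label the top concept",
            empty_rows,
        )
    if empty_cols:
        logger.warning(
            "%d condition(s) mark no gene; they label the bottom concept", empty_cols
        )

    return ConceptLattice(
        concepts=tuple(concepts),
        covers=tuple(covers),
        top=top,
        bottom=bottom,
        own_genes=tuple(frozenset(s) for s in own_genes),
        own_conditions=tuple(frozenset(s) for s in own_conditions),
    )


def reduced_labeling(lat: ConceptLattice) -> tuple[dict, dict]:
    """Reduced labels as dicts concept-index -> own genes / own conditions."""
    return (
        {i: s for i, s in enumerate(lat.own_genes) if s},
        {i: s for i, s in enumerate(lat.own_conditions) if s},
    )


def parallel_sublattices(lat: ConceptLattice) -> list[list[Concept]]:
    """Groups of concepts incomparable with the rest except via top/bottom.

    Computed as connected components of the cover graph with the top and
    bottom concepts removed; each component is sorted by canonical concept
    index, components ordered by their smallest member.
    """
    if len(lat.concepts) <= 2:
        return []
    g = lat.cover_graph().to_undirected()
    g.remove_nodes_from({lat.top, lat.bottom})
    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: c[0])
    return [[lat.concepts[i] for i in comp] for comp in comps]


# ---------------------------------------------------------------------------
# I/O: Burmeister .cxt and JSON
# ---------------------------------------------------------------------------


def read_cxt(path) -> FormalContext:
    """Read a Burmeister-format context file."""
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    body = [ln for ln in lines if ln.strip() != ""]
    if not body or body[0].strip() != "B":
        raise ValueError(f"{path}: not a Burmeister context (missing 'B' header)")
    try:
        m, n = int(body[1]), int(body[2])
    except (IndexError, ValueError):
        raise ValueError(f"{path}: malformed object/attribute counts") from None
    names = body[3 : 3 + m + n]
    rows = body[3 + m + n : 3 + m + n + m]
    if len(names) != m + n or len(rows) != m:
        raise ValueError(f"{path}: truncated context body")
    genes, conditions = names[:m], names[m:]
    inc = np.zeros((m, n), dtype=bool)
    for i, row in enumerate(rows):
        if len(row) != n or any(ch not in ".Xx" for ch in row):
            raise ValueError(f"{path}: bad incidence row {i + 1}: {row!r}")
        inc[i] = [ch in "Xx" for ch in row]
    return FormalContext(genes, conditions, inc)


def write_cxt(ctx: FormalContext, path) -> None:
    m, n = ctx.shape
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("B\n\n")
        fh.write(f"{m}\n{n}\n\n")
        for g in ctx.genes:
            fh.write(g + "\n")
        for c in ctx.conditions:
            fh.write(c + "\n")
        for row in ctx.incidence:
            fh.write("".join("X" if v else "." for v in row) + "\n")


def context_to_json(ctx: FormalContext) -> dict:
    return {
        "genes": list(ctx.genes),
        "conditions": list(ctx.conditions),
        "incidence": ["".join("1" if v else "0" for v in row) for row in ctx.incidence],
    }


def context_from_json(d: dict) -> FormalContext:
    inc = np.array(
        [[ch == "1" for ch in row] for row in d["incidence"]], dtype=bool
    ).reshape(len(d["genes"]), len(d["conditions"]))
    return FormalContext(d["genes"], d["conditions"], inc)


def lattice_to_json(lat: ConceptLattice) -> dict:
    return {
        "concepts": [
            {
                "id": i,
                "extent": sorted(c.extent),
                "intent": sorted(c.intent),
                "own_genes": sorted(lat.own_genes[i]),
                "own_conditions": sorted(lat.own_conditions[i]),
            }
            for i, c in enumerate(lat.concepts)
        ],
        "covers": [list(e) for e in lat.covers],
        "top": lat.top,
        "bottom": lat.bottom,
    }


def lattice_from_json(d: dict) -> ConceptLattice:
    concepts = tuple(
        Concept(frozenset(c["extent"]), frozenset(c["intent"])) for c in d["concepts"]
    )
    return ConceptLattice(
        concepts=concepts,
        covers=tuple((int(a), int(b)) for a, b in d["covers"]),
        top=int(d["top"]),
        bottom=int(d["bottom"]),
        own_genes=tuple(frozenset(c["own_genes"]) for c in d["concepts"]),
        own_conditions=tuple(frozenset(c["own_conditions"]) for c in d["concepts"]),
    )


def contranominal(names: Sequence[str]) -> FormalContext:
    """The contranominal scale (M, M, !=); its lattice is the 2^|M| powerset."""
    n = len(names)
    return FormalContext(names, names, ~np.eye(n, dtype=bool))
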