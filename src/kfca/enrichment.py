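"""Hypergeometric gene-set enrichment of bicluster extents.

Given a catalogue mapping genes to annotation terms (e.g. GO), each term
found in a bicluster's gene set is scored with the hypergeometric tail
probabilities: drawing n genes (the extent) from a universe of N genes of
which K carry the term,

    p_enrich  = P[X >= k]      (over-representation)
    p_deplete = P[X <= k]      (depletion)

for the observed overlap k.  p-values are floored at double-precision
resolution (no exact zero is ever reported) and adjusted for multiplicity
with the Benjamini-Hochberg step-up procedure.  Annotations are taken as
a flat table — no ontology-graph propagation is performed.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .context import Concept
from .sweep import LatticeSequence

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationTable",
    "EnrichmentResult",
    "read_annotations",
    "write_annotations",
    "hypergeometric_p",
    "enrich_concept",
    "bh_adjust",
    "term_index",
    "gene_index",
    "write_enrichment_csv",
]

#: smallest reported p-value (double-precision resolution)
P_FLOOR = float(np.finfo(float).epsneg)  # 1.11e-16


@dataclass
class AnnotationTable:
    """Flat gene -> terms catalogue with optional term metadata."""

    gene_to_terms: dict[str, frozenset]
    term_info: dict[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self):
        self.gene_to_terms = {
            g: frozenset(ts) for g, ts in self.gene_to_terms.items()
        }
        for ts in self.gene_to_terms.values():
            for t in ts:
                if t not in self.term_info:
                    logger.debug("term %r has no metadata; creating empty entry", t)
                    self.term_info[t] = ("", "other")

    @property
    def terms(self) -> set[str]:
        out = set()
        for ts in self.gene_to_terms.values():
            out |= ts
        return out

    def carriers(self, term: str) -> frozenset:
        return frozenset(g for g, ts in self.gene_to_terms.items() if term in ts)


@dataclass
class EnrichmentResult:
    """One term scored against one bicluster extent."""

    concept: Concept
    term: str
    name: str
    namespace: str
    k: int  # annotated genes inside the extent
    K: int  # annotated genes in the universe
    n: int  # extent size (within the universe)
    N: int  # universe size
    p_enrich: float
    p_deplete: float
    q_value: float | None
    genes: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_annotations(path, dialect: str = "tsv2col") -> AnnotationTable:
    """Read a gene->term table.

    ``tsv2col``: one ``gene<TAB>term`` pair per line.  ``gaf``: GAF 2.x,
    using column 2 (object id) and column 5 (term id); '!' comment lines
    are skipped.  Duplicate pairs collapse under set semantics.
    """
    pairs: set[tuple[str, str]] = set()
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if dialect == "gaf":
                if line.startswith("!"):
                    continue
                cols = line.split("\t")
                if len(cols) < 5:
                    raise ValueError(
                        f"{path}: line {lineno}: GAF record has {len(cols)} "
                        "columns, need >= 5"
                    )
                pairs.add((cols[1].strip(), cols[4].strip()))
            elif dialect == "tsv2col":
                cols = line.split("\t")
                if len(cols) != 2:
                    raise ValueError(
                        f"{path}: line {lineno}: expected 'gene<TAB>term', "
                        f"got {line!r}"
                    )
                pairs.add((cols[0].strip(), cols[1].strip()))
            else:
                raise ValueError(f"unknown annotation dialect {dialect!r}")
    if not pairs:
        warnings.warn(f"{path}: empty annotation table", stacklevel=2)
    gene_to_terms: dict[str, set] = {}
    for g, t in pairs:
        gene_to_terms.setdefault(g, set()).add(t)
    return AnnotationTable({g: frozenset(ts) for g, ts in gene_to_terms.items()})


def write_annotations(ann: AnnotationTable, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in sorted(ann.gene_to_terms):
            for t in sorted(ann.gene_to_terms[g]):
                fh.write(f"{g}\t{t}\n")


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------


def _check_counts(k: int, K: int, n: int, N: int) -> None:
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"invalid counts: K={K}, n={n} must lie in 0..N={N}")
    if not (max(0, K + n - N) <= k <= min(K, n)):
        raise ValueError(
            f"overlap k={k} outside hypergeometric support "
            f"[{max(0, K + n - N)}, {min(K, n)}] for K={K}, n={n}, N={N}"
        )


def hypergeometric_p(k: int, K: int, n: int, N: int) -> tuple[float, float]:
    """Hypergeometric tail probabilities (enrichment, depletion).

    X ~ Hypergeometric(N, K, n): the overlap between a random n-subset and
    a fixed K-subset of an N-universe.  Returns ``(P[X >= k], P[X <= k])``,
    each floored at double-precision resolution and capped at 1.
    """
    _check_counts(k, K, n, N)
    rv = hypergeom(N, K, n)
    p_enrich = float(rv.sf(k - 1))
    p_deplete = float(rv.cdf(k))
    clip = lambda p: min(1.0, max(P_FLOOR, p))
    return clip(p_enrich), clip(p_deplete)


def bh_adjust(pvalues) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return [float(x) for x in q]


def enrich_concept(
    concept: Concept,
    ann: AnnotationTable,
    universe: str = "all_genes",
    universe_genes=None,
) -> list[EnrichmentResult]:
    """Score every term represented in a bicluster's extent.

    ``universe="all_genes"`` tests against the supplied ``universe_genes``
    (typically all genes of the expression matrix); ``"annotated_genes"``
    restricts the universe to genes carrying at least one term.  Results
    are sorted by ascending enrichment p-value (ties by term id) and carry
    BH-adjusted q-values computed across the returned terms.
    """
    if not concept.extent:
        warnings.warn("empty extent; no enrichment computed", stacklevel=2)
        return []
    if universe == "all_genes":
        if universe_genes is None:
            raise ValueError("universe='all_genes' requires universe_genes")
        uni = frozenset(universe_genes)
    elif universe == "annotated_genes":
        uni = frozenset(ann.gene_to_terms)
        if universe_genes is not None:
            uni &= frozenset(universe_genes)
    else:
        raise ValueError(
            f"universe must be 'all_genes' or 'annotated_genes', got {universe!r}"
        )
    if not uni:
        raise ValueError("empty gene universe")
    extent = frozenset(concept.extent) & uni
    N, n = len(uni), len(extent)
    results: list[EnrichmentResult] = []
    for term in sorted(ann.terms):
        carriers = ann.carriers(term) & uni
        hits = carriers & extent
        if not hits:
            continue
        k, K = len(hits), len(carriers)
        p_e, p_d = hypergeometric_p(k, K, n, N)
        name, namespace = ann.term_info.get(term, ("", "other"))
        results.append(
            EnrichmentResult(
                concept, term, name, namespace, k, K, n, N, p_e, p_d, None,
                genes=tuple(sorted(hits)),
            )
        )
    results.sort(key=lambda r: (r.p_enrich, r.term))
    qs = bh_adjust([r.p_enrich for r in results])
    for r, q in zip(results, qs):
        r.q_value = q
    return results


# ---------------------------------------------------------------------------
# Indexing a sweep by term / by gene
# ---------------------------------------------------------------------------


def term_index(
    seq: LatticeSequence, ann: AnnotationTable
) -> dict[str, list[tuple[float, list[int]]]]:
    """For each term, the concepts whose extents contain a carrier gene.

    Returns term -> list of (threshold, sorted concept indices); terms
    with no carrier among any extent are absent.
    """
    carriers = {t: ann.carriers(t) for t in sorted(ann.terms)}
    index: dict[str, list[tuple[float, list[int]]]] = {}
    for t in seq.thresholds:
        lat = seq.lattices[t]
        for term, cset in carriers.items():
            ids = [
                i for i, c in enumerate(lat.concepts) if c.extent & cset
            ]
            if ids:
                index.setdefault(term, []).append((t, ids))
    return index


def gene_index(seq: LatticeSequence) -> dict[str, list[tuple[float, int]]]:
    """Per gene, the concept whose own-gene label holds it at each threshold."""
    index: dict[str, list[tuple[float, int]]] = {}
    for t in seq.thresholds:
        lat = seq.lattices[t]
        for i, own in enumerate(lat.own_genes):
            for g in own:
                index.setdefault(g, []).append((t, i))
    return index


_CSV_COLUMNS = [
    "threshold", "concept_id", "term", "name", "namespace",
    "k", "K", "n", "N", "p_enrich", "p_deplete", "q_value", "probesets",
]


def write_enrichment_csv(rows, path) -> None:
    """Write (threshold, concept_id, EnrichmentResult) triples as CSV."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(_CSV_COLUMNS)
        for threshold, concept_id, r in rows:
            writer.writerow(
                [
                    repr(float(threshold)), concept_id, r.term, r.name, r.namespace,
                    r.k, r.K, r.n, r.N,
                    "%.6e" % r.p_enrich, "%.6e" % r.p_deplete,
                    "%.6e" % r.q_value if r.q_value is not None else "",
                    ";".join(r.genes),
                ]
            )
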