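"""Fixed-silhouette lattice layout and exporters.

Every lattice of a sweep is drawn over the silhouette of the concept
lattice of a (virtual) contranominal scale on the condition set: the
powerset of conditions arranged in |C|+1 rows, row 1 the empty intent at
the top, row k+1 holding all intents of size k (up to C(|C|, k) slots),
the bottom row the full condition set.  Because a concept is placed purely
by its intent, a bicluster with a given condition set occupies identical
coordinates in every frame of the sweep — the property that makes
frame-by-frame exploration readable.  Within a row, subsets sit at their
colexicographic rank, centred horizontally; this ordering is a stated
convention (any fixed deterministic rule preserves the guarantee).

Nodes are annotated with the intent's condition names and the count of
*own* genes (those labelling exactly that node under reduced labeling).
"""

from __future__ import annotations

import json
from math import comb
from typing import Iterable, Sequence
from xml.sax.saxutils import escape

import networkx as nx

from .context import ConceptLattice

__all__ = [
    "SilhouetteLayout",
    "silhouette_positions",
    "layout_lattice",
    "export",
    "to_dot",
    "to_graphml",
    "to_json",
    "to_svg",
]

#: hard cap on conditions; beyond this the 2^|C| silhouette is unusable
MAX_CONDITIONS = 20
#: positions are materialized eagerly only below this size
_MATERIALIZE_LIMIT = 14


class SilhouetteLayout:
    """Coordinates for every condition subset on the contranominal silhouette.

    ``position(subset)`` returns ``(x, y)`` with ``y = |subset| + 1`` (row
    index, row 1 on top) and ``x`` the colex rank of the subset within its
    row, centred so each row spans symmetrically around 0 with unit
    spacing.
    """

    def __init__(self, conditions: Sequence[str]):
        self.conditions = tuple(str(c) for c in conditions)
        if len(set(self.conditions)) != len(self.conditions):
            raise ValueError("duplicate condition ids in silhouette")
        if not 1 <= len(self.conditions) <= MAX_CONDITIONS:
            raise ValueError(
                f"silhouette supports 1..{MAX_CONDITIONS} conditions, got "
                f"{len(self.conditions)}; consider a pre-processing stage that "
                "groups conditions into fewer composite ones"
            )
        self._index = {c: i for i, c in enumerate(self.conditions)}
        self._positions = None

    @property
    def rows(self) -> int:
        """Total number of rows, top and bottom included: |C| + 1."""
        return len(self.conditions) + 1

    def row_size(self, row: int) -> int:
        """Maximum number of slots in a row (binomial coefficient)."""
        if not 1 <= row <= self.rows:
            raise ValueError(f"row must be in 1..{self.rows}")
        return comb(len(self.conditions), row - 1)

    def position(self, subset: Iterable[str]) -> tuple[float, int]:
        try:
            idx = sorted(self._index[c] for c in subset)
        except KeyError as e:
            raise ValueError(
                f"condition {e.args[0]!r} is not part of this silhouette"
            ) from None
        if len(idx) != len(set(idx)):
            raise ValueError("subset contains duplicate conditions")
        k = len(idx)
        rank = sum(comb(i, j + 1) for j, i in enumerate(idx))  # colex rank
        total = comb(len(self.conditions), k)
        return (rank - (total - 1) / 2.0, k + 1)

    @property
    def positions(self) -> dict[frozenset, tuple[float, int]]:
        """All 2^|C| subset positions (materialized lazily, small |C| only)."""
        if self._positions is None:
            n = len(self.conditions)
            if n > _MATERIALIZE_LIMIT:
                raise ValueError(
                    f"refusing to materialize 2^{n} positions; use position()"
                )
            pos = {}
            for bits in range(1 << n):
                subset = frozenset(
                    self.conditions[i] for i in range(n) if bits >> i & 1
                )
                pos[subset] = self.position(subset)
            self._positions = pos
        return self._positions


def silhouette_positions(conditions: Sequence[str]) -> SilhouetteLayout:
    """Fixed drawing silhouette for a condition universe."""
    return SilhouetteLayout(conditions)


def layout_lattice(
    lat: ConceptLattice, sil: SilhouetteLayout
) -> dict[int, tuple[float, int]]:
    """Place each concept of a lattice at its intent's silhouette position.

    Returns a map concept-index -> (x, y).  Raises if a concept's intent
    mentions a condition foreign to the silhouette.  Because placement
    depends on the intent only, a shared intent gets identical coordinates
    in every lattice of a sequence.
    """
    return {i: sil.position(c.intent) for i, c in enumerate(lat.concepts)}


# ---------------------------------------------------------------------------
# Exporters (all deterministic: stable node/edge ordering)
# ---------------------------------------------------------------------------


def _node_label(lat: ConceptLattice, i: int) -> str:
    intent = ",".join(sorted(lat.concepts[i].intent))
    return "{%s}\\n+%d genes" % (intent, len(lat.own_genes[i]))


def to_dot(lat: ConceptLattice, layout: dict[int, tuple[float, int]]) -> str:
    """Graphviz DOT with fixed positions (pos=...!); edges point upward."""
    lines = ["digraph lattice {", "  node [shape=circle];"]
    for i in range(len(lat.concepts)):
        x, y = layout[i]
        # silhouette rows grow downward; DOT y grows upward
        lines.append(
            f'  n{i} [label="{_node_label(lat, i)}", pos="{x:g},{-y}!"];'
        )
    for lo, hi in sorted(lat.covers):
        lines.append(f"  n{lo} -> n{hi};")
    lines.append("}")
    return "\n".join(lines) + "\n"


def to_graphml(lat: ConceptLattice, layout: dict[int, tuple[float, int]]) -> str:
    g = nx.DiGraph()
    for i, c in enumerate(lat.concepts):
        x, y = layout[i]
        g.add_node(
            i,
            intent=",".join(sorted(c.intent)),
            own_genes=len(lat.own_genes[i]),
            x=float(x),
            y=float(y),
        )
    g.add_edges_from(sorted(lat.covers))
    return "\n".join(nx.generate_graphml(g)) + "\n"


def to_json(lat: ConceptLattice, layout: dict[int, tuple[float, int]]) -> str:
    from .context import lattice_to_json

    d = lattice_to_json(lat)
    for node in d["concepts"]:
        x, y = layout[node["id"]]
        node["x"], node["y"] = float(x), int(y)
    return json.dumps(d, indent=2, sort_keys=True) + "\n"


def to_svg(
    lat: ConceptLattice,
    layout: dict[int, tuple[float, int]],
    *,
    cell: float = 80.0,
    node_floor: float = 6.0,
    node_scale: float = 1.5,
) -> str:
    """Static SVG rendering; node radius grows linearly with own-gene count."""
    xs = [layout[i][0] for i in range(len(lat.concepts))]
    ys = [layout[i][1] for i in range(len(lat.concepts))]
    x0, y0 = min(xs), min(ys)
    width = (max(xs) - x0 + 2) * cell
    height = (max(ys) - y0 + 2) * cell

    def pt(i):
        x, y = layout[i]
        return ((x - x0 + 1) * cell, (y - y0 + 1) * cell)

    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width:g}" '
        f'height="{height:g}" viewBox="0 0 {width:g} {height:g}">'
    ]
    for lo, hi in sorted(lat.covers):
        (x1, y1), (x2, y2) = pt(lo), pt(hi)
        parts.append(
            f'<line x1="{x1:g}" y1="{y1:g}" x2="{x2:g}" y2="{y2:g}" '
            'stroke="#999" stroke-width="1"/>'
        )
    for i in range(len(lat.concepts)):
        x, y = pt(i)
        r = node_floor + node_scale * len(lat.own_genes[i]) ** 0.5
        label = escape(
            "{%s} +%d" % (",".join(sorted(lat.concepts[i].intent)), len(lat.own_genes[i]))
        )
        parts.append(
            f'<circle cx="{x:g}" cy="{y:g}" r="{r:g}" fill="#7fb3d5" '
            'stroke="#2c3e50"/>'
        )
        parts.append(
            f'<text x="{x:g}" y="{y - r - 3:g}" font-size="9" '
            f'text-anchor="middle">{label}</text>'
        )
    parts.append("</svg>")
    return "\n".join(parts) + "\n"


_RENDERERS = {"dot": to_dot, "graphml": to_graphml, "json": to_json, "svg": to_svg}


def export(
    lat: ConceptLattice,
    layout: dict[int, tuple[float, int]],
    format: str,
    path=None,
) -> str:
    """Render a laid-out lattice to dot/graphml/json/svg.

    Returns the rendered text; writes it to ``path`` when given.  Output
    is byte-identical across re-runs for identical inputs.
    """
    try:
        renderer = _RENDERERS[format]
    except KeyError:
        raise ValueError(
            f"unknown format {format!r}; choose from {sorted(_RENDERERS)}"
        ) from None
    text = renderer(lat, layout)
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
    return text
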