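# Methods

## Model and procedure

The object of analysis is a gene-expression matrix X ∈ ℝ^m×n, genes by
conditions.  The pipeline has four stages.

**1. Contextualization.**  Raw expression values must be strictly
positive.  Replicate conditions are collapsed to their per-group
geometric mean (computed as exp of the mean of logs, which cannot
overflow), then each gene row is normalized by its geometric mean over
the n remaining conditions and log-compressed:
r_ij = log a_ij − (1/n) Σ_k log a_ik.  Every normalized row sums to
exactly zero (checked to 1e-9·n) and is invariant to per-gene positive
scaling, so r_ij measures deviation from the gene's own typical level,
not absolute abundance.  The log base defaults to natural log, is
configurable (e, 2, 10), and is carried on the output as metadata,
because threshold magnitudes are base-dependent and must not be compared
across bases.  Zeros or negative raw values are a hard error; an explicit
nonnegative pseudocount may be supplied and its use is logged.  Replicate
averaging precedes normalization (the composition is asserted against a
straight-line recomputation in the tests).

**2. Thresholding.**  For a threshold φ ≤ 0 the under-expression context
marks (g, c) when r_gc ≤ φ; for ϕ ≥ 0 the over-expression context marks
r_gc ≥ ϕ.  Comparisons are closed (≤/≥) and exact on the stored floats —
grid values are taken from the data itself, so equality is
well-defined.  The concepts of the thresholded boolean context coincide
with the inclusion-maximal biclusters whose max-norm (under) or min-norm
(over) clears the threshold; `bicluster_norm` verifies this equivalence
on every swept lattice in the test suite.  At φ = ϕ = 0 the two
incidences tile the matrix and overlap exactly on zero cells.

**3. Sweep.**  The threshold grid is the set of observed values on the
relevant side of 0, optionally decimated histogram-style: equal-width
bins over the in-range values, each nonempty bin represented by its value
closest to the bin centre.  A threshold at exactly 0 is appended by
default even when 0 is not observed (flagged as synthetic); the
`threshold_grid` function itself returns observed values only unless
asked.  Contexts are nested along the sweep (growing with φ for under,
shrinking with ϕ for over); each lattice is nevertheless enumerated
independently — correctness over incremental cleverness, and the
enumeration is cheap at the condition counts this layout can display.

**4. Reading.**  Concept enumeration uses NextClosure in lectic order
over the condition dimension (n ≪ m in expression data; the closure of a
condition set costs one O(m·n) boolean reduction).  Output order is
canonical: intent size, then lexicographic intent.  Covers are computed
by a minimal-superset scan over extent bitsets; top is the concept with
extent G, bottom the one with maximal intent.  Reduced labeling assigns
each gene to the concept closing {g} (equivalently: its incidence row,
which is already a closed intent) and each condition to the concept
closing {c}.  A gene marked under no condition therefore labels the *top*
concept and a condition marking no gene labels the *bottom*; both are
logged.  This is forced by the reading rule — the extent of a concept
must equal the union of gene labels over its down-set, which would fail
under any other assignment of degenerate rows.  Parallel sublattices are
reported as connected components of the cover graph with top and bottom
removed; components may in pathological contexts touch in other ways, so
they are reported as graph components and nothing stronger is claimed.

## Visualization

Frames are drawn over the silhouette of the contranominal-scale lattice
on the condition set: row k+1 (row 1 at the top) holds the intents of
size k with up to C(n, k) slots.  A concept is placed purely by its
intent — colexicographic rank within the row, centred, unit spacing — so
an intent's coordinates are identical in every frame of a sweep.  The
within-row ordering is our own deterministic convention; any fixed rule
preserves the frame-coherence guarantee.  If the top concept has a
nonempty intent (some condition holds for every gene) it is drawn at its
intent's true row and row 1 stays empty: position fixity wins over "top
in row 1".  Node annotations carry the intent and the own-gene count;
SVG node radius grows with the square root of that count above a floor.
The silhouette is capped at 20 conditions (2^n slots); beyond that the
advice is to pre-group conditions.  Exports (dot, graphml, json, svg) are
byte-deterministic.

## Persistence

A bicluster is identified across thresholds by its **intent** — the same
rule that fixes its drawing position.  It is *present* at a threshold
when some concept there has exactly that intent and a nonempty extent;
persistence is the interval [first, last] of presence and its span.
Whether presence should additionally require nonempty *own* genes is a
judgment call; the default (any nonempty extent) is the laxer reading,
and the report sorts by descending span so robust biclusters lead.

## Enrichment

For a bicluster extent of size n drawn from a universe of N genes, a term
carried by K universe genes and k extent genes is scored with the
hypergeometric tails P[X ≥ k] and P[X ≤ k] (scipy's implementation;
verified in the tests against exhaustive enumeration of all draws for
every universe size up to 20).  p-values are floored at double-precision
resolution (≈1.11e-16) — no exact zero is ever printed — and adjusted
with Benjamini–Hochberg (statsmodels).  The universe defaults to all
genes of the expression matrix; an annotated-genes-only universe is
available, as is testing own-gene blocks instead of full extents.
Annotations are flat: no ontology-graph propagation, identifiers are
opaque strings, and no probeset→gene collapsing is attempted.

## Synthetic data

The generator plants p transcription modules: module k couples
⌈sparsity·m⌉ genes with ⌈sparsity·n⌉ conditions at a signed level λ_k,
and X is the sum of level-weighted module blocks plus i.i.d. Gaussian
noise of standard deviation σ (a binary variant returns per-cell module
counts instead).  Negative levels plant under-expression, positive
over-expression.  Randomness comes from numpy's default PCG64 generator
under a fixed seed; the noise stream is seeded separately from the
membership draw so the same plan can be realized at several noise
levels.  With `disjoint=True` modules share no genes or conditions — the
regime with a clean guarantee: for noise-free, same-sign, disjoint
modules whose level clears the threshold, each planted (gene-set,
condition-set) pair is literally a concept of the thresholded context,
and recovery (product of extent- and intent-Jaccard of the best-matching
concept over the sweep) is exactly 1.

What the generator does *not* emulate: probe effects, saturation,
heavy-tailed or correlated noise, and overlapping modules with
conflicting signs.  Passing recovery tests therefore show the machinery
is correct under the additive model, not that real microarray data will
yield equally clean lattices.

## Problem sizes and numerical choices

Study sizes used by the tests and the acceptance script are the
package's own defaults: oracle comparisons run on 200 random contexts
with up to 10 genes and 8 conditions (where closure of *every* subset is
feasible); the noise-degradation study uses m=60, n=8, p=3 modules at
level −1 with σ ∈ {0.1, 0.3, 0.6} over 20 seeds, compared with one
standard error of slack per adjacent pair; the synthetic full-pipeline
study mirrors a 621-gene, 27-sample (9 tissues × 3 replicates) design
with sweep grids decimated to ~15 points per direction.  Monotone
degradation of mean recovery with noise is a stochastic property, hence
the standard-error slack rather than strict inequality.

Ties in slope-change detection (equal second differences of the concept
count) break toward the threshold nearer 0.  Concept equality is
extensional (same extent); hashes use the extent.  Geometric means are
always computed in log space.

## Known limitations

* Enumeration is exponential in the condition count in the worst case
  (2^n concepts); the tool is designed for the small-n regime where the
  silhouette is drawable, and offers no iceberg/pruned lattices.
* Bicluster identity across thresholds is by intent only; extent-based
  tracking (genes migrating between intents) is out of scope.
* The two-sided sweep treats under- and over-expression independently;
  no joint sign-mixed biclusters are produced.
* Enrichment treats annotations as given and flat; results depend
  entirely on the catalogue supplied.
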