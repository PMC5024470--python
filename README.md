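# kfca — threshold-sweep concept-lattice biclustering of expression data

`kfca` analyzes a real-valued gene-expression matrix *X* ∈ ℝ^m×n (m genes,
n conditions) as a *sequence of concept lattices*: hierarchies of
overlapping biclusters obtained by sweeping an under- or over-expression
threshold.  It is aimed at exploratory transcriptomics — finding which
gene sets behave coherently across which condition sets, how robust those
groupings are, and what annotation terms they are enriched for — without
choosing a distance metric, a cluster count, or a partitional structure
up front.

## The method

After geometric-mean replicate averaging, each gene row is normalized by
its geometric mean over conditions and log-compressed,

&nbsp;&nbsp;&nbsp;&nbsp;r<sub>ij</sub> = log ( a<sub>ij</sub> / (∏<sub>k</sub> a<sub>ik</sub>)<sup>1/n</sup> ),

so r<sub>ij</sub> < 0 means gene *i* is under-expressed in condition *j*
relative to its own typical level.  For a threshold φ ≤ 0 the boolean
*formal context* I<sub>φ</sub> marks (g, c) when r<sub>gc</sub> ≤ φ; its
*formal concepts* — pairs (A, B) of a gene set and a condition set, each
the polar image of the other — are exactly the inclusion-maximal
biclusters whose max-norm clears φ.  Ordered by extent inclusion they form
a complete lattice (dually, thresholds ϕ ≥ 0 and the min-norm give
over-expression lattices).  Sweeping φ over the values observed in the
data yields a nested family of contexts and a sequence of lattices:

* the **concept-count curve** (number of concepts vs. threshold) flags,
  via sudden slope changes, thresholds where the lattice reorganizes;
* every lattice is drawn over the fixed **contranominal silhouette** — the
  2^n powerset arranged in n+1 rows, row k+1 holding intents of size k —
  so a bicluster with a given condition set occupies identical coordinates
  in every frame;
* the **persistence** of a bicluster is the threshold range over which its
  intent keeps a nonempty extent — a robustness score;
* bicluster gene sets are tested against an annotation catalogue with
  **hypergeometric tails** P[X ≥ k] (enrichment) and P[X ≤ k] (depletion),
  BH-adjusted.

Reduced labeling annotates each gene at its most specific concept and
each condition at its most abstract one, so extents are read as unions of
gene labels downward and intents as unions of condition labels upward.

## Worked example

Plant two disjoint under-expression modules (level −1) in a 60×8 matrix
with Gaussian noise (sd 0.1), then sweep:

```python
from kfca import (generate_plan, generate_expression, KFCABiclusterer,
                  slope_change_points, persistence)

plan = generate_plan(m=60, n=8, p=2, sparsity=0.15, level_range=(-1.0, -1.0),
                     noise_sd=0.1, seed=42, disjoint=True)
em = generate_expression(plan)
model = KFCABiclusterer(direction="under", max_points=8).fit(em.to_frame())
print("thresholds:", [round(t, 3) for t in model.thresholds_])
print("concept counts:", [c for _, c in model.counts_])
print("hinge thresholds:", [round(t, 3) for t in slope_change_points(model.counts_, 2)])
rec = persistence(model.sequence_, sorted(plan.module_conditions(0)))
```

prints

```
thresholds: [-1.156, -0.993, -0.836, -0.343, -0.229, -0.077, 0.0]
concept counts: [5, 6, 5, 6, 9, 65, 183]
hinge thresholds: [-0.077, -0.229]
biclusters at phi=0.000: 182
module intent ['c4', 'c7'] persists over [-0.836, 0.000], span 0.836
```

Read: at strict thresholds (φ ≤ −0.8) only the planted modules and their
combinations exist (5–6 concepts); as φ approaches 0 noise-driven
concepts flood in (65, then 183), and the slope-change detector flags
exactly that inflation zone (−0.077, −0.229) as the interesting
boundary.  The planted module's condition set persists over a 0.84-wide
threshold interval — a robust bicluster — while noise concepts live only
near 0.  `KFCABiclusterer` is a scikit-learn estimator (`get_params`,
`fit`, `rows_`/`columns_` in the sklearn bicluster convention);
`ReplicateGeometricMean` and `LogRatioNormalizer` are transformers that
compose with sklearn pipelines.

The same pipeline is scriptable from the shell:

```sh
kfca simulate --m 600 --n 9 --p 4 --sparsity 0.1 --levels -1,-0.5 \
     --noise-sd 0.1 --seed 7 --out sim.tsv --truth truth.json
kfca normalize --in expr.tsv --groups groups.tsv --log-base e --out norm.tsv
kfca sweep --in norm.tsv --direction under --max-points 20 --out seq.json
kfca curve --seq seq.json --out curve.tsv
kfca layout --seq seq.json --format dot --out frame.dot
kfca enrich --seq seq.json --annotations ann.tsv --out enrich.csv
kfca persistence --seq seq.json --out persistence.tsv
kfca run --config run.yaml          # all stages + hashed manifest
```

## Layout

```
src/kfca/
  expression.py   I/O, replicate geometric means, log-ratio normalization
  context.py      formal contexts, concepts, lattices, reduced labeling
  sweep.py        binarization, threshold grids, sweeps, persistence,
                  KFCABiclusterer
  layout.py       contranominal-silhouette layout, dot/graphml/json/svg
  enrichment.py   hypergeometric tails, BH adjustment, term indexing
  simulate.py     planted-module generator and recovery scoring
  pipeline.py     end-to-end run with hashed artifact manifest
  cli.py          `kfca` command-line entry point
docs/methods.md   model, assumptions, parameter choices, limitations
```
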