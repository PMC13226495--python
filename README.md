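# topoqspr

Degree-based topological indices and QSPR regression for
hydrogen-suppressed molecular graphs, built around a complete, bundled
dataset of 21 drugs used to treat major depressive disorder.

## The problem

Quantitative structure–property relationship (QSPR) modelling predicts a
molecule's physicochemical behaviour from its structure alone.  The
cheapest structural descriptors are *topological indices*: single real
numbers computed from the hydrogen-suppressed molecular graph `G`
(heavy atoms as vertices, bonds as edges).  This package implements the
bond-additive family

```
index(G) = Σ_{uv ∈ E(G)} ξ(ℓ(u), ℓ(v))
```

where the vertex label `ℓ` is either the degree `d(v)` or the
neighborhood degree `nd(v) = Σ_{u~v} d(u)`, and `ξ(l, m)` is one of
twelve closed forms — atom-bond connectivity `√((l+m−2)/lm)`, Randić
`1/√(lm)`, first/second Zagreb `l+m` / `lm`, redefined Zagreb variants,
Sombor `√(l²+m²)`, Shilpa–Shanmukha `√(lm/(l+m))`, bi-Zagreb-geometric
`(l+m+lm)/√(lm)` and its reciprocal, geometric-arithmetic
`2√(lm)/(l+m)`, and modified second Zagreb `1/(lm)`.  Because `ξ`
depends only on the endpoint labels, each index is a count-weighted sum
over the graph's *edge partition* — the tally of edges by sorted label
pair — which is how the bundled dataset stores the 21 drug structures.

Each of the 24 descriptors (12 indices × 2 flavors) is regressed
against nine properties (molecular weight, heavy atom count,
complexity, boiling point, enthalpy of vaporization, flash point, molar
refractivity, polarizability, molar volume) under three families,
`P = a₁ + a₂ξ`, `P = a₁ + a₂ξ + a₃ξ²` and `P = a₁ + a₂ ln ξ`.  The
best model per property (maximum correlation `r = +√R²`) is validated
by leave-one-out cross-validation (Q²_LOO, RMSECV, MAE) and on an
external two-drug test set.

It is aimed at chemical graph theorists and cheminformaticians who want
a reproducible, offline reference implementation of this analysis, and
a harness for running the same pipeline on their own graphs.

## Worked example

```python
from topoqspr import DEGREE, NEIGHBORHOOD, read_graph, edge_partition, compute_index

g = read_graph(open("src/topoqspr/data/graphs/tranylcypromine.edges").read())
print(g.n_vertices, g.n_edges)                       # 10 11
print(edge_partition(g, DEGREE).counts)              # {(1,3):1, (2,2):4, (2,3):4, (3,3):2}
print(round(compute_index(edge_partition(g, DEGREE), "R"), 2))        # 4.88
print(round(compute_index(edge_partition(g, NEIGHBORHOOD), "R"), 2))  # 2.11
```

The two printed numbers are the degree- and neighborhood-degree Randić
indices of tranylcypromine; 4.88 is `1/√3 + 4/2 + 4/√6 + 2/3` summed
over the four partition cells.  Fitting the selected quadratic
molecular-weight model on the bundled dataset:

```python
from topoqspr import data, fit_model, predict
from topoqspr.pipeline import compute_index_tables

idx = compute_index_tables()[DEGREE]
mw = data.load_properties()["MW"]
model = fit_model(idx["ReZ1"], mw, "quadratic")
print(model.formula())            # y = -0.0147308*x^2 + 14.995*x + -14.0515
print(round(model.stats.r2, 4))   # 0.963
print(round(predict(model, 26.0), 1))  # 365.9  (trazodone, actual 371.9)
```

`ReZ1` over the degree partition equals the heavy atom count exactly
(each vertex contributes `d(v)·(1/d(v))` across its incident edges), so
the heavy-atom-count model is an exact identity: `r² = 1`, zero
standard error, undefined F.

The `examples/` directory holds one short script per capability
(indices, fitting, model selection + LOO, external test set, synthetic
parameter recovery); each prints its results with a closing comment on
what they mean.  A thin CLI wraps the same calls:

```sh
topoqspr indices --flavor degree          # 21 x 12 index table
topoqspr reproduce -o study_output        # recompute + verify everything
```

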