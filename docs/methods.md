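# Methods

## Graph model

Molecules are hydrogen-suppressed simple graphs: one vertex per heavy
atom, one edge per bonded heavy-atom pair, bond order ignored.  This is
the convention under which the bundled edge partitions were tallied —
their row sums equal single-edge bond counts — and it is enforced at
construction: graphs must be connected (an isolated fragment would give
`nd(v) = 0` and break several `ξ` forms), loop-free, duplicate-free and
valence-bounded (degree ≤ 4 by default).  Vertex labels are opaque
strings; no element typing enters any computation.  Disconnected or
malformed edge-list input is rejected with the offending line, not
repaired.

The valence cap applies to actual vertex degrees and hence to
degree-flavor partition labels; neighborhood-degree labels legitimately
exceed it (the bundled data reaches `nd = 11`).

## The twelve indices

Every index is `Σ_cells count(l,m) · ξ(l,m)` over an edge partition.
The canonical closed forms are listed in `topoqspr.indices`.  Two of
them circulate in typographically ambiguous renderings; this package
fixes

* `BMG(l,m) = (l + m + lm) / √(lm)`
* `GBM(l,m) = √(lm) / (l + m + lm)`

which are the unique readings that reproduce the bundled reference
index tables (checked cell-by-cell in the test suite; the reference
tranylcypromine values 48 and 2.54 alone already discriminate the
candidate readings).

Two exact identities fall out of the definitions and serve as internal
cross-checks: over the degree partition, `ReZ1` equals the vertex count
(so it correlates perfectly with heavy atom count) and `M1` equals the
sum of squared degrees.  The neighborhood-flavor `M1` equals `2·M2`
of the degree flavor (`Σ_v nd(v)·d(v) = 2 Σ_{uv} d(u)d(v)`), which the
reference correlation grids confirm: their `M1` (neighborhood) and `M2`
(degree) rows coincide.

## Data

The 21-drug dataset ships as plain TSV: degree partitions,
neighborhood partitions, nine properties per drug, and the reference
index tables and correlation grids at their reported rounding, all
integrity-checked against a SHA-256 manifest at load time.  Three cells
of the neighborhood partition tables were transcribed from zero-width
placeholders; each was resolved to 0 only after confirming that the row
sum then matches the drug's degree-partition edge count (all 21 rows
reconcile).  A thousands separator ("1,224") was normalized during
transcription.  The bundled tables, not any external database, are the
single source of truth; no network lookup ever happens.

Only one training structure (tranylcypromine) ships as an explicit
edge list, hand-encoded and verified against its printed partitions;
for the other 20 drugs the partitions themselves are authoritative, as
published.  The two external test compounds (duloxetine, esketamine)
ship as hand-encoded edge lists taken from their public chemical
structures, with their PubChem-computed MW and HAC; the remaining seven
external property values are proprietary vendor predictions and are not
redistributed, so external validation is demonstrated on MW and HAC
only.

## Regression

All fits are ordinary least squares (statsmodels) on the designs
`{1, x}`, `{1, x, x²}` and `{1, ln x}` (natural log).  The reported
correlation is `r = +√R²`: for the linear family this is |Pearson r|,
and for the quadratic family the multiple correlation of the
two-predictor fit — the only definition under which the quadratic grid
dominates the linear grid entrywise.  Slope signs are retained on the
coefficients.  Statistics: `adj r² = 1 − (1−r²)(n−1)/(n−p−1)`,
`F = (r²/p)/((1−r²)/(n−p−1))`, `SE = √(SS_res/(n−p−1))`.

Grids are computed from unrounded index values (the partitions are
integer tables, so the indices are exact); recomputing from the rounded
reference tables is available as a sensitivity option but is never the
default — the reference statistics only reproduce from unrounded
values.

Numerical choices: a fit whose residual sum of squares is below 1e-12
of the total sum of squares is snapped to exact — `r² = 1`, `SE = 0`,
`F` undefined (`None`) — so the heavy-atom-count identity reports
cleanly instead of as `F ≈ 1e16`.  Model selection maximizes `r` over
all 648 candidates per property; ties break toward the simpler family
(linear < logarithmic < quadratic), then the earlier index in canonical
order, and an exact linear fit excludes higher-order families for that
property outright (they can add nothing).  Constant descriptors,
nonpositive `x` under the logarithmic family, and designs with no
residual degrees of freedom are errors, not warnings.

## Validation

Leave-one-out refits the same family on the other `n−1` points and
predicts the held-out one:

`Q² = 1 − Σ (y_j − ŷ_{j,LOO})² / Σ (y_j − ȳ)²`

with `ȳ` the full-sample mean by default.  The subscripting of the mean
is genuinely ambiguous in parts of the literature, so the per-fold
training mean is implemented behind `mean="training"` and reported
alongside in the reproduction bundle, but it is never gated on.  RMSECV
and MAE are the root-mean-square and mean-absolute LOO residuals.  LOO
is applied to each property's selected best model.  External validation
evaluates an already-fitted model on held-out compounds and reports
per-compound residuals (actual − predicted), RMSE and MAE.

## Synthetic data

The generator emulates the structural class of the study molecules:
connected simple graphs under the valence cap, built as a random
spanning tree (each vertex attaches to a uniformly chosen existing
vertex with spare valence) plus a requested number of extra edges drawn
uniformly from the feasible non-adjacent pairs.  This guarantees
connectivity without rejection sampling; it does *not* attempt
realistic ring statistics, aromaticity or element assignment, so
passing tests demonstrate correctness of the index/regression
machinery, not chemical realism of the generator.  The property
simulator inverts the model families with i.i.d. Gaussian noise
(`σ = 0` allowed for exact tests); Gaussian is a choice of convenience
— OLS itself assumes no specific law.  Recovery experiments draw graph
sizes uniformly between 4 vertices and the configured maximum so the
descriptor varies, with 21 graphs per replicate mirroring the study's
sample size.  All randomness flows through numpy `SeedSequence`, so
identical seeds give identical graphs and noise.

## Problem sizes

Everything is desk scale by design: 21 training compounds, 648
candidate models, 9 × 21 LOO refits.  Property-based checks in the test
suite use a few hundred random graphs of up to ~24 vertices and
Monte-Carlo runs of tens to hundreds of replicates, which keeps the
full suite under ten seconds while still exercising every invariant.

## Known limitations

* Bond order, stereochemistry and heteroatom identity are invisible to
  these descriptors; isomeric drugs with identical skeletons (two in
  the bundled set) get identical descriptors and predictions.
* Single-descriptor models only; no multivariate QSPR, regularization,
  or applicability-domain analysis.
* The external test set has two compounds and two bundled properties —
  a demonstration of the machinery, not a basis for strong claims.
* Model selection by maximum `r` with 648 candidates on 21 observations
  is prone to selection optimism; the LOO results partly, but not
  fully, guard against it.
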