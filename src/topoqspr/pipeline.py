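"""End-to-end pipeline over the bundled 21-drug dataset.

Runs the whole chain — edge partitions -> index tables -> correlation
grids -> best-model selection -> predictions -> leave-one-out
validation — and, on request, checks every stage against the bundled
reference tables, writing the recomputed tables as TSV.

Tolerances used by the checks:

* index tables: one unit in the last reported digit, per cell (the
  reference tables are rounded to at most two decimals);
* correlation grids: +/- 0.001 absolute, per cell (reference rounding
  varies between three and five decimals);
* model statistics, predictions and LOO spot values: the per-quantity
  tolerances recorded next to each reference constant below.

All computation is from unrounded index values; ``from_rounded=True``
recomputes the grids from the rounded reference index tables instead,
as a sensitivity check (not the default, and never used by the
pass/fail manifest).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import data
from .graph import DEGREE, NEIGHBORHOOD
from .indices import index_table
from .regression import FAMILIES, RegressionModel, model_table, predict, select_best_models
from .validation import loo_cv

#: Reported reference statistics for three best-fitted models
#: (property -> (r2, adj_r2, F or None, SE)).
REFERENCE_MODEL_STATS = {
    "MW": (0.963, 0.9589, 234.0981, 15.6895),
    "HAC": (1.0, 1.0, None, 0.0),
    "BP": (0.9455, 0.9395, 156.2866, 30.1562),
}
_STATS_TOL = {"r2": 0.002, "adj_r2": 0.002, "F": 1.0, "SE": 0.05}

#: Reported reference predictions ((property, graph) -> value) and
#: worked single-index values for the tranylcypromine graph G12.
REFERENCE_PREDICTIONS = {("MW", "G1"): 365.9, ("BP", "G12"): 248.2}
REFERENCE_G12 = {("R", DEGREE): 4.88, ("R", NEIGHBORHOOD): 2.11}

#: Reported reference LOO results (property -> (Q2, RMSECV, MAE)).
REFERENCE_LOO = {
    "MW": (0.9442, 17.84, 13.43),
    "HAC": (1.0, 0.0, 0.0),
    "CO": (0.9245, 39.52, 29.23),
}
_LOO_TOL = (0.005, 0.05, 0.05)


def compute_index_tables() -> dict[str, pd.DataFrame]:
    """Unrounded 21 x 12 index tables for both flavors."""
    return {
        DEGREE: index_table(data.load_degree_partitions()),
        NEIGHBORHOOD: index_table(data.load_neighborhood_partitions()),
    }


def compute_grids(
    indices: dict[str, pd.DataFrame] | None = None,
    properties: pd.DataFrame | None = None,
) -> dict[tuple[str, str], pd.DataFrame]:
    """All six correlation grids, keyed by (family, flavor)."""
    from .regression import correlation_grid

    indices = indices or compute_index_tables()
    properties = properties if properties is not None else data.load_properties()
    return {
        (family, flavor): correlation_grid(indices[flavor], properties, family)
        for family in FAMILIES
        for flavor in indices
    }


def best_models(
    indices: dict[str, pd.DataFrame] | None = None,
    properties: pd.DataFrame | None = None,
) -> dict[str, RegressionModel]:
    """The nine selected best-fitted models, one per property."""
    indices = indices or compute_index_tables()
    properties = properties if properties is not None else data.load_properties()
    return select_best_models(compute_grids(indices, properties), indices, properties)


def prediction_table(
    models: dict[str, RegressionModel],
    indices: dict[str, pd.DataFrame],
    properties: pd.DataFrame,
) -> pd.DataFrame:
    """Actual vs predicted value of every property for every drug."""
    frames = {}
    for prop, m in models.items():
        x = indices[m.flavor][m.descriptor]
        frames[(prop, "actual")] = properties[prop]
        frames[(prop, "predicted")] = pd.Series(predict(m, x.to_numpy()), index=x.index)
    out = pd.DataFrame(frames)
    out.index.name = "graph"
    return out


def loo_table(
    models: dict[str, RegressionModel],
    indices: dict[str, pd.DataFrame],
    properties: pd.DataFrame,
    *,
    mean: str = "full",
) -> pd.DataFrame:
    """Q2, RMSECV and MAE of leave-one-out validation of each best model."""
    rows = []
    for prop, m in models.items():
        rep = loo_cv(
            indices[m.flavor][m.descriptor].to_numpy(),
            properties[prop].to_numpy(),
            m.family,
            mean=mean,
        )
        rows.append({"property": prop, "Q2": rep.q2, "RMSECV": rep.rmsecv, "MAE": rep.mae})
    return pd.DataFrame(rows).set_index("property")


@dataclass(frozen=True)
class Check:
    """One pass/fail entry of the reproduction manifest."""

    name: str
    passed: bool
    detail: str


def _check_table(name, computed, reference, tol_fn) -> Check:
    worst, worst_cell = 0.0, None
    for row in reference.index:
        for col in reference.columns:
            ref = float(reference.loc[row, col])
            got = float(computed.loc[row, col])
            tol = tol_fn(row, col)
            excess = abs(got - ref) - tol
            if excess > worst:
                worst, worst_cell = excess, (row, col, got, ref)
    if worst_cell is None:
        return Check(name, True, f"all {reference.size} cells within tolerance")
    r, c, got, ref = worst_cell
    return Check(name, False, f"cell ({r},{c}): computed {got:.6g} vs reference {ref}")


def _last_digit_tol(raw: pd.DataFrame):
    def tol(row, col):
        s = str(raw.loc[row, col])
        dec = len(s.split(".")[1]) if "." in s else 0
        return 10.0**-dec + 1e-9

    return tol


def reproduce(outdir: str | Path | None = None, *, flavors=(DEGREE, NEIGHBORHOOD)) -> list[Check]:
    """Recompute every results table from the bundled fixtures and check it.

    Writes the recomputed tables under ``outdir`` (if given) and returns
    the pass/fail manifest.  Output is deterministic: rerunning with the
    same arguments produces byte-identical files.
    """
    flavors = tuple(flavors)
    indices = {f: t for f, t in compute_index_tables().items() if f in flavors}
    properties = data.load_properties()
    checks: list[Check] = []

    for key, flavor in (("R", DEGREE), ("R", NEIGHBORHOOD)):
        if flavor not in flavors:
            continue
        got = round(float(indices[flavor].loc["G12", key]), 2)
        ref = REFERENCE_G12[(key, flavor)]
        checks.append(
            Check(f"worked-example R {flavor} G12", abs(got - ref) < 5e-3, f"{got} vs {ref}")
        )

    for flavor in flavors:
        ref_raw = data.load_reference_indices(flavor, raw=True)
        ref = data.load_reference_indices(flavor)
        checks.append(
            _check_table(f"index-table {flavor}", indices[flavor], ref, _last_digit_tol(ref_raw))
        )
    checks.append(
        Check(
            "ReZ1-degree equals heavy atom count",
            DEGREE not in flavors
            or bool(np.allclose(indices.get(DEGREE, properties)["ReZ1"], properties["HAC"])),
            "ReZ1 over the degree partition counts the vertices",
        )
    )

    grids = compute_grids(indices, properties)
    for (family, flavor), grid in sorted(grids.items()):
        ref = data.load_reference_correlations(family, flavor)
        ref.index = grid.index  # same canonical order
        checks.append(
            _check_table(f"correlation-grid {family} {flavor}", grid, ref, lambda r, c: 0.001)
        )

    models = preds = loo = None
    if set(flavors) == {DEGREE, NEIGHBORHOOD}:
        models = select_best_models(grids, indices, properties)
        stats_tbl = model_table(models)
        for prop, (r2, adj, f, se) in REFERENCE_MODEL_STATS.items():
            m = models[prop].stats
            ok = (
                abs(m.r2 - r2) <= _STATS_TOL["r2"]
                and abs(m.adj_r2 - adj) <= _STATS_TOL["adj_r2"]
                and ((f is None) == (m.f is None))
                and (f is None or abs(m.f - f) <= _STATS_TOL["F"])
                and abs(m.se - se) <= _STATS_TOL["SE"]
            )
            checks.append(Check(f"model-stats {prop}", ok, models[prop].formula()))
        preds = prediction_table(models, indices, properties)
        for (prop, gid), ref in REFERENCE_PREDICTIONS.items():
            got = round(float(preds.loc[gid, (prop, "predicted")]), 1)
            checks.append(
                Check(f"prediction {prop} {gid}", abs(got - ref) <= 0.1, f"{got} vs {ref}")
            )
        loo = loo_table(models, indices, properties)
        for prop, ref in REFERENCE_LOO.items():
            got = loo.loc[prop]
            ok = all(
                abs(float(got[c]) - r) <= t
                for c, r, t in zip(("Q2", "RMSECV", "MAE"), ref, _LOO_TOL)
            )
            checks.append(
                Check(f"loo {prop}", ok, f"Q2={got['Q2']:.4f} RMSECV={got['RMSECV']:.2f}")
            )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for flavor in flavors:
            indices[flavor].round(6).to_csv(outdir / f"indices_{flavor}.tsv", sep="\t")
        for (family, flavor), grid in sorted(grids.items()):
            grid.round(6).to_csv(outdir / f"correlations_{family}_{flavor}.tsv", sep="\t")
        if models is not None:
            model_table(models).round(6).to_csv(outdir / "best_models.tsv", sep="\t")
            flat = preds.round(4)
            flat.columns = [f"{p}_{k}" for p, k in flat.columns]
            flat.to_csv(outdir / "predictions.tsv", sep="\t")
            loo.round(6).to_csv(outdir / "loo_validation.tsv", sep="\t")
            loo_table(models, indices, properties, mean="training").round(6).to_csv(
                outdir / "loo_validation_trainmean.tsv", sep="\t"
            )
        lines = [
            f"{'PASS' if c.passed else 'FAIL'}\t{c.name}\t{c.detail}" for c in checks
        ]
        (outdir / "manifest.tsv").write_text("\n".join(lines) + "\n")
    return checks
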