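"""Single-descriptor QSPR regression: fitting, grids and model selection.

Three model families relate a property P to a topological index x:

* linear       P = a1 + a2 x
* quadratic    P = a1 + a2 x + a3 x^2
* logarithmic  P = a1 + a2 ln x        (natural log)

All fits are ordinary least squares (via statsmodels).  The reported
correlation coefficient is the positive square root of R^2 of the fit,
so for the linear family it equals |Pearson r| and for the quadratic
family it is the multiple correlation of the two-predictor fit; this is
the only definition under which the quadratic grid dominates the linear
grid entrywise.  The sign of the relationship is retained on the fitted
slope.

Degenerate fits are snapped: when the residual sum of squares is zero to
within 1e-12 of the total sum of squares, R^2 is reported as exactly 1,
the standard error as 0 and the F statistic as undefined (``None``) —
this is how the exact HAC = ReZ1 (degree) identity surfaces in the
model-statistics table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .graph import FLAVORS
from .indices import INDEX_ORDER

FAMILIES = ("linear", "quadratic", "logarithmic")

#: Tie-break preference: simpler families first.
_FAMILY_RANK = {"linear": 0, "logarithmic": 1, "quadratic": 2}

#: Relative tolerance under which a fit counts as exact (R^2 == 1).
_EXACT_RTOL = 1e-12


@dataclass(frozen=True)
class FitStats:
    """Goodness-of-fit summary: r, r^2, adjusted r^2, F (None when the
    fit is exact) and residual standard error."""

    r: float
    r2: float
    adj_r2: float
    f: float | None
    se: float


@dataclass(frozen=True)
class RegressionModel:
    """A fitted single-descriptor model.

    ``coef`` holds (a1, a2) or (a1, a2, a3) for the quadratic family.
    ``descriptor``/``flavor``/``prop`` are optional bookkeeping labels.
    """

    family: str
    coef: tuple[float, ...]
    n: int
    stats: FitStats
    descriptor: str | None = None
    flavor: str | None = None
    prop: str | None = None

    @property
    def n_terms(self) -> int:
        """Number of predictor terms p (1, or 2 for quadratic)."""
        return len(self.coef) - 1

    def formula(self) -> str:
        """Human-readable model equation."""
        x = self.descriptor or "x"
        if self.flavor:
            x += {"degree": "d", "neighborhood": "nd"}[self.flavor]
        a = self.coef
        lhs = self.prop or "y"
        if self.family == "linear":
            rhs = f"{a[1]:.6g}*{x} + {a[0]:.6g}"
        elif self.family == "quadratic":
            rhs = f"{a[2]:.6g}*{x}^2 + {a[1]:.6g}*{x} + {a[0]:.6g}"
        else:
            rhs = f"{a[1]:.6g}*ln({x}) + {a[0]:.6g}"
        return f"{lhs} = {rhs}"


def _design(x: np.ndarray, family: str) -> np.ndarray:
    if family == "linear":
        cols = [x]
    elif family == "quadratic":
        cols = [x, x * x]
    elif family == "logarithmic":
        if np.any(x <= 0):
            raise ValueError("logarithmic family requires strictly positive x")
        cols = [np.log(x)]
    else:
        raise ValueError(f"unknown regression family {family!r}; expected one of {FAMILIES}")
    return sm.add_constant(np.column_stack(cols), has_constant="add")


def fit_model(
    x: Sequence[float],
    y: Sequence[float],
    family: str,
    *,
    descriptor: str | None = None,
    flavor: str | None = None,
    prop: str | None = None,
) -> RegressionModel:
    """Ordinary-least-squares fit of one family on (x, y).

    Requires at least four observations and a non-constant descriptor.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be one-dimensional and of equal length")
    if len(x) < 4:
        raise ValueError(f"need at least 4 observations, got {len(x)}")
    if np.ptp(x) == 0:
        raise ValueError("descriptor is constant; design matrix is singular")
    design = _design(x, family)
    res = sm.OLS(y, design).fit()
    coef = tuple(float(c) for c in res.params)
    stats = _stats_from_sums(float(res.ssr), float(res.centered_tss), len(x), design.shape[1] - 1)
    return RegressionModel(family, coef, len(x), stats, descriptor, flavor, prop)


def _stats_from_sums(ssres: float, sstot: float, n: int, p: int) -> FitStats:
    if n <= p + 1:
        raise ValueError(f"n={n} leaves no residual degrees of freedom for p={p} terms")
    if sstot <= 0:
        raise ValueError("response is constant; r^2 is undefined")
    exact = ssres <= _EXACT_RTOL * sstot
    r2 = 1.0 if exact else 1.0 - ssres / sstot
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    f = None if exact else (r2 / p) / ((1.0 - r2) / (n - p - 1))
    se = 0.0 if exact else math.sqrt(ssres / (n - p - 1))
    return FitStats(r=math.sqrt(max(r2, 0.0)), r2=r2, adj_r2=adj, f=f, se=se)


def fit_stats(model: RegressionModel, x: Sequence[float], y: Sequence[float]) -> FitStats:
    """Recompute goodness-of-fit of ``model`` on data (x, y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    resid = y - predict(model, x)
    ssres = float(resid @ resid)
    sstot = float(((y - y.mean()) ** 2).sum())
    return _stats_from_sums(ssres, sstot, len(y), model.n_terms)


def predict(model: RegressionModel, x):
    """Evaluate the fitted family formula at descriptor value(s) ``x``."""
    x = np.asarray(x, dtype=float)
    a = model.coef
    if model.family == "linear":
        out = a[0] + a[1] * x
    elif model.family == "quadratic":
        out = a[0] + a[1] * x + a[2] * x * x
    else:
        out = a[0] + a[1] * np.log(x)
    return float(out) if out.ndim == 0 else out


def correlation_grid(
    indices: pd.DataFrame, properties: pd.DataFrame, family: str
) -> pd.DataFrame:
    """Correlation coefficients of every (index, property) fit.

    ``indices`` holds one row per graph and one column per index;
    ``properties`` one row per graph and one column per property.  Entry
    (i, p) is the positive root of R^2 of the single-descriptor fit of
    family ``family``.
    """
    if set(indices.index) != set(properties.index):
        raise ValueError("indices and properties cover different graph sets")
    props = properties.loc[indices.index]
    grid = pd.DataFrame(index=indices.columns, columns=props.columns, dtype=float)
    for ind in indices.columns:
        x = indices[ind].to_numpy()
        for p in props.columns:
            grid.loc[ind, p] = fit_model(x, props[p].to_numpy(), family).stats.r
    grid.index.name = "index"
    return grid


def select_best_models(
    grids: Mapping[tuple[str, str], pd.DataFrame],
    indices: Mapping[str, pd.DataFrame],
    properties: pd.DataFrame,
) -> dict[str, RegressionModel]:
    """Pick and refit the best (index, flavor, family) model per property.

    ``grids`` maps (family, flavor) to a correlation grid; ``indices``
    maps flavor to its index table.  For each property the candidate
    maximizing r wins; ties break toward the simpler family
    (linear < logarithmic < quadratic) and then the earlier index in
    canonical order.  When a linear fit is exact (r == 1) the
    higher-order families are excluded for that property, since they can
    add nothing.
    """
    order = {str(i): k for k, i in enumerate(INDEX_ORDER)}
    best: dict[str, RegressionModel] = {}
    for prop in properties.columns:
        cands = []
        for (family, flavor), grid in grids.items():
            for ind in grid.index:
                r = float(grid.loc[ind, prop])
                cands.append((r, _FAMILY_RANK[family], order[str(ind)], family, flavor, ind))
        if any(r >= 1.0 - _EXACT_RTOL and fam == "linear" for r, _, _, fam, _, _ in cands):
            cands = [c for c in cands if c[3] == "linear"]
        cands.sort(key=lambda c: (-c[0], c[1], c[2]))
        _, _, _, family, flavor, ind = cands[0]
        best[prop] = fit_model(
            indices[flavor][ind].to_numpy(),
            properties[prop].to_numpy(),
            family,
            descriptor=str(ind),
            flavor=flavor,
            prop=prop,
        )
    return best


def model_table(models: Mapping[str, RegressionModel]) -> pd.DataFrame:
    """Summary table of fitted models (formula and fit statistics)."""
    rows = []
    for prop, m in models.items():
        rows.append(
            {
                "property": prop,
                "model": m.formula(),
                "r": m.stats.r,
                "r2": m.stats.r2,
                "adj_r2": m.stats.adj_r2,
                "F": np.nan if m.stats.f is None else m.stats.f,
                "SE": m.stats.se,
            }
        )
    return pd.DataFrame(rows).set_index("property")


def save_model(model: RegressionModel) -> str:
    """Serialize a model to a small key=value text block."""
    lines = [f"family={model.family}", f"n={model.n}"]
    for k, v in (("descriptor", model.descriptor), ("flavor", model.flavor), ("property", model.prop)):
        if v is not None:
            lines.append(f"{k}={v}")
    for i, a in enumerate(model.coef, start=1):
        lines.append(f"a{i}={a!r}")
    s = model.stats
    lines += [f"r={s.r!r}", f"r2={s.r2!r}", f"adj_r2={s.adj_r2!r}",
              f"F={'undefined' if s.f is None else repr(s.f)}", f"se={s.se!r}"]
    return "\n".join(lines) + "\n"


def load_model(text: str) -> RegressionModel:
    """Parse a model serialized by :func:`save_model`."""
    kv: dict[str, str] = {}
    for line in text.splitlines():
        line = line.strip()
        if line and "=" in line:
            k, v = line.split("=", 1)
            kv[k] = v
    coef = []
    i = 1
    while f"a{i}" in kv:
        coef.append(float(kv[f"a{i}"]))
        i += 1
    stats = FitStats(
        r=float(kv["r"]), r2=float(kv["r2"]), adj_r2=float(kv["adj_r2"]),
        f=None if kv["F"] == "undefined" else float(kv["F"]), se=float(kv["se"]),
    )
    flavor = kv.get("flavor")
    if flavor is not None and flavor not in FLAVORS:
        raise ValueError(f"unknown flavor {flavor!r} in model file")
    return RegressionModel(
        kv["family"], tuple(coef), int(kv["n"]), stats,
        kv.get("descriptor"), flavor, kv.get("property"),
    )
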