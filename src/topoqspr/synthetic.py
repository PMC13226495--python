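"""Synthetic molecular graphs and descriptor-property simulations.

The graph generator emulates the structural class of the bundled drug
skeletons: connected simple graphs with every vertex degree capped at
the heavy-atom valence bound of 4.  Construction is a random spanning
tree (each new vertex attaches to a uniformly chosen existing vertex
with spare valence) followed by a requested number of extra edges drawn
uniformly from the still-feasible non-adjacent pairs, so connectivity is
guaranteed without rejection sampling.  The generator makes no attempt
at chemically realistic ring statistics or element assignment; it
exists to drive property-based tests and parameter-recovery
experiments.

The property simulator inverts the regression models: given descriptor
values x it draws y = f(x; a) + eps with i.i.d. Gaussian noise, so that
with sigma = 0 the fitting code must recover the coefficients exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .graph import DEGREE, MAX_VALENCE, MolecularGraph, edge_partition
from .indices import IndexId, compute_index
from .regression import FAMILIES, fit_model, predict
from .validation import loo_cv


@dataclass(frozen=True)
class GraphGenConfig:
    """Recipe for one random valence-bounded connected graph."""

    n_vertices: int
    extra_edges: int = 0
    max_degree: int = MAX_VALENCE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_vertices < 2:
            raise ValueError("need at least 2 vertices")
        if self.extra_edges < 0:
            raise ValueError("extra_edges must be >= 0")
        if self.max_degree < 2 and self.n_vertices > 2:
            raise ValueError("max_degree < 2 cannot yield a connected graph")


@dataclass(frozen=True)
class PropertySimConfig:
    """Recipe for simulated property values from a known model."""

    family: str
    coef: tuple[float, ...]
    sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        want = 3 if self.family == "quadratic" else 2
        if len(self.coef) != want:
            raise ValueError(f"{self.family} family needs {want} coefficients, got {len(self.coef)}")
        if self.sigma < 0:
            raise ValueError("noise sd sigma must be >= 0")


def random_molecular_graph(config: GraphGenConfig) -> MolecularGraph:
    """Draw one connected simple graph under the degree cap.

    Deterministic given ``config.seed``.  Raises if ``extra_edges``
    cannot be placed without breaking the cap or duplicating an edge.
    """
    rng = np.random.default_rng(config.seed)
    n, cap = config.n_vertices, config.max_degree
    labels = [f"v{i}" for i in range(1, n + 1)]
    deg = {v: 0 for v in labels}
    edges: list[tuple[str, str]] = []
    adjacent: set[frozenset[str]] = set()
    for i in range(1, n):
        hosts = [v for v in labels[:i] if deg[v] < cap]
        if not hosts:
            raise ValueError(
                f"infeasible config: cannot attach vertex {i + 1} under degree cap {cap}"
            )
        host = hosts[rng.integers(len(hosts))]
        v = labels[i]
        edges.append((host, v))
        adjacent.add(frozenset((host, v)))
        deg[host] += 1
        deg[v] += 1
    for k in range(config.extra_edges):
        open_v = [v for v in labels if deg[v] < cap]
        candidates = [
            (u, w)
            for i, u in enumerate(open_v)
            for w in open_v[i + 1 :]
            if frozenset((u, w)) not in adjacent
        ]
        if not candidates:
            raise ValueError(
                f"infeasible config: only {k} of {config.extra_edges} extra edges "
                f"fit under degree cap {cap}"
            )
        u, w = candidates[rng.integers(len(candidates))]
        edges.append((u, w))
        adjacent.add(frozenset((u, w)))
        deg[u] += 1
        deg[w] += 1
    return MolecularGraph(edges, max_degree=cap)


def simulate_property(x: Sequence[float], config: PropertySimConfig) -> np.ndarray:
    """Draw property values y = f(x; coef) + Gaussian(0, sigma^2) noise."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("descriptor values must be finite")
    if config.family == "logarithmic" and np.any(x <= 0):
        raise ValueError("logarithmic family requires strictly positive x")
    a = config.coef
    if config.family == "linear":
        y = a[0] + a[1] * x
    elif config.family == "quadratic":
        y = a[0] + a[1] * x + a[2] * x * x
    else:
        y = a[0] + a[1] * np.log(x)
    rng = np.random.default_rng(config.seed)
    return y + rng.normal(0.0, config.sigma, size=x.shape)


@dataclass(frozen=True)
class RecoveryResult:
    """Per-replicate fits plus coefficient bias/RMSE summary."""

    replicates: pd.DataFrame
    bias: tuple[float, ...]
    rmse: tuple[float, ...]


def recovery_experiment(
    graph_config: GraphGenConfig,
    index: IndexId | str,
    property_config: PropertySimConfig,
    replicates: int,
    *,
    n_graphs: int = 21,
    flavor: str = DEGREE,
) -> RecoveryResult:
    """Simulate descriptor-property datasets and measure coefficient recovery.

    Each replicate draws ``n_graphs`` random graphs whose sizes vary
    uniformly between 4 vertices and ``graph_config.n_vertices`` (so the
    descriptor actually varies), computes the chosen index, simulates
    the property under ``property_config`` and refits the same family.
    The result records fitted coefficients, r and Q2 per replicate and
    the bias and RMSE of each coefficient across replicates.
    """
    index = IndexId(index)
    ss = np.random.SeedSequence([graph_config.seed, property_config.seed])
    children = ss.spawn(replicates)
    rows = []
    lo = min(4, graph_config.n_vertices)
    for rep, child in enumerate(children):
        rng = np.random.default_rng(child)
        sizes = rng.integers(lo, graph_config.n_vertices + 1, size=n_graphs)
        extras = rng.integers(0, graph_config.extra_edges + 1, size=n_graphs)
        x = np.empty(n_graphs)
        for i, (nv, ex) in enumerate(zip(sizes, extras)):
            g = random_molecular_graph(
                GraphGenConfig(int(nv), int(ex), graph_config.max_degree,
                               seed=int(rng.integers(2**31)))
            )
            x[i] = compute_index(edge_partition(g, flavor), index)
        noise_seed = int(rng.integers(2**31))
        y = simulate_property(
            x,
            PropertySimConfig(property_config.family, property_config.coef,
                              property_config.sigma, seed=noise_seed),
        )
        model = fit_model(x, y, property_config.family)
        loo = loo_cv(x, y, property_config.family)
        row = {"replicate": rep, "r": model.stats.r, "q2": loo.q2}
        for i, a in enumerate(model.coef, start=1):
            row[f"a{i}"] = a
        rows.append(row)
    reps = pd.DataFrame(rows).set_index("replicate")
    true = np.asarray(property_config.coef)
    est = reps[[f"a{i}" for i in range(1, len(true) + 1)]].to_numpy()
    err = est - true
    return RecoveryResult(
        replicates=reps,
        bias=tuple(err.mean(axis=0)),
        rmse=tuple(np.sqrt((err**2).mean(axis=0))),
    )
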