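"""Bundled study dataset: 21 antidepressant drug graphs and properties.

The package ships, as plain TSV under ``topoqspr/data``:

* degree- and neighborhood-degree-based edge partitions for the 21
  hydrogen-suppressed drug skeletons (``G1``..``G21``);
* the nine physicochemical properties per drug (molecular weight MW,
  heavy atom count HAC, complexity CO, boiling point BP, enthalpy of
  vaporization EV, flash point FP, molar refractivity MR,
  polarizability PO, molar volume MV);
* reference index tables and correlation grids, kept at their reported
  rounding, used as regression-test oracles;
* hand-encoded edge lists for tranylcypromine (G12) and for the two
  external test compounds duloxetine and esketamine, plus the external
  compounds' MW/HAC.

Every file is integrity-checked against a SHA-256 manifest at load time;
no network access is ever performed.
"""

from __future__ import annotations

import hashlib
from importlib import resources

import pandas as pd

from .graph import DEGREE, NEIGHBORHOOD, EdgePartition, MolecularGraph, read_graph, _check_flavor

#: Property columns, in canonical reporting order.
PROPERTIES = ("MW", "HAC", "CO", "BP", "EV", "FP", "MR", "PO", "MV")

#: Graph ids of the 21-drug training set.
GRAPH_IDS = tuple(f"G{i}" for i in range(1, 22))


class FixtureError(RuntimeError):
    """A bundled data file is missing, corrupted or incomplete."""


def _data_root():
    return resources.files(__package__) / "data"


def _manifest() -> dict[str, str]:
    text = (_data_root() / "MANIFEST.tsv").read_text()
    out = {}
    for line in text.splitlines()[1:]:
        name, digest = line.split("\t")
        out[name] = digest
    return out


def _read_text(relpath: str) -> str:
    node = _data_root() / relpath
    try:
        raw = node.read_bytes()
    except FileNotFoundError:
        raise FixtureError(f"bundled data file {relpath!r} is missing") from None
    digest = hashlib.sha256(raw).hexdigest()
    expected = _manifest().get(relpath)
    if expected is None:
        raise FixtureError(f"{relpath!r} is not listed in the data manifest")
    if digest != expected:
        raise FixtureError(
            f"checksum mismatch for bundled file {relpath!r}: "
            f"expected {expected[:12]}.., got {digest[:12]}.."
        )
    return raw.decode("utf-8")


def _read_tsv(relpath: str, **kw) -> pd.DataFrame:
    from io import StringIO

    return pd.read_csv(StringIO(_read_text(relpath)), sep="\t", **kw)


def load_drug_names() -> dict[str, str]:
    """Graph id -> drug name for the 21-drug set."""
    df = _read_tsv("drugs.tsv", index_col="graph")
    return df["drug"].to_dict()


def _load_partitions(relpath: str, flavor: str) -> dict[str, EdgePartition]:
    df = _read_tsv(relpath, index_col="graph")
    out: dict[str, EdgePartition] = {}
    for gid, row in df.iterrows():
        counts = {}
        for col, val in row.items():
            if int(val) > 0:
                l, m = col.strip("()").split(",")
                counts[(int(l), int(m))] = int(val)
        if not counts:
            raise FixtureError(f"empty partition row for {gid}")
        out[gid] = EdgePartition(flavor, counts)
    if list(out) != list(GRAPH_IDS):
        raise FixtureError(f"expected rows {GRAPH_IDS[0]}..{GRAPH_IDS[-1]} in {relpath}")
    return out


def load_degree_partitions() -> dict[str, EdgePartition]:
    """The 21 degree-based edge partitions, keyed by graph id."""
    return _load_partitions("degree_partitions.tsv", DEGREE)


def load_neighborhood_partitions() -> dict[str, EdgePartition]:
    """The 21 neighborhood-degree-based edge partitions, keyed by graph id."""
    return _load_partitions("neighborhood_partitions.tsv", NEIGHBORHOOD)


def load_properties() -> pd.DataFrame:
    """Physicochemical property table: 21 rows, columns ``PROPERTIES``.

    Units: MW g/mol; BP and FP deg C; EV kJ/mol; MR and MV cm^3;
    PO 1e-24 cm^3; HAC and CO dimensionless.
    """
    df = _read_tsv("properties.tsv", index_col="graph")
    df = df.drop(columns=["drug"])
    if df.shape != (21, 9) or df.isna().any().any():
        raise FixtureError("property table must hold 21 complete rows")
    if (df <= 0).any().any():
        raise FixtureError("property values must be positive")
    return df.astype(float)


def load_reference_indices(flavor: str, *, raw: bool = False) -> pd.DataFrame:
    """Reported index table for one flavor (regression-test oracle).

    With ``raw=True`` the values are returned as the printed strings so
    callers can recover the reported rounding precision.
    """
    _check_flavor(flavor)
    name = f"reference_indices_{flavor}.tsv"
    if raw:
        return _read_tsv(name, index_col="graph", dtype=str)
    return _read_tsv(name, index_col="graph").astype(float)


def load_reference_correlations(family: str, flavor: str) -> pd.DataFrame:
    """Reported correlation grid (12 indices x 9 properties) for one
    regression family and label flavor."""
    _check_flavor(flavor)
    if family not in ("linear", "quadratic", "logarithmic"):
        raise ValueError(f"unknown regression family {family!r}")
    return _read_tsv(f"reference_correlations_{family}_{flavor}.tsv", index_col="index").astype(float)


def load_graph(name: str) -> MolecularGraph:
    """Load a bundled hand-encoded molecular graph by drug name.

    Available: ``tranylcypromine`` (training drug G12), ``duloxetine``
    and ``esketamine`` (external test compounds).
    """
    return read_graph(_read_text(f"graphs/{name}.edges"))


def load_external_properties() -> pd.DataFrame:
    """MW and HAC of the two external test compounds, indexed by drug name.

    Only PubChem-computed values are bundled; the remaining seven
    properties of the external compounds are vendor predictions that are
    not redistributed here.
    """
    df = _read_tsv("external_properties.tsv", index_col="drug")
    return df.drop(columns=["graph"]).astype(float)
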