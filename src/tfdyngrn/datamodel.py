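"""Core data containers and tab-separated readers/writers.

Everything downstream of raw counts flows through four containers:

* :class:`SampleDesign` — the experimental layout (patient, condition,
  day, replicate) of every sample column.
* :class:`ExpressionMatrix` — a gene × sample matrix tagged with the
  processing layer it carries (raw counts, normalised, or per-gene
  standardised values).
* :class:`Regulon` — prior knowledge mapping each transcription factor
  to its target genes with a regulation mode (+1 activation, −1
  repression) and a confidence weight.
* :class:`NetworkEdgeTable` — a generic edge list for every inferred
  network, carrying weight, sign, correlation and a provenance tag.

All tabular IO is TSV with '.' decimals and UTF-8; identifiers are
opaque, case-sensitive strings. Readers and writers round-trip at full
float precision (``repr`` formatting on write).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

AUTOLOGOUS = "autologous"
MONOCULTURE = "monoculture"
CONDITIONS = (AUTOLOGOUS, MONOCULTURE)

_DESIGN_COLUMNS = ["sample_id", "patient", "condition", "day", "replicate"]
_EDGE_COLUMNS = ["source", "target", "weight", "sign", "correlation", "provenance"]


class DataError(ValueError):
    """Malformed or inconsistent input data."""


@dataclasses.dataclass
class SampleDesign:
    """Sample layout table with columns sample_id/patient/condition/day/replicate."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _DESIGN_COLUMNS if c not in self.table.columns]
        if missing:
            raise DataError(f"design table missing columns: {missing}")
        t = self.table.loc[:, _DESIGN_COLUMNS].copy()
        t["sample_id"] = t["sample_id"].astype(str)
        t["patient"] = t["patient"].astype(str)
        t["condition"] = t["condition"].astype(str)
        t["day"] = t["day"].astype(int)
        t["replicate"] = t["replicate"].astype(int)
        dup = t["sample_id"][t["sample_id"].duplicated()]
        if len(dup):
            raise DataError(f"duplicate sample ids: {sorted(set(dup))}")
        bad = sorted(set(t["condition"]) - set(CONDITIONS))
        if bad:
            raise DataError(f"unknown conditions {bad}; expected {CONDITIONS}")
        self.table = t.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def patients(self) -> list[str]:
        return sorted(set(self.table["patient"]))

    @property
    def conditions(self) -> list[str]:
        return sorted(set(self.table["condition"]))

    def days(self, patient: str | None = None, condition: str | None = None) -> list[int]:
        """Strictly increasing day sequence, optionally within one series."""
        t = self.table
        if patient is not None:
            t = t[t["patient"] == patient]
        if condition is not None:
            t = t[t["condition"] == condition]
        return sorted(set(t["day"]))

    def samples_for(
        self,
        patient: str | None = None,
        condition: str | None = None,
        day: int | None = None,
        replicate: int | None = None,
    ) -> list[str]:
        t = self.table
        if patient is not None:
            t = t[t["patient"] == patient]
        if condition is not None:
            t = t[t["condition"] == condition]
        if day is not None:
            t = t[t["day"] == day]
        if replicate is not None:
            t = t[t["replicate"] == replicate]
        return list(t["sample_id"])

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleDesign":
        return cls(pd.read_csv(path, sep="\t", dtype={"sample_id": str, "patient": str}))


@dataclasses.dataclass
class ExpressionMatrix:
    """Gene × sample matrix; ``layer`` is one of counts/normalised/standardised."""

    data: pd.DataFrame
    layer: str = "counts"

    LAYERS = ("counts", "normalised", "standardised")

    def __post_init__(self) -> None:
        if self.layer not in self.LAYERS:
            raise DataError(f"unknown layer {self.layer!r}; expected one of {self.LAYERS}")
        if self.data.index.duplicated().any():
            dup = sorted(set(self.data.index[self.data.index.duplicated()]))
            raise DataError(f"duplicate gene ids: {dup[:10]}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise DataError("non-numeric cells in expression matrix")
        if self.layer == "counts":
            if (values < 0).any():
                raise DataError("counts layer contains negative values")
            if not np.allclose(values, np.round(values)):
                raise DataError("counts layer contains non-integral values")

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    def aligned_to(self, design: SampleDesign) -> "ExpressionMatrix":
        """Reorder columns to the design order; raise naming any mismatch."""
        matrix_samples = set(self.data.columns)
        design_samples = set(design.sample_ids)
        only_design = sorted(design_samples - matrix_samples)
        if only_design:
            raise DataError(f"samples in design but not in matrix: {only_design}")
        only_matrix = sorted(matrix_samples - design_samples)
        if only_matrix:
            raise DataError(f"samples in matrix but not in design: {only_matrix}")
        return ExpressionMatrix(self.data.loc[:, design.sample_ids], layer=self.layer)

    def to_tsv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.index.name = "gene"
        out.to_csv(path, sep="\t", float_format=None)

    @classmethod
    def from_tsv(cls, path: str | Path, layer: str = "counts") -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
        df.index = df.index.astype(str)
        df.index.name = None
        return cls(df, layer=layer)


def read_expression(
    path: str | Path, design_path: str | Path, layer: str = "counts"
) -> tuple[ExpressionMatrix, SampleDesign]:
    """Read an expression TSV and its design TSV, aligning columns to the design."""
    design = SampleDesign.from_tsv(design_path)
    expr = ExpressionMatrix.from_tsv(path, layer=layer)
    return expr.aligned_to(design), design


_MODE_ALIASES = {"1": 1, "+1": 1, "A": 1, "-1": -1, "−1": -1, "I": -1}


@dataclasses.dataclass
class Regulon:
    """TF → (target, mode ±1, weight ∈ (0,1]) prior; (tf, target) pairs unique."""

    table: pd.DataFrame  # columns: tf, target, mode, weight

    def __post_init__(self) -> None:
        t = self.table.loc[:, ["tf", "target", "mode", "weight"]].copy()
        t["tf"] = t["tf"].astype(str)
        t["target"] = t["target"].astype(str)
        t["mode"] = t["mode"].astype(int)
        t["weight"] = t["weight"].astype(float)
        if len(t) == 0:
            raise DataError("empty regulon")
        if not t["mode"].isin([-1, 1]).all():
            bad = sorted(set(t["mode"]) - {-1, 1})
            raise DataError(f"regulation mode must be ±1, got {bad}")
        if ((t["weight"] <= 0) | (t["weight"] > 1)).any():
            raise DataError("regulon weights must lie in (0, 1]")
        # duplicates with identical mode collapse; contradictory modes are an error
        dedup = t.drop_duplicates(subset=["tf", "target", "mode"])
        if dedup.duplicated(subset=["tf", "target"]).any():
            conflict = dedup[dedup.duplicated(subset=["tf", "target"], keep=False)]
            pairs = sorted(set(zip(conflict["tf"], conflict["target"])))
            raise DataError(f"conflicting modes for tf-target pairs: {pairs[:10]}")
        self.table = dedup.drop_duplicates(subset=["tf", "target"]).reset_index(drop=True)

    @property
    def tfs(self) -> list[str]:
        return sorted(set(self.table["tf"]))

    def targets_of(self, tf: str) -> pd.DataFrame:
        return self.table[self.table["tf"] == tf]

    def restrict_targets(self, genes: Iterable[str]) -> "Regulon":
        keep = self.table["target"].isin(set(genes))
        sub = self.table[keep]
        if len(sub) == 0:
            raise DataError("no regulon target measured in the expression matrix")
        return Regulon(sub)

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Regulon":
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = {"tf", "target", "mode"}
        lower = {c.lower(): c for c in df.columns}
        rename = {}
        for want, aliases in (
            ("tf", ("tf", "source", "regulator")),
            ("target", ("target",)),
            ("mode", ("mode", "mor", "sign")),
            ("weight", ("weight", "confidence")),
        ):
            for a in aliases:
                if a in lower:
                    rename[lower[a]] = want
                    break
        df = df.rename(columns=rename)
        if not required <= set(df.columns):
            raise DataError(f"regulon file needs columns {sorted(required)}")
        if len(df) == 0:
            raise DataError(f"empty regulon file: {path}")
        modes = []
        for raw in df["mode"]:
            key = str(raw).strip()
            if key in _MODE_ALIASES:
                modes.append(_MODE_ALIASES[key])
            else:
                try:
                    v = float(key)
                except ValueError:
                    raise DataError(f"unparseable regulation mode {raw!r}")
                if v not in (-1.0, 1.0):
                    raise DataError(f"regulation mode must normalise to ±1, got {raw!r}")
                modes.append(int(v))
        df["mode"] = modes
        if "weight" not in df.columns:
            df["weight"] = 1.0
        else:
            df["weight"] = df["weight"].astype(float).fillna(1.0)
        return cls(df)


def read_regulon(path: str | Path) -> Regulon:
    return Regulon.from_tsv(path)


@dataclasses.dataclass
class NetworkEdgeTable:
    """Edge list with fixed columns source/target/weight/sign/correlation/provenance."""

    edges: pd.DataFrame
    directed: bool = True

    def __post_init__(self) -> None:
        e = self.edges.copy()
        for col in _EDGE_COLUMNS:
            if col not in e.columns:
                e[col] = np.nan if col in ("weight", "sign", "correlation") else ""
        e = e.loc[:, list(_EDGE_COLUMNS) + [c for c in e.columns if c not in _EDGE_COLUMNS]]
        if len(e) and (e["source"] == e["target"]).any():
            raise DataError("self-loops are not allowed in network edge tables")
        self.edges = e.reset_index(drop=True)

    @property
    def nodes(self) -> list[str]:
        return sorted(set(self.edges["source"]) | set(self.edges["target"]))

    def __len__(self) -> int:
        return len(self.edges)

    def to_graph(self, node_attrs: dict[str, dict] | None = None) -> nx.Graph:
        g: nx.Graph = nx.DiGraph() if self.directed else nx.Graph()
        g.add_nodes_from(self.nodes)
        for row in self.edges.itertuples(index=False):
            attrs = {}
            for col in ("weight", "sign", "correlation"):
                v = getattr(row, col)
                if pd.notna(v):
                    attrs[col] = float(v)
            prov = getattr(row, "provenance")
            if isinstance(prov, str) and prov:
                attrs["provenance"] = prov
            g.add_edge(row.source, row.target, **attrs)
        if node_attrs:
            for name, mapping in node_attrs.items():
                nx.set_node_attributes(g, mapping, name)
        return g


def write_network(
    net: NetworkEdgeTable,
    path: str | Path,
    fmt: str = "tsv",
    node_attrs: dict[str, dict] | None = None,
) -> None:
    """Write a network as edge-TSV or GraphML (node attributes GraphML-only)."""
    if fmt == "tsv":
        net.edges.loc[:, _EDGE_COLUMNS].to_csv(path, sep="\t", index=False)
    elif fmt == "graphml":
        nx.write_graphml(net.to_graph(node_attrs=node_attrs), str(path))
    else:
        raise DataError(f"unknown network format {fmt!r}; expected 'tsv' or 'graphml'")


def read_network(path: str | Path, directed: bool = True) -> NetworkEdgeTable:
    df = pd.read_csv(path, sep="\t", dtype={"source": str, "target": str},
                     float_precision="round_trip")
    return NetworkEdgeTable(df, directed=directed)


def edge_table(
    rows: Sequence[tuple],
    columns: Sequence[str] = ("source", "target", "weight"),
    directed: bool = True,
    provenance: str = "",
) -> NetworkEdgeTable:
    """Convenience constructor from row tuples."""
    df = pd.DataFrame(list(rows), columns=list(columns))
    if "provenance" not in df.columns and provenance:
        df["provenance"] = provenance
    return NetworkEdgeTable(df, directed=directed)
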