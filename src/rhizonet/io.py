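"""Domain types and tabular/network I/O.

The pipeline's central container is :class:`CountTable`, a taxa-by-samples
matrix of raw integer counts. Sample metadata, phenotype panels, and taxon
annotations travel as :class:`pandas.DataFrame` objects with documented
column contracts. Inferred co-occurrence structures are wrapped in
:class:`Network`, a thin layer over :class:`networkx.Graph` that carries
per-edge association statistics.

All matrices in the pipeline use one canonical sample order: lexicographic
by sample identifier. This makes every downstream artifact deterministic
with respect to input row/column ordering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Columns a sample-metadata table must provide.
METADATA_COLUMNS = ("sample_id", "treatment", "cultivar", "growth_stage", "field_block")

#: Columns a taxon-annotation table must provide.
ANNOTATION_COLUMNS = ("taxon_id", "domain", "lineage", "lifestyle")

#: Edge attributes carried by every co-occurrence edge.
EDGE_ATTRS = ("coefficient", "p", "q", "sign")


class TableError(ValueError):
    """Raised when an input table violates its contract."""


# ---------------------------------------------------------------------------
# CountTable
# ---------------------------------------------------------------------------


@dataclass
class CountTable:
    """Taxa x samples matrix of non-negative integer counts.

    Parameters
    ----------
    taxon_ids
        Row identifiers; unique.
    sample_ids
        Column identifiers; unique.
    counts
        Integer array of shape ``(len(taxon_ids), len(sample_ids))`` with
        all entries >= 0.
    """

    taxon_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape != (len(self.taxon_ids), len(self.sample_ids)):
            raise TableError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.taxon_ids)} taxa x {len(self.sample_ids)} samples"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(counts, 1), 0)):
                raise TableError("counts must be integers")
            counts = counts.astype(np.int64)
        else:
            counts = counts.astype(np.int64)
        if (counts < 0).any():
            i, j = np.argwhere(counts < 0)[0]
            raise TableError(
                f"negative count at taxon {self.taxon_ids[i]!r}, sample {self.sample_ids[j]!r}"
            )
        _check_unique(self.taxon_ids, "taxon")
        _check_unique(self.sample_ids, "sample")
        self.counts = counts

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.taxon_ids, columns=self.sample_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CountTable":
        return cls(list(df.index), list(df.columns), df.to_numpy())

    def select_samples(self, sample_ids: Sequence[str]) -> "CountTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return CountTable(list(self.taxon_ids), list(sample_ids), self.counts[:, idx])

    def select_taxa(self, taxon_ids: Sequence[str]) -> "CountTable":
        idx = [self.taxon_ids.index(t) for t in taxon_ids]
        return CountTable(list(taxon_ids), list(self.sample_ids), self.counts[idx, :])

    def drop_empty_samples(self) -> "CountTable":
        """Drop samples with no positive count (logged), as for failed libraries."""
        keep = self.counts.sum(axis=0) > 0
        if keep.all():
            return self
        dropped = [s for s, k in zip(self.sample_ids, keep) if not k]
        logger.warning("dropping %d all-zero sample(s): %s", len(dropped), dropped)
        return CountTable(
            list(self.taxon_ids),
            [s for s, k in zip(self.sample_ids, keep) if k],
            self.counts[:, keep],
        )


def _check_unique(ids: Sequence[str], kind: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise TableError(f"duplicate {kind} identifier: {x!r}")
        seen.add(x)


def read_count_table(path: str | Path) -> CountTable:
    """Read a tab-separated count table (taxa rows, first column = taxon id).

    Rejects duplicate identifiers, ragged rows, and non-integer or negative
    cells with errors naming the offending location.
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise TableError(f"{path}: header must name at least one sample")
        sample_ids = header[1:]
        taxon_ids: list[str] = []
        rows: list[list[int]] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise TableError(
                    f"{path}:{lineno}: ragged row ({len(parts)} fields, expected {len(header)})"
                )
            taxon_ids.append(parts[0])
            try:
                row = [int(x) for x in parts[1:]]
            except ValueError as exc:
                raise TableError(f"{path}:{lineno}: non-integer count ({exc})") from None
            rows.append(row)
    counts = np.asarray(rows, dtype=np.int64).reshape(len(taxon_ids), len(sample_ids))
    return CountTable(taxon_ids, sample_ids, counts)


def write_count_table(ct: CountTable, path: str | Path) -> None:
    ct.to_dataframe().to_csv(path, sep="\t", index_label="taxon_id")


# ---------------------------------------------------------------------------
# Metadata / phenotype / annotation tables
# ---------------------------------------------------------------------------


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read sample metadata; one row per sample, columns per METADATA_COLUMNS."""
    md = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in METADATA_COLUMNS if c not in md.columns]
    if missing:
        raise TableError(f"metadata missing columns: {missing}")
    _check_unique(list(md["sample_id"]), "sample")
    return md


def write_metadata(md: pd.DataFrame, path: str | Path) -> None:
    md.to_csv(path, sep="\t", index=False)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read a wide phenotype table: sample_id column + one column per phenotype.

    All cells must be finite reals; missing values are rejected.
    """
    ph = pd.read_csv(path, sep="\t")
    if "sample_id" not in ph.columns:
        raise TableError("phenotype table missing 'sample_id' column")
    ph["sample_id"] = ph["sample_id"].astype(str)
    _check_unique(list(ph["sample_id"]), "sample")
    values = ph.drop(columns="sample_id")
    arr = values.to_numpy(dtype=float)
    if not np.all(np.isfinite(arr)):
        bad = values.columns[np.argwhere(~np.isfinite(arr))[0][1]]
        raise TableError(f"non-finite phenotype value in column {bad!r}")
    return ph


def write_phenotypes(ph: pd.DataFrame, path: str | Path) -> None:
    ph.to_csv(path, sep="\t", index=False)


def read_annotations(path: str | Path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise TableError(f"annotation table missing columns: {missing}")
    return ann


# ---------------------------------------------------------------------------
# Network
# ---------------------------------------------------------------------------


@dataclass
class Network:
    """Undirected signed association network over taxa.

    Nodes are taxon identifiers; every edge carries ``coefficient`` (in
    [-1, 1]), ``p``, ``q`` and ``sign`` attributes. No self-edges.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple[str, str, float, float, float]]
    ) -> "Network":
        """Build from (u, v, coefficient, p, q) tuples."""
        g = nx.Graph()
        for u, v, coef, p, q in edges:
            if u == v:
                raise TableError(f"self-edge on node {u!r}")
            g.add_edge(u, v, coefficient=float(coef), p=float(p), q=float(q),
                       sign=1 if coef >= 0 else -1)
        return cls(g)

    @property
    def node_count(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def edge_count(self) -> int:
        return self.graph.number_of_edges()

    def degrees(self) -> dict[str, int]:
        return dict(self.graph.degree())

    def edge_table(self) -> pd.DataFrame:
        rows = []
        for u, v, data in sorted(self.graph.edges(data=True), key=lambda e: tuple(sorted((e[0], e[1])))):
            a, b = sorted((u, v))
            rows.append({"source": a, "target": b, **{k: data.get(k) for k in EDGE_ATTRS}})
        return pd.DataFrame(rows, columns=["source", "target", *EDGE_ATTRS])


def write_network(net: Network, path_prefix: str | Path) -> tuple[Path, Path]:
    """Write a network as an edge-list TSV and a GraphML document.

    Returns the two paths written. An empty network produces a header-only
    edge list and a valid node-free GraphML file.
    """
    prefix = Path(path_prefix)
    edge_path = prefix.with_suffix(".edges.tsv")
    graphml_path = prefix.with_suffix(".graphml")
    net.edge_table().to_csv(edge_path, sep="\t", index=False, float_format="%.12g")
    g = nx.Graph()
    g.add_nodes_from(net.graph.nodes(data=True))
    g.add_edges_from(net.graph.edges(data=True))
    nx.write_graphml(g, graphml_path)
    return edge_path, graphml_path


def read_network_graphml(path: str | Path) -> Network:
    return Network(nx.read_graphml(Path(path)))


def read_network_edges(path: str | Path) -> Network:
    df = pd.read_csv(path, sep="\t")
    return Network.from_edges(
        (r.source, r.target, r.coefficient, r.p, r.q) for r in df.itertuples()
    )


# ---------------------------------------------------------------------------
# Table alignment
# ---------------------------------------------------------------------------


@dataclass
class AlignedBundle:
    """Count table, metadata, and optional phenotypes on one sample order."""

    counts: CountTable
    metadata: pd.DataFrame
    phenotypes: pd.DataFrame | None = None

    @property
    def sample_ids(self) -> list[str]:
        return self.counts.sample_ids


def align_tables(
    ct: CountTable,
    md: pd.DataFrame,
    ph: pd.DataFrame | None = None,
) -> AlignedBundle:
    """Restrict all tables to the shared samples, in canonical order.

    The canonical order is lexicographic by sample identifier. Samples
    missing from any table are dropped with a logged warning; an empty
    intersection is a hard error.
    """
    sets = [set(ct.sample_ids), set(md["sample_id"].astype(str))]
    if ph is not None:
        sets.append(set(ph["sample_id"].astype(str)))
    shared = sorted(set.intersection(*sets))
    if not shared:
        raise TableError("no shared samples between input tables")
    dropped = sorted(set.union(*sets) - set(shared))
    if dropped:
        logger.warning("align_tables dropped %d sample(s): %s", len(dropped), dropped)
    ct2 = ct.select_samples(shared)
    md2 = (
        md.assign(sample_id=md["sample_id"].astype(str))
        .set_index("sample_id")
        .loc[shared]
        .reset_index()
    )
    ph2 = None
    if ph is not None:
        ph2 = (
            ph.assign(sample_id=ph["sample_id"].astype(str))
            .set_index("sample_id")
            .loc[shared]
            .reset_index()
        )
    return AlignedBundle(ct2, md2, ph2)
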