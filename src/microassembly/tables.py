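"""Data model and I/O for OTU tables, sample metadata, taxonomy and networks.

All tabular formats are tab-separated text with a header row (taxa as rows for
count tables); trees are newick; association networks are two- or three-column
edge lists.  Taxon identifiers form a single namespace shared across locations,
so edges from different networks are comparable by id.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

VALID_DOMAINS = ("bacteria", "fungi")


class DataError(ValueError):
    """Raised when an input file or table violates the data contract."""


@dataclasses.dataclass
class OtuTable:
    """Non-negative integer count matrix, taxa x samples, with domain labels.

    Parameters
    ----------
    counts : pandas.DataFrame
        Integer counts; index = taxon ids, columns = sample ids.
    domain : pandas.Series
        Per-taxon label, ``"bacteria"`` or ``"fungi"``, indexed like `counts`.
    """

    counts: pd.DataFrame
    domain: pd.Series

    def __post_init__(self) -> None:
        counts = self.counts
        if counts.index.duplicated().any():
            dups = counts.index[counts.index.duplicated()].unique().tolist()
            raise DataError(f"duplicate taxon ids: {dups}")
        if counts.columns.duplicated().any():
            dups = counts.columns[counts.columns.duplicated()].unique().tolist()
            raise DataError(f"duplicate sample ids: {dups}")
        values = counts.to_numpy()
        if values.size and values.min() < 0:
            raise DataError("negative counts are not allowed")
        missing = counts.index.difference(self.domain.index)
        if len(missing):
            raise DataError(f"taxa without a domain label: {list(missing)}")
        self.domain = self.domain.reindex(counts.index)
        bad = set(self.domain.unique()) - set(VALID_DOMAINS)
        if bad:
            raise DataError(f"unknown domain labels: {sorted(bad)}")

    # -- convenience views -------------------------------------------------
    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def depths(self) -> pd.Series:
        """Total reads per sample."""
        return self.counts.sum(axis=0)

    def subset_samples(self, sample_ids: Sequence[str]) -> "OtuTable":
        return OtuTable(self.counts.loc[:, list(sample_ids)], self.domain)

    def subset_domain(self, domain: str) -> "OtuTable":
        if domain not in VALID_DOMAINS:
            raise DataError(f"unknown domain {domain!r}")
        keep = self.domain.index[self.domain == domain]
        return OtuTable(self.counts.loc[keep], self.domain.loc[keep])

    # -- I/O ---------------------------------------------------------------
    def to_tsv(self, table_path: str | Path, taxonomy_path: str | Path | None = None) -> None:
        self.counts.rename_axis("taxon_id").to_csv(table_path, sep="\t")
        if taxonomy_path is not None:
            tax = pd.DataFrame({"taxon_id": self.counts.index, "domain": self.domain.values})
            tax.to_csv(taxonomy_path, sep="\t", index=False)


@dataclasses.dataclass
class SampleMetadata:
    """Sample design table: location code, plot number (1-10), subsample letter."""

    frame: pd.DataFrame  # index = sample_id; columns location, plot, subsample

    def __post_init__(self) -> None:
        required = {"location", "plot", "subsample"}
        missing = required - set(self.frame.columns)
        if missing:
            raise DataError(f"metadata missing columns: {sorted(missing)}")
        if self.frame.index.duplicated().any():
            raise DataError("duplicate sample ids in metadata")
        trip = self.frame[["location", "plot", "subsample"]]
        if trip.duplicated().any():
            raise DataError("duplicate (location, plot, subsample) triples")

    @property
    def locations(self) -> list[str]:
        return sorted(self.frame["location"].unique())

    def samples_in(self, location: str) -> list[str]:
        sel = self.frame.index[self.frame["location"] == location]
        return list(sel)

    def grouping(self) -> dict[str, list[str]]:
        """Mapping location -> sample ids."""
        return {loc: self.samples_in(loc) for loc in self.locations}

    def subset(self, sample_ids: Sequence[str]) -> "SampleMetadata":
        return SampleMetadata(self.frame.loc[list(sample_ids)])

    def to_tsv(self, path: str | Path) -> None:
        self.frame.rename_axis("sample_id").to_csv(path, sep="\t")


class AssociationNetwork:
    """Undirected association network over taxon ids with domain labels.

    Thin wrapper around :class:`networkx.Graph` enforcing the invariants: no
    self-edges, no duplicate edges, every endpoint labeled with a domain.
    """

    def __init__(self, graph: nx.Graph):
        for node, data in graph.nodes(data=True):
            if data.get("domain") not in VALID_DOMAINS:
                raise DataError(f"node {node!r} has no valid domain label")
        for u, v in graph.edges():
            if u == v:
                raise DataError(f"self-edge on node {u!r}")
        self.graph = graph

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple],
        domain_map: Mapping[str, str],
        nodes: Iterable[str] | None = None,
    ) -> "AssociationNetwork":
        g = nx.Graph()
        for item in edges:
            u, v = item[0], item[1]
            w = item[2] if len(item) > 2 else None
            if u == v:
                raise DataError(f"self-edge on node {u!r}")
            if w is None:
                g.add_edge(u, v)
            else:
                g.add_edge(u, v, weight=float(w))
        if nodes is not None:
            g.add_nodes_from(nodes)
        for node in g.nodes:
            if node not in domain_map:
                raise DataError(f"node {node!r} missing from domain map")
            g.nodes[node]["domain"] = domain_map[node]
        return cls(g)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def domains(self) -> dict[str, str]:
        return {n: d["domain"] for n, d in self.graph.nodes(data=True)}

    def edge_set(self) -> set[frozenset]:
        """Edges as unordered taxon-id pairs (the cross-network identity)."""
        return {frozenset((u, v)) for u, v in self.graph.edges()}

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("source\ttarget\tweight\n")
            for u, v, data in self.graph.edges(data=True):
                w = data.get("weight", 1.0)
                fh.write(f"{u}\t{v}\t{w}\n")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_taxonomy(path: str | Path) -> pd.DataFrame:
    """Read a taxonomy TSV mapping taxon_id -> domain (plus optional lineage)."""
    tax = pd.read_csv(path, sep="\t", dtype=str)
    if "taxon_id" not in tax.columns or "domain" not in tax.columns:
        raise DataError("taxonomy file needs 'taxon_id' and 'domain' columns")
    if tax["taxon_id"].duplicated().any():
        dups = tax.loc[tax["taxon_id"].duplicated(), "taxon_id"].tolist()
        raise DataError(f"duplicate taxon ids in taxonomy: {dups}")
    return tax.set_index("taxon_id")


def load_dataset(
    table_path: str | Path,
    metadata_path: str | Path,
    taxonomy_path: str | Path,
) -> tuple[OtuTable, SampleMetadata]:
    """Load an OTU count table, its sample metadata and taxonomy.

    Taxa labeled with a domain other than bacteria/fungi (e.g. sporadic
    archaea) are excluded at load time; taxa with no taxonomy entry at all are
    rejected.  Samples present in the table but absent from the metadata raise
    an error naming the sample.
    """
    counts = pd.read_csv(table_path, sep="\t", index_col=0)
    if counts.index.duplicated().any():
        dups = counts.index[counts.index.duplicated()].unique().tolist()
        raise DataError(f"duplicate taxon ids: {dups}")
    counts = counts.astype(np.int64)

    tax = read_taxonomy(taxonomy_path)
    missing = counts.index.difference(tax.index)
    if len(missing):
        raise DataError(f"taxa without taxonomy entry: {list(missing)}")
    domain = tax["domain"].reindex(counts.index)
    keep = domain.isin(VALID_DOMAINS)
    counts, domain = counts.loc[keep], domain.loc[keep]

    meta = pd.read_csv(metadata_path, sep="\t", index_col=0)
    absent = [s for s in counts.columns if s not in meta.index]
    if absent:
        raise DataError(f"samples without metadata: {absent}")
    metadata = SampleMetadata(meta.loc[list(counts.columns)])
    return OtuTable(counts, domain), metadata


def read_network(edge_list_path: str | Path, domain_map: Mapping[str, str]) -> AssociationNetwork:
    """Read an undirected edge-list TSV (source, target[, weight])."""
    frame = pd.read_csv(edge_list_path, sep="\t", dtype={0: str, 1: str})
    cols = list(frame.columns)
    if len(cols) < 2:
        raise DataError("edge list needs at least two columns")
    rows = frame.itertuples(index=False)
    edges = [tuple(row)[: 3 if len(cols) >= 3 else 2] for row in rows]
    return AssociationNetwork.from_edges(edges, domain_map)


# ---------------------------------------------------------------------------
# filtering and normalization
# ---------------------------------------------------------------------------

def filter_low_depth(
    table: OtuTable, min_reads: int = 5000
) -> tuple[OtuTable, list[str]]:
    """Drop samples with fewer than `min_reads` total reads (strict ``<``).

    Returns the filtered table and the list of dropped sample ids.  Samples at
    exactly the threshold are kept.
    """
    if min_reads <= 0:
        raise DataError("min_reads must be positive")
    depths = table.depths()
    dropped = list(depths.index[depths < min_reads])
    kept = [s for s in table.sample_ids if s not in set(dropped)]
    if not kept:
        raise DataError("depth filter removed every sample")
    return table.subset_samples(kept), dropped


def relative_abundance(table: OtuTable) -> pd.DataFrame:
    """Per-sample proportions; every column sums to 1."""
    totals = table.counts.sum(axis=0)
    zero = list(totals.index[totals == 0])
    if zero:
        raise DataError(f"zero-sum samples: {zero}")
    return table.counts / totals
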