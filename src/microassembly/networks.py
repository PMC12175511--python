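"""Bacterial-fungal association-network statistics and null models.

Covers the descriptive statistics reported for glacier-forefield networks
(node and edge counts per domain, linkage density 2E/N, edge density as a
percentage of realized node pairs, module counts), degree-preserving and
Erdos-Renyi-style random-network nulls, the cross-network shared-association
test with empirical p-values, and the projection of neutral-model classes
onto network nodes.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .tables import AssociationNetwork, DataError, OtuTable

NCM_CLASSES = ("neutral", "above", "below")


# ---------------------------------------------------------------------------
# edge extraction and descriptive statistics
# ---------------------------------------------------------------------------

def extract_bf_edges(network: AssociationNetwork) -> AssociationNetwork:
    """Keep only bacterial-fungal edges (drop within-domain associations).

    Nodes are retained even if they become isolated; isolates carry an
    ``isolated=True`` attribute.
    """
    domains = network.domains()
    g = nx.Graph()
    for node, dom in domains.items():
        g.add_node(node, domain=dom)
    for u, v, data in network.graph.edges(data=True):
        if domains[u] != domains[v]:
            g.add_edge(u, v, **data)
    for node in g.nodes:
        g.nodes[node]["isolated"] = g.degree(node) == 0
    return AssociationNetwork(g)


@dataclasses.dataclass
class NetworkStats:
    n_nodes: int
    n_bacteria: int
    n_fungi: int
    n_edges: int
    linkage_density: float      # average edges per node, 2E/N
    max_degree: int
    edge_density: float         # percent of realized node pairs, 0-100
    n_modules: int | None
    degree_mean_by_domain: dict[str, float]
    degree_sd_by_domain: dict[str, float]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def summary_from_counts(n_bacteria: int, n_fungi: int, n_edges: int) -> NetworkStats:
    """Linkage and edge density from bare node/edge counts.

    Useful for recomputing published per-network summaries when only the
    counts, not the edge lists, are available.
    """
    n = n_bacteria + n_fungi
    if n < 2:
        raise DataError("need at least 2 nodes")
    return NetworkStats(
        n_nodes=n,
        n_bacteria=n_bacteria,
        n_fungi=n_fungi,
        n_edges=n_edges,
        linkage_density=2.0 * n_edges / n,
        max_degree=0,
        edge_density=100.0 * n_edges / (n * (n - 1) / 2),
        n_modules=None,
        degree_mean_by_domain={},
        degree_sd_by_domain={},
    )


def network_stats(
    network: AssociationNetwork,
    modules: bool = True,
    seed: int = 0,
) -> NetworkStats:
    """Descriptive statistics of one association network."""
    g = network.graph
    n = g.number_of_nodes()
    if n == 0:
        raise DataError("empty network")
    e = g.number_of_edges()
    domains = network.domains()
    degs = dict(g.degree())
    by_dom_mean, by_dom_sd = {}, {}
    for dom in ("bacteria", "fungi"):
        vals = [degs[v] for v in g.nodes if domains[v] == dom]
        by_dom_mean[dom] = float(np.mean(vals)) if vals else float("nan")
        by_dom_sd[dom] = float(np.std(vals, ddof=1)) if len(vals) > 1 else float("nan")
    stats = NetworkStats(
        n_nodes=n,
        n_bacteria=sum(1 for v in g.nodes if domains[v] == "bacteria"),
        n_fungi=sum(1 for v in g.nodes if domains[v] == "fungi"),
        n_edges=e,
        linkage_density=2.0 * e / n,
        max_degree=max(degs.values()),
        edge_density=100.0 * e / (n * (n - 1) / 2) if n > 1 else float("nan"),
        n_modules=None,
        degree_mean_by_domain=by_dom_mean,
        degree_sd_by_domain=by_dom_sd,
    )
    if modules:
        partition, _ = detect_modules(network, seed=seed)
        stats.n_modules = len(partition)
    return stats


def core_degree_medians(
    network: AssociationNetwork, core_set: set[str]
) -> dict[str, dict[str, float]]:
    """Median degree of core vs non-core nodes, per domain."""
    g = network.graph
    domains = network.domains()
    out: dict[str, dict[str, float]] = {}
    for dom in ("bacteria", "fungi"):
        core_deg = [g.degree(v) for v in g.nodes if domains[v] == dom and v in core_set]
        rest_deg = [g.degree(v) for v in g.nodes if domains[v] == dom and v not in core_set]
        out[dom] = {
            "core_median_degree": float(np.median(core_deg)) if core_deg else float("nan"),
            "noncore_median_degree": float(np.median(rest_deg)) if rest_deg else float("nan"),
        }
    return out


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------

def detect_modules(
    network: AssociationNetwork, seed: int = 0
) -> tuple[list[set[str]], float]:
    """Greedy modularity maximization (deterministic); returns (partition, Q).

    Isolated nodes each form their own module; the partition covers every
    node.  `seed` is accepted for interface stability but the greedy
    algorithm itself is deterministic.
    """
    g = network.graph
    if g.number_of_edges() == 0:
        partition = [{v} for v in g.nodes]
        return partition, 0.0
    comms = nx.community.greedy_modularity_communities(g)
    partition = [set(c) for c in comms]
    q = nx.community.modularity(g, partition)
    return partition, float(q)


def compare_modules(
    partition_a: Sequence[set[str]], partition_b: Sequence[set[str]]
) -> dict:
    """Best-match Jaccard comparison of two module partitions.

    Restricted to nodes present in both partitions.  The summary score is
    the mean, over modules of each partition, of the best Jaccard similarity
    with any module of the other partition (averaged over both directions).
    """
    nodes_a = set().union(*partition_a) if partition_a else set()
    nodes_b = set().union(*partition_b) if partition_b else set()
    shared = nodes_a & nodes_b
    if not shared:
        return {"jaccard_matrix": np.zeros((0, 0)), "score": 0.0, "no_shared_nodes": True}
    pa = [m & shared for m in partition_a if m & shared]
    pb = [m & shared for m in partition_b if m & shared]
    mat = np.zeros((len(pa), len(pb)))
    for i, ma in enumerate(pa):
        for j, mb in enumerate(pb):
            mat[i, j] = len(ma & mb) / len(ma | mb)
    score = float((mat.max(axis=1).mean() + mat.max(axis=0).mean()) / 2.0)
    return {"jaccard_matrix": mat, "score": score, "no_shared_nodes": False}


# ---------------------------------------------------------------------------
# null models
# ---------------------------------------------------------------------------

def _typed_er_edge_set(network: AssociationNetwork, rng: np.random.Generator) -> set[frozenset]:
    """ER-null edge set preserving the count of each association type.

    Bacterial-bacterial, bacterial-fungal and fungal-fungal edge counts are
    each kept and redrawn uniformly among the node pairs of that type, so a
    purely bipartite network stays bipartite under the null.
    """
    domains = network.domains()
    bact = [v for v, d in domains.items() if d == "bacteria"]
    fung = [v for v, d in domains.items() if d == "fungi"]
    counts = {"bb": 0, "bf": 0, "ff": 0}
    for u, v in network.graph.edges():
        du, dv = domains[u], domains[v]
        key = "bf" if du != dv else ("bb" if du == "bacteria" else "ff")
        counts[key] += 1
    out: set[frozenset] = set()

    def _within(nodes, e):
        n = len(nodes)
        if e > n * (n - 1) // 2:
            raise DataError("more edges than node pairs")
        chosen: set[tuple[int, int]] = set()
        while len(chosen) < e:
            us = rng.integers(0, n, size=2 * (e - len(chosen)) + 8)
            vs = rng.integers(0, n, size=us.size)
            for u, v in zip(us, vs):
                if u != v:
                    chosen.add((u, v) if u < v else (v, u))
                    if len(chosen) == e:
                        break
        out.update(frozenset((nodes[u], nodes[v])) for u, v in chosen)

    def _between(a_nodes, b_nodes, e):
        if e > len(a_nodes) * len(b_nodes):
            raise DataError("more edges than node pairs")
        chosen: set[tuple[int, int]] = set()
        while len(chosen) < e:
            us = rng.integers(0, len(a_nodes), size=2 * (e - len(chosen)) + 8)
            vs = rng.integers(0, len(b_nodes), size=us.size)
            for u, v in zip(us, vs):
                chosen.add((u, v))
                if len(chosen) == e:
                    break
        out.update(frozenset((a_nodes[u], b_nodes[v])) for u, v in chosen)

    if counts["bb"]:
        _within(bact, counts["bb"])
    if counts["ff"]:
        _within(fung, counts["ff"])
    if counts["bf"]:
        _between(bact, fung, counts["bf"])
    return out


def _er_null(g: nx.Graph, rng: np.random.Generator) -> nx.Graph:
    """Uniform random graph on the same node set with the same edge count."""
    nodes = list(g.nodes)
    n, e = len(nodes), g.number_of_edges()
    out = nx.Graph()
    out.add_nodes_from((v, g.nodes[v]) for v in nodes)
    max_pairs = n * (n - 1) // 2
    if e > max_pairs:
        raise DataError("more edges than node pairs")
    chosen: set[tuple[int, int]] = set()
    while len(chosen) < e:
        need = e - len(chosen)
        us = rng.integers(0, n, size=2 * need + 8)
        vs = rng.integers(0, n, size=2 * need + 8)
        for u, v in zip(us, vs):
            if u == v:
                continue
            pair = (u, v) if u < v else (v, u)
            if pair in chosen:
                continue
            chosen.add(pair)
            if len(chosen) == e:
                break
    out.add_edges_from((nodes[u], nodes[v]) for u, v in chosen)
    return out


def _rewire_null(g: nx.Graph, rng: np.random.Generator, swaps_per_edge: int = 10) -> nx.Graph:
    """Degree-preserving randomization by double-edge swaps."""
    if g.number_of_edges() < 2:
        raise DataError("rewiring needs at least 2 edges")
    out = g.copy()
    nswap = swaps_per_edge * g.number_of_edges()
    # networkx uses the global random module unless given a seed; derive one
    nx.double_edge_swap(
        out, nswap=nswap, max_tries=100 * nswap, seed=int(rng.integers(2**31 - 1))
    )
    return out


def random_networks(
    network: AssociationNetwork,
    n: int,
    null_model: str = "rewire",
    seed: int | np.random.Generator = 0,
) -> Iterable[AssociationNetwork]:
    """Stream of `n` randomized networks.

    ``rewire`` preserves every node's degree exactly (double-edge swaps);
    ``er`` preserves only the node set and edge count (uniform edges).  Both
    produce simple graphs and are reproducible for a fixed seed.
    """
    if null_model not in ("rewire", "er"):
        raise DataError(f"unknown null model {null_model!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    for _ in range(n):
        g = _rewire_null(network.graph, rng) if null_model == "rewire" else _er_null(network.graph, rng)
        yield AssociationNetwork(g)


# ---------------------------------------------------------------------------
# shared associations
# ---------------------------------------------------------------------------

def shared_associations(
    networks_by_location: Mapping[str, AssociationNetwork],
    subset: Sequence[str] | None = None,
) -> set[frozenset]:
    """Edges (as unordered taxon-id pairs) present in every chosen network."""
    locs = list(subset) if subset is not None else list(networks_by_location)
    if len(locs) < 2:
        raise DataError("need at least two networks to intersect")
    edge_sets = [networks_by_location[loc].edge_set() for loc in locs]
    return set.intersection(*edge_sets)


@dataclasses.dataclass
class SharedEdgeTest:
    network_subset: list[str]
    observed_shared: int
    null_counts: np.ndarray
    p_empirical: float
    null_model: str
    two_sided: bool = False


def shared_edge_test(
    networks_by_location: Mapping[str, AssociationNetwork],
    subset: Sequence[str] | None = None,
    n: int = 999,
    null_model: str = "er",
    seed: int | np.random.Generator = 0,
    two_sided: bool = False,
) -> SharedEdgeTest:
    """Do the chosen networks share more associations than chance predicts?

    All networks in the subset are randomized jointly `n` times; the null
    distribution is the shared-edge count of each joint randomization and
    the one-sided empirical p is ``(1 + #{null >= observed}) / (n + 1)``
    (never zero, and 1 attainable).  The two-sided option doubles the
    smaller tail (capped at 1).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    locs = list(subset) if subset is not None else list(networks_by_location)
    observed = len(shared_associations(networks_by_location, locs))
    null_counts = np.empty(n, dtype=np.int64)
    if null_model == "er":
        # edge sets suffice for the intersection; skip graph construction.
        # the ER null here is stratified by association type so bipartite
        # networks stay bipartite (otherwise the null shared count would be
        # biased low and the test anti-conservative on the other tail)
        for r in range(n):
            sets = [_typed_er_edge_set(networks_by_location[loc], rng) for loc in locs]
            null_counts[r] = len(set.intersection(*sets))
    else:
        streams = {
            loc: random_networks(networks_by_location[loc], n, null_model, rng)
            for loc in locs
        }
        for r in range(n):
            sets = [next(streams[loc]).edge_set() for loc in locs]
            null_counts[r] = len(set.intersection(*sets))
    upper = (1 + int((null_counts >= observed).sum())) / (n + 1)
    if two_sided:
        lower = (1 + int((null_counts <= observed).sum())) / (n + 1)
        p = min(1.0, 2.0 * min(upper, lower))
    else:
        p = upper
    return SharedEdgeTest(locs, observed, null_counts, float(p), null_model, two_sided)


# ---------------------------------------------------------------------------
# neutral-model integration
# ---------------------------------------------------------------------------

def attach_ncm_classes(network: AssociationNetwork, ncm_results) -> dict:
    """Project per-OTU neutral-model classes onto network nodes.

    Returns node classes (``unassigned`` when a node was not in the fit),
    per-domain class percentages, and the edge class-pair contingency counts
    (unordered class pairs, summing to the edge count).
    """
    classes = ncm_results.per_otu["otu_class"]
    domains = network.domains()
    node_class = {
        v: (classes.get(v, "unassigned")) for v in network.graph.nodes
    }
    levels = list(NCM_CLASSES) + ["unassigned"]
    pct: dict[str, dict[str, float]] = {}
    for dom in ("bacteria", "fungi"):
        members = [v for v in node_class if domains[v] == dom]
        if not members:
            continue
        pct[dom] = {
            lev: 100.0 * sum(node_class[v] == lev for v in members) / len(members)
            for lev in levels
        }
    pair_counts: dict[tuple[str, str], int] = {}
    for u, v in network.graph.edges():
        key = tuple(sorted((node_class[u], node_class[v])))
        pair_counts[key] = pair_counts.get(key, 0) + 1
    contingency = pd.DataFrame(0, index=levels, columns=levels, dtype=int)
    for (a, b), c in pair_counts.items():
        contingency.loc[a, b] += c
    return {
        "node_class": node_class,
        "class_percent_by_domain": pct,
        "edge_class_pairs": pair_counts,
        "contingency": contingency,
    }


# ---------------------------------------------------------------------------
# demo network inference (plumbing only)
# ---------------------------------------------------------------------------

def naive_network_inference(
    table: OtuTable, threshold: float = 0.9, pseudocount: float = 1.0
) -> AssociationNetwork:
    """Simple correlation-based demo inferrer.

    Centered-log-ratio transform (with a pseudocount) followed by pairwise
    Pearson correlation; an edge is drawn where |r| >= threshold.  This is
    plumbing for end-to-end runs and is NOT equivalent to sparse inverse
    covariance approaches used for real survey data.
    """
    if not 0 < threshold < 1:
        raise DataError("threshold must lie in (0, 1)")
    if table.shape[1] < 20:
        raise DataError("need at least 20 samples for the demo inferrer")
    logs = np.log(table.counts.to_numpy(dtype=float) + pseudocount)
    clr = logs - logs.mean(axis=0, keepdims=True)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(clr)
    np.fill_diagonal(corr, 0.0)
    corr = np.nan_to_num(corr)
    taxa = table.taxon_ids
    edges = []
    ii, jj = np.where(np.triu(np.abs(corr) >= threshold, k=1))
    for i, j in zip(ii, jj):
        edges.append((taxa[i], taxa[j], float(corr[i, j])))
    return AssociationNetwork.from_edges(
        edges, dict(table.domain), nodes=taxa
    )
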