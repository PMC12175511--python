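"""Synthetic amplicon-survey generator for testing the assembly pipeline.

Emulates a four-location hierarchical soil survey (10 plots per location,
5 subsamples per plot) in which most taxa assemble neutrally — local
communities drift under immigration from a shared log-normal metacommunity —
while designated minorities are occupancy-inflated ("selected-for") or
occupancy-deflated ("selected-against").  Outputs use exactly the formats the
I/O layer reads (count tables, metadata, taxonomy, newick trees, edge lists),
and every generator is reproducible from its seed.
"""

from __future__ import annotations

import dataclasses
import string
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd
from numba import njit

from .neutral import ncm_predict
from .tables import AssociationNetwork, DataError, OtuTable, SampleMetadata


@dataclasses.dataclass
class SyntheticConfig:
    """Study-design parameters of the synthetic survey.

    Defaults mirror the emulated survey: 4 locations x 10 plots x 5
    subsamples (200 samples), read depths of 10,000 (comfortably above the
    5,000-read quality filter), local communities of 10,000 individuals
    drifting for 20 generations at immigration rate 0.1, and 5% of taxa each
    given five-fold inflated or deflated per-sample inclusion odds.
    """

    seed: int = 0
    n_locations: int = 4
    plots_per_location: int = 10
    subsamples_per_plot: int = 5
    s_meta: int = 2000
    sad_lognormal_mean: float = 0.0
    sad_lognormal_sd: float = 2.0
    j_local: int = 10_000
    m: float = 0.1
    generations: int = 20
    depth: int = 10_000
    frac_selected_for: float = 0.05
    frac_selected_against: float = 0.05
    selection_strength: float = 5.0
    domain_split: float = 0.85  # fraction of taxa labeled bacterial

    def __post_init__(self) -> None:
        if not 0 < self.m <= 1:
            raise DataError("m must lie in (0, 1]")
        if self.j_local < 10:
            raise DataError("j_local must be at least 10")
        if not (0 <= self.frac_selected_for <= 1 and 0 <= self.frac_selected_against <= 1):
            raise DataError("selected fractions must lie in [0, 1]")
        if self.frac_selected_for + self.frac_selected_against > 1:
            raise DataError("selected fractions sum above 1")
        if self.s_meta < 2:
            raise DataError("s_meta must be at least 2")

    @property
    def n_samples(self) -> int:
        return self.n_locations * self.plots_per_location * self.subsamples_per_plot


# ---------------------------------------------------------------------------
# metacommunity and local drift
# ---------------------------------------------------------------------------

def simulate_metacommunity(
    s_meta: int, sad_params: tuple[float, float] = (0.0, 2.0), seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Log-normal species-abundance distribution, normalized to sum to 1."""
    if s_meta < 2:
        raise DataError("s_meta must be at least 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mu, sd = sad_params
    raw = rng.lognormal(mean=mu, sigma=sd, size=s_meta)
    return raw / raw.sum()


@njit(cache=True)
def _moran_run(individuals, meta_cdf, m, steps, uniforms, choices, sources):
    """In-place Moran urn: one death + one replacement per step.

    `uniforms` picks the metacommunity parent via the CDF, `choices` holds
    pre-drawn individual indices (death, local parent), `sources` the
    immigration coin flips.
    """
    for t in range(steps):
        dead = choices[2 * t]
        if sources[t] < m:
            # immigrant: invert the metacommunity CDF
            u = uniforms[t]
            lo, hi = 0, meta_cdf.size - 1
            while lo < hi:
                mid = (lo + hi) // 2
                if meta_cdf[mid] < u:
                    lo = mid + 1
                else:
                    hi = mid
            individuals[dead] = lo
        else:
            # parent drawn uniformly (it may be the dying individual itself,
            # i.e. it reproduces in the same event; standard Moran sampling)
            individuals[dead] = individuals[choices[2 * t + 1]]


def simulate_neutral_local(
    metacommunity: np.ndarray,
    j_local: int,
    m: float,
    generations: int,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Counts of individuals per taxon after immigration-drift dynamics.

    The local community starts as a random draw of `j_local` individuals
    from the metacommunity and then experiences ``generations * j_local``
    Moran events: a uniformly chosen individual dies and is replaced by an
    immigrant (probability m, parent drawn by metacommunity abundance) or by
    the offspring of a local individual (probability 1 - m).  Community size
    is conserved exactly at every step.
    """
    if j_local < 10:
        raise DataError("j_local must be at least 10")
    if not 0 <= m <= 1:  # m = 0 permitted here: pure drift to fixation
        raise DataError("m must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    s = metacommunity.size
    meta_cdf = np.cumsum(metacommunity)
    meta_cdf[-1] = 1.0
    individuals = rng.choice(s, size=j_local, p=metacommunity).astype(np.int64)
    steps = int(generations) * j_local
    if steps:
        uniforms = rng.random(steps)
        sources = rng.random(steps)
        choices = rng.integers(0, j_local, size=2 * steps)
        _moran_run(individuals, meta_cdf, m, steps, uniforms, choices, sources)
    return np.bincount(individuals, minlength=s)


# ---------------------------------------------------------------------------
# full survey
# ---------------------------------------------------------------------------

def _selection_flip_probs(config: SyntheticConfig, meta: np.ndarray,
                          truth_class: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-taxon probabilities implementing the inclusion-odds perturbation.

    The baseline presence probability q of each taxon is the neutral
    beta-CDF prediction at Nm = j_local * m with detection limit 1/depth.
    Selected-for taxa get odds multiplied by the selection strength: when a
    sample would lack the taxon, it is injected with probability
    (q' - q)/(1 - q).  Selected-against taxa get odds divided by the
    strength: when present, the taxon is removed with probability 1 - q'/q.
    """
    nm = config.j_local * config.m
    d = 1.0 / config.depth
    q = np.asarray(ncm_predict(np.clip(meta, 1e-12, 1 - 1e-12), nm, d))
    q = np.clip(q, 1e-9, 1.0 - 1e-9)
    s = config.selection_strength
    odds = q / (1.0 - q)
    q_up = (s * odds) / (1.0 + s * odds)
    q_dn = (odds / s) / (1.0 + odds / s)
    inject = np.zeros_like(q)
    remove = np.zeros_like(q)
    sel_for = truth_class == "selected_for"
    sel_against = truth_class == "selected_against"
    inject[sel_for] = np.clip((q_up[sel_for] - q[sel_for]) / (1.0 - q[sel_for]), 0, 1)
    remove[sel_against] = np.clip(1.0 - q_dn[sel_against] / q[sel_against], 0, 1)
    return inject, remove


def simulate_dataset(
    config: SyntheticConfig,
) -> tuple[OtuTable, SampleMetadata, dict]:
    """Full synthetic survey: OTU table, metadata, and a truth record.

    Each sample is an independent neutral local community, read-sampled
    multinomially at the configured depth; the designated selected taxa then
    receive the per-sample inclusion-odds perturbation as read transfers
    against the sample's dominant taxon (depths stay exact).  The truth
    record lists every taxon's class and the generating parameters.
    """
    rng = np.random.default_rng(config.seed)
    s = config.s_meta
    meta = simulate_metacommunity(
        s, (config.sad_lognormal_mean, config.sad_lognormal_sd), rng
    )
    taxon_ids = [f"otu{i:05d}" for i in range(s)]
    n_bact = int(round(config.domain_split * s))
    domain = pd.Series(
        ["bacteria"] * n_bact + ["fungi"] * (s - n_bact), index=taxon_ids
    )

    truth_class = np.array(["neutral"] * s, dtype=object)
    n_for = int(round(config.frac_selected_for * s))
    n_against = int(round(config.frac_selected_against * s))
    special = rng.choice(s, size=n_for + n_against, replace=False)
    truth_class[special[:n_for]] = "selected_for"
    truth_class[special[n_for:]] = "selected_against"
    inject, remove = (
        _selection_flip_probs(config, meta, truth_class)
        if n_for + n_against
        else (np.zeros(s), np.zeros(s))
    )

    locations = [string.ascii_uppercase[i] for i in range(config.n_locations)]
    sub_letters = string.ascii_uppercase[: config.subsamples_per_plot]
    sample_ids, meta_rows = [], []
    columns = {}
    inject_reads = 2  # minimal reliably-detectable abundance footprint
    for loc in locations:
        for plot in range(1, config.plots_per_location + 1):
            for sub in sub_letters:
                sid = f"{loc}{plot}{sub}"
                local = simulate_neutral_local(
                    meta, config.j_local, config.m, config.generations, rng
                )
                reads = rng.multinomial(config.depth, local / local.sum())
                if n_for + n_against:
                    # occupancy perturbation in read space: presence flips
                    # trade reads with the sample's dominant taxon, so the
                    # depth stays exact and the abundance footprint minimal
                    u = rng.random(s)
                    for i in np.flatnonzero((u < remove) & (reads > 0)):
                        top = int(np.argmax(reads))
                        if top != i:
                            reads[top] += reads[i]
                            reads[i] = 0
                    for i in np.flatnonzero((u < inject) & (reads == 0)):
                        top = int(np.argmax(reads))
                        take = min(inject_reads, reads[top] - 1)
                        if top != i and take > 0:
                            reads[top] -= take
                            reads[i] = take
                columns[sid] = reads
                sample_ids.append(sid)
                meta_rows.append({"location": loc, "plot": plot, "subsample": sub})

    counts = pd.DataFrame(columns, index=taxon_ids)
    table = OtuTable(counts, domain)
    metadata = SampleMetadata(
        pd.DataFrame(meta_rows, index=pd.Index(sample_ids, name="sample_id"))
    )
    truth = {
        "taxon_class": dict(zip(taxon_ids, truth_class)),
        "metacommunity": dict(zip(taxon_ids, meta)),
        "config": dataclasses.asdict(config),
    }
    return table, metadata, truth


# ---------------------------------------------------------------------------
# trees and clustered communities
# ---------------------------------------------------------------------------

def simulate_tree(
    s: int, seed: int = 0, prefix: str = "otu", birth_rate: float = 1.0
) -> dendropy.Tree:
    """Yule (pure-birth) tree with `s` tips and exponential branch waits.

    Grown by repeatedly splitting a uniformly chosen extant lineage; all
    branch lengths are strictly positive.  Tip labels are ``{prefix}00000``
    onward, matching synthetic OTU ids.
    """
    if s < 3:
        raise DataError("need at least 3 tips")
    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node.edge.length = 0.0
    leaves = [tree.seed_node]
    # lineage birth: pick a leaf, give it two children
    while len(leaves) < s:
        wait = rng.exponential(1.0 / (birth_rate * len(leaves)))
        for leaf in leaves:
            leaf.edge.length = (leaf.edge.length or 0.0) + wait
        victim = leaves.pop(rng.integers(len(leaves)))
        for _ in range(2):
            child = victim.new_child()
            child.edge.length = 0.0
            leaves.append(child)
    final_wait = rng.exponential(1.0 / (birth_rate * len(leaves)))
    for leaf in leaves:
        leaf.edge.length = (leaf.edge.length or 0.0) + final_wait
    order = rng.permutation(len(leaves))
    for i, leaf in zip(order, leaves):
        leaf.taxon = taxa.new_taxon(f"{prefix}{i:05d}")
    # the root is not a branch: drop the length accumulated while the seed
    # node was still the only extant lineage
    tree.seed_node.edge.length = None
    return tree


def simulate_clustered_community(
    tree: dendropy.Tree, clade_bias: float, size: int, seed: int | np.random.Generator = 0
) -> list[str]:
    """Community of tip labels with tunable phylogenetic clustering.

    With bias 0 the community is a uniform random subset of tips; with bias
    1 every member comes from one randomly chosen clade of at least `size`
    tips; intermediate biases mix the two per member.
    """
    if not 0 <= clade_bias <= 1:
        raise DataError("clade_bias must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if size >= len(tips):
        raise DataError("community size must be below the number of tips")
    if clade_bias == 0:
        return list(rng.choice(tips, size=size, replace=False))
    candidates = []
    for node in tree.preorder_internal_node_iter():
        clade_tips = [leaf.taxon.label for leaf in node.leaf_iter()]
        if size <= len(clade_tips) < len(tips):
            candidates.append(clade_tips)
    if not candidates:
        raise DataError("no clade large enough for the requested size")
    clade = candidates[rng.integers(len(candidates))]
    n_clade = int(round(clade_bias * size))
    chosen = list(rng.choice(clade, size=n_clade, replace=False))
    outside = [t for t in tips if t not in set(chosen)]
    chosen += list(rng.choice(outside, size=size - n_clade, replace=False))
    return chosen


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

def simulate_networks(
    locations: Sequence[str],
    nodes_per_location: int,
    edges_per_location: int,
    n_planted_shared: int = 0,
    seed: int = 0,
    pool_factor: float = 1.5,
    bacterial_fraction: float = 0.8,
) -> tuple[dict[str, AssociationNetwork], dict]:
    """Random bipartite bacterial-fungal networks with planted shared edges.

    Node sets are overlapping subsets of a global taxon pool; each location
    receives `edges_per_location` random bacterial-fungal edges, and the
    `n_planted_shared` planted pairs are inserted into every network (their
    endpoints are forced into every node set).  Returns the networks and a
    truth record of the planted pairs.
    """
    if n_planted_shared > edges_per_location:
        raise DataError("cannot plant more shared edges than edges per location")
    rng = np.random.default_rng(seed)
    pool_size = int(pool_factor * nodes_per_location)
    n_bact = int(round(bacterial_fraction * pool_size))
    bacteria = [f"b{i:04d}" for i in range(n_bact)]
    fungi = [f"f{i:04d}" for i in range(pool_size - n_bact)]
    if not fungi:
        raise DataError("pool has no fungal nodes")
    domain_map = {**{b: "bacteria" for b in bacteria}, **{f: "fungi" for f in fungi}}

    planted: set[frozenset] = set()
    while len(planted) < n_planted_shared:
        b = bacteria[rng.integers(len(bacteria))]
        f = fungi[rng.integers(len(fungi))]
        planted.add(frozenset((b, f)))
    planted_nodes = set().union(*planted) if planted else set()

    networks = {}
    for loc in locations:
        nodes = set(rng.choice(pool_size, size=nodes_per_location, replace=False))
        node_ids = {(bacteria + fungi)[i] for i in nodes} | planted_nodes
        loc_b = [v for v in node_ids if domain_map[v] == "bacteria"]
        loc_f = [v for v in node_ids if domain_map[v] == "fungi"]
        for pair in planted:
            if not pair <= node_ids:
                raise DataError(f"planted pair {set(pair)} missing from {loc}")
        edges = set(planted)
        while len(edges) < edges_per_location:
            b = loc_b[rng.integers(len(loc_b))]
            f = loc_f[rng.integers(len(loc_f))]
            edges.add(frozenset((b, f)))
        networks[loc] = AssociationNetwork.from_edges(
            [tuple(sorted(e)) for e in sorted(edges, key=sorted)],
            domain_map,
            nodes=node_ids,
        )
    truth = {"planted_pairs": [tuple(sorted(p)) for p in sorted(planted, key=sorted)]}
    return networks, truth
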