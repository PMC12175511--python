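"""Occupancy, core-microbiome partitioning, abundance-occupancy relation and
supporting alpha-diversity statistics.

Occupancy is defined per location as the fraction of that location's samples
in which an OTU is detected (count > 0).  The core microbiome is the set of
OTUs whose per-location occurrence count reaches a per-domain sample threshold
in *every* location (default: 10 samples for bacteria, 5 for fungi, the
convention for reducing sparsity in soil-survey association networks).
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .tables import DataError, OtuTable, relative_abundance

DEFAULT_CORE_THRESHOLDS = {"bacteria": 10, "fungi": 5}


@dataclasses.dataclass
class CoreSummary:
    """Result of the per-location occupancy filter and Venn partition."""

    retained: dict[str, set[str]]          # location -> retained taxon set
    venn: dict[frozenset, set[str]]        # location subset -> exclusive region
    core: set[str]                         # passes threshold in all locations

    @property
    def venn_counts(self) -> dict[frozenset, int]:
        return {region: len(taxa) for region, taxa in self.venn.items()}

    def union_size(self) -> int:
        out: set[str] = set()
        for taxa in self.retained.values():
            out |= taxa
        return len(out)


@dataclasses.dataclass
class AbundanceOccupancy:
    """Per-OTU occupancy vs mean relative abundance within one location."""

    location: str
    table: pd.DataFrame  # columns: mean_relative_abundance, occupancy, occupancy_to_abundance_ratio
    rho: float
    p_value: float
    constant_occupancy: bool = False


def occupancy(
    table: OtuTable, location_grouping: Mapping[str, Sequence[str]]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-OTU, per-location occupancy.

    Returns ``(fraction, n_samples)``: a taxa x locations frame of occupancy
    fractions and a matching frame of raw occurrence counts (the integer
    numerators used by the core thresholds).
    """
    frac = {}
    count = {}
    for loc, samples in location_grouping.items():
        if len(samples) == 0:
            raise DataError(f"location {loc!r} has no samples")
        present = (table.counts.loc[:, list(samples)] > 0).sum(axis=1)
        count[loc] = present
        frac[loc] = present / len(samples)
    return pd.DataFrame(frac), pd.DataFrame(count)


def core_partition(
    occurrence_counts: pd.DataFrame,
    domain: pd.Series,
    thresholds: Mapping[str, int] = DEFAULT_CORE_THRESHOLDS,
) -> CoreSummary:
    """Venn partition of per-location retained OTU sets.

    An OTU is retained in a location when its occurrence count there reaches
    the threshold for its domain.  The Venn partition assigns each retained
    OTU to the exact subset of locations in which it is retained; the core is
    the region covering all locations.
    """
    unknown = set(domain.unique()) - set(thresholds)
    if unknown:
        raise DataError(f"no threshold for domains: {sorted(unknown)}")
    thr = domain.map(thresholds)
    locations = list(occurrence_counts.columns)
    retained = {
        loc: set(occurrence_counts.index[occurrence_counts[loc] >= thr])
        for loc in locations
    }
    venn: dict[frozenset, set[str]] = {}
    for r in range(1, len(locations) + 1):
        for combo in itertools.combinations(locations, r):
            inside = set.intersection(*(retained[loc] for loc in combo))
            for loc in set(locations) - set(combo):
                inside -= retained[loc]
            venn[frozenset(combo)] = inside
    core = set.intersection(*retained.values()) if retained else set()
    return CoreSummary(retained=retained, venn=venn, core=core)


def core_abundance_fraction(
    table: OtuTable, core_set: set[str]
) -> dict[str, pd.DataFrame]:
    """Fraction of reads belonging to core OTUs, per sample and per domain.

    Denominators are domain-specific: the bacterial core fraction divides by
    each sample's total bacterial reads, the fungal one by fungal reads.
    Returns ``{"per_sample": frame, "mean": frame}`` with one column per
    domain.
    """
    unknown = core_set - set(table.taxon_ids)
    if unknown:
        raise DataError(f"core taxa not in table: {sorted(unknown)[:5]}")
    if not core_set:
        warnings.warn("empty core set; core abundance fraction is 0")
    per_sample = {}
    for dom in sorted(table.domain.unique()):
        sub = table.subset_domain(dom)
        totals = sub.counts.sum(axis=0)
        core_taxa = [t for t in sub.taxon_ids if t in core_set]
        core_reads = sub.counts.loc[core_taxa].sum(axis=0)
        with np.errstate(invalid="ignore"):
            frac = (core_reads / totals).fillna(0.0)
        per_sample[dom] = frac
    frame = pd.DataFrame(per_sample)
    return {"per_sample": frame, "mean": frame.mean(axis=0).to_frame("mean_fraction")}


def abundance_occupancy_relation(
    table: OtuTable, location: str, samples: Sequence[str]
) -> AbundanceOccupancy:
    """Occupancy vs mean relative abundance for OTUs detected in a location.

    Spearman's rank correlation (midrank ties, two-sided p) relates per-OTU
    mean relative abundance to occupancy.  The literal per-OTU ratio
    occupancy / mean relative abundance is emitted as an extra column for
    transparency but plays no role in the test.
    """
    sub = table.subset_samples(samples)
    detected = sub.counts.index[(sub.counts > 0).any(axis=1)]
    if len(detected) < 3:
        raise DataError(f"fewer than 3 OTUs detected in {location!r}")
    rel = relative_abundance(sub).loc[detected]
    mean_ra = rel.mean(axis=1)
    occ = (sub.counts.loc[detected] > 0).sum(axis=1) / len(samples)
    frame = pd.DataFrame(
        {
            "mean_relative_abundance": mean_ra,
            "occupancy": occ,
            "occupancy_to_abundance_ratio": occ / mean_ra,
        }
    )
    constant = occ.nunique() == 1 or mean_ra.nunique() == 1
    if constant:
        rho, p = float("nan"), float("nan")
    else:
        rho, p = stats.spearmanr(mean_ra, occ)
    return AbundanceOccupancy(
        location=location, table=frame, rho=float(rho), p_value=float(p),
        constant_occupancy=constant,
    )


# ---------------------------------------------------------------------------
# alpha diversity
# ---------------------------------------------------------------------------

def _faith_pd(tree, present_tips: set[str]) -> float:
    """Total branch length of the subtree spanning `present_tips` and the root."""
    node_keep = {}
    total = 0.0
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            keep = node.taxon is not None and node.taxon.label in present_tips
        else:
            keep = any(node_keep[id(c)] for c in node.child_nodes())
        node_keep[id(node)] = keep
        if keep and node.parent_node is not None:
            total += node.edge.length or 0.0
    return total


def alpha_diversity(table: OtuTable, tree=None) -> pd.DataFrame:
    """Per-sample richness, Shannon (nats), Simpson, Pielou evenness, Faith PD.

    Shannon = -sum p_i ln p_i over detected taxa; Simpson = 1 - sum p_i^2;
    evenness = Shannon / ln(richness) (NaN for single-taxon samples); Faith PD
    requires a dendropy tree whose tips cover the detected taxa.
    """
    rel = relative_abundance(table)
    rows = {}
    for sample in table.sample_ids:
        p = rel[sample].to_numpy()
        p = p[p > 0]
        richness = p.size
        shannon = float(-(p * np.log(p)).sum())
        simpson = float(1.0 - (p ** 2).sum())
        evenness = shannon / np.log(richness) if richness > 1 else float("nan")
        rows[sample] = {
            "richness": richness,
            "shannon": shannon,
            "simpson": simpson,
            "evenness": evenness,
        }
        if tree is not None:
            present = set(table.counts.index[table.counts[sample] > 0])
            rows[sample]["faith_pd"] = _faith_pd(tree, present)
    return pd.DataFrame(rows).T
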