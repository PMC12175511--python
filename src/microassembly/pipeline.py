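"""End-to-end orchestration of the community-assembly analysis.

Stage order mirrors the analysis flow of a survey: depth filter -> core
microbiome / Venn / abundance-occupancy -> neutral-model fits per location ->
NTI per sample with per-plot tests -> network statistics -> cross-network
shared-association test -> neutral-class projection onto networks.  A single
global seed is fanned out to per-stage seeds by fixed offsets so every stage
is reproducible in isolation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import core as core_mod
from . import networks as net_mod
from . import phylo, synthetic
from .neutral import SloanNCM
from .tables import (
    AssociationNetwork,
    DataError,
    OtuTable,
    SampleMetadata,
    filter_low_depth,
    load_dataset,
    read_network,
    read_taxonomy,
)

log = logging.getLogger("microassembly")

_STAGE_SEED_OFFSETS = {
    "simulate": 0,
    "ncm": 101,
    "nti": 202,
    "networks": 303,
    "shared": 404,
}


@dataclasses.dataclass
class PipelineConfig:
    """Validated pipeline options (see :func:`validate_config`)."""

    synthetic: synthetic.SyntheticConfig | None = None
    table_path: str | None = None
    metadata_path: str | None = None
    taxonomy_path: str | None = None
    tree_path: str | None = None
    network_paths: dict[str, str] | None = None
    min_reads: int = 5000
    core_thresholds: dict[str, int] = dataclasses.field(
        default_factory=lambda: dict(core_mod.DEFAULT_CORE_THRESHOLDS)
    )
    ncm_by_location: bool = True
    ncm_ci: float = 0.95
    ncm_d: float | None = None
    nti_n_null: int = 999
    nti_weighted: bool = False
    network_null: str = "rewire"
    network_n_null: int = 999
    inference_threshold: float = 0.9
    run_networks: bool = True
    run_nti: bool = True
    seed: int = 0
    outdir: str = "results"


def validate_config(raw: dict[str, Any] | None) -> PipelineConfig:
    """Normalize a parsed YAML dict; report all problems at once.

    An empty or missing document means "default synthetic mode".  Exactly one
    of {input paths, synthetic block} may be given.
    """
    raw = dict(raw or {})
    errors: list[str] = []
    cfg = PipelineConfig()

    has_paths = any(raw.get(k) for k in ("table_path", "metadata_path", "taxonomy_path"))
    has_synth = "synthetic" in raw
    if has_paths and has_synth:
        errors.append("give either input paths or a synthetic block, not both")
    if has_paths:
        for k in ("table_path", "metadata_path", "taxonomy_path"):
            if not raw.get(k):
                errors.append(f"input mode needs {k}")
            else:
                setattr(cfg, k, str(raw[k]))
        cfg.synthetic = None
        cfg.tree_path = raw.get("tree_path")
        nets = raw.get("network_paths")
        cfg.network_paths = {str(k): str(v) for k, v in nets.items()} if nets else None
    else:
        synth_raw = raw.get("synthetic") or {}
        try:
            cfg.synthetic = synthetic.SyntheticConfig(**synth_raw)
        except (TypeError, DataError) as exc:
            errors.append(f"synthetic block: {exc}")

    def _num(key, lo, hi, cast=float, lo_open=True, hi_open=True):
        if key not in raw:
            return
        try:
            val = cast(raw[key])
        except (TypeError, ValueError):
            errors.append(f"{key} must be a number")
            return
        below = val <= lo if lo_open else val < lo
        above = val >= hi if hi_open else val > hi
        if below or above:
            lob, hib = "(" if lo_open else "[", ")" if hi_open else "]"
            errors.append(f"{key} must be in {lob}{lo}, {hi}{hib}")
            return
        setattr(cfg, key, val)

    _num("ncm_ci", 0, 1)
    _num("min_reads", 0, 10**9, cast=int)
    _num("nti_n_null", 99, 10**6, cast=int, lo_open=False)
    _num("network_n_null", 1, 10**6, cast=int, lo_open=False)
    _num("inference_threshold", 0, 1)
    if "ncm_d" in raw and raw["ncm_d"] is not None:
        _num("ncm_d", 0, 1)
    for key in ("ncm_by_location", "nti_weighted", "run_networks", "run_nti"):
        if key in raw:
            if not isinstance(raw[key], bool):
                errors.append(f"{key} must be boolean")
            else:
                setattr(cfg, key, raw[key])
    if "network_null" in raw:
        if raw["network_null"] not in ("rewire", "er"):
            errors.append("network_null must be 'rewire' or 'er'")
        else:
            cfg.network_null = raw["network_null"]
    if "core_thresholds" in raw:
        thr = raw["core_thresholds"]
        if not isinstance(thr, dict) or not all(
            isinstance(v, int) and v >= 0 for v in thr.values()
        ):
            errors.append("core_thresholds must map domain to a non-negative integer")
        else:
            cfg.core_thresholds.update(thr)
    if "seed" in raw:
        cfg.seed = int(raw["seed"])
    if "outdir" in raw:
        cfg.outdir = str(raw["outdir"])

    if errors:
        raise DataError("invalid configuration: " + "; ".join(errors))
    return cfg


def _stage_seed(config: PipelineConfig, stage: str) -> int:
    return (config.seed + _STAGE_SEED_OFFSETS[stage]) % (2**31 - 1)


def run_pipeline(config: PipelineConfig, write: bool = True) -> dict:
    """Execute every stage and return the machine-readable summary.

    On stage failure the error is re-raised annotated with the stage name;
    outputs of completed stages remain on disk.
    """
    outdir = Path(config.outdir)
    if write:
        outdir.mkdir(parents=True, exist_ok=True)
    summary: dict[str, Any] = {"seed": config.seed, "stages": {}}

    stage = "load"
    try:
        t0 = time.time()
        tree = None
        networks: dict[str, AssociationNetwork] | None = None
        if config.synthetic is not None:
            synth_cfg = dataclasses.replace(
                config.synthetic, seed=_stage_seed(config, "simulate")
            )
            table, metadata, truth = synthetic.simulate_dataset(synth_cfg)
            tree = synthetic.simulate_tree(
                synth_cfg.s_meta, seed=_stage_seed(config, "simulate") + 1
            )
            summary["stages"]["simulate"] = {
                "n_samples": table.shape[1],
                "n_taxa": table.shape[0],
                "truth_classes": pd.Series(
                    list(truth["taxon_class"].values())
                ).value_counts().to_dict(),
            }
        else:
            table, metadata = load_dataset(
                config.table_path, config.metadata_path, config.taxonomy_path
            )
            if config.tree_path:
                import dendropy

                tree = dendropy.Tree.get(path=config.tree_path, schema="newick")
            if config.network_paths:
                tax = read_taxonomy(config.taxonomy_path)
                dmap = dict(tax["domain"])
                networks = {
                    loc: read_network(path, dmap)
                    for loc, path in config.network_paths.items()
                }
        log.info("stage load: %s taxa x %s samples (%.1fs)", *table.shape, time.time() - t0)

        # ---- depth filter -------------------------------------------------
        stage = "depth_filter"
        t0 = time.time()
        table, dropped = filter_low_depth(table, config.min_reads)
        metadata = metadata.subset(table.sample_ids)
        summary["stages"]["depth_filter"] = {
            "min_reads": config.min_reads,
            "n_dropped": len(dropped),
            "dropped": dropped,
            "n_samples": table.shape[1],
        }
        log.info("stage depth_filter: dropped %d (%.1fs)", len(dropped), time.time() - t0)

        # ---- core / venn / abundance-occupancy ---------------------------
        stage = "core"
        t0 = time.time()
        grouping = metadata.grouping()
        occ_frac, occ_counts = core_mod.occupancy(table, grouping)
        core_summary = core_mod.core_partition(
            occ_counts, table.domain, config.core_thresholds
        )
        frac = core_mod.core_abundance_fraction(table, core_summary.core)
        ao = {}
        for loc, samples in grouping.items():
            rel = core_mod.abundance_occupancy_relation(table, loc, samples)
            ao[loc] = {"rho": rel.rho, "p": rel.p_value, "n_otus": len(rel.table)}
            if write:
                rel.table.to_csv(outdir / f"ao_{loc}.tsv", sep="\t")
        summary["stages"]["core"] = {
            "core_size": len(core_summary.core),
            "core_by_domain": {
                dom: sum(1 for t in core_summary.core if table.domain[t] == dom)
                for dom in sorted(table.domain.unique())
            },
            "venn_counts": {
                "+".join(sorted(k)): v for k, v in core_summary.venn_counts.items()
            },
            "core_abundance_mean": frac["mean"]["mean_fraction"].to_dict(),
            "abundance_occupancy": ao,
        }
        if write:
            occ_frac.to_csv(outdir / "occupancy.tsv", sep="\t")
            with open(outdir / "venn.json", "w") as fh:
                json.dump(summary["stages"]["core"]["venn_counts"], fh, indent=1)
        log.info("stage core: core size %d (%.1fs)",
                 len(core_summary.core), time.time() - t0)

        # ---- neutral model ------------------------------------------------
        stage = "ncm"
        t0 = time.time()
        fits = {}
        ncm_block = {}
        units = grouping if config.ncm_by_location else {"pooled": table.sample_ids}
        for unit, samples in units.items():
            model = SloanNCM.from_otu_table(table, samples=samples, d=config.ncm_d)
            res = model.fit(ci=config.ncm_ci)
            fits[unit] = res
            ncm_block[unit] = {
                **res.to_json_dict(),
                "class_percent": res.class_summary(by_domain=False).iloc[0].to_dict(),
            }
            if write:
                res.per_otu.to_csv(outdir / f"ncm_{unit}.tsv", sep="\t")
        summary["stages"]["ncm"] = ncm_block
        log.info("stage ncm: %d fits (%.1fs)", len(fits), time.time() - t0)

        # ---- NTI ---------------------------------------------------------
        if config.run_nti and tree is not None:
            stage = "nti"
            t0 = time.time()
            labels, dist = phylo.patristic_distances(tree)
            pos = {lab: i for i, lab in enumerate(labels)}
            rng = np.random.default_rng(_stage_seed(config, "nti"))
            nti_rows = []
            for loc, samples in grouping.items():
                pool = [
                    t for t in table.taxon_ids
                    if (table.counts.loc[t, samples] > 0).any() and t in pos
                ]
                pool_idx = [pos[t] for t in pool]
                sub_dist = dist[np.ix_(pool_idx, pool_idx)]
                cache = phylo.neighbor_cache(sub_dist)
                loc_counts = table.counts.loc[pool, samples]
                for sid in samples:
                    present = list(loc_counts.index[loc_counts[sid] > 0])
                    if len(present) < 2:
                        continue
                    res = phylo.nti(
                        present, pool, sub_dist, n_null=config.nti_n_null,
                        seed=rng, community_id=sid, cache=cache,
                    )
                    row = metadata.frame.loc[sid]
                    nti_rows.append(
                        {"sample_id": sid, "location": loc, "plot": int(row["plot"]),
                         "mntd": res.mntd_obs, "nti": res.nti,
                         "undefined": res.undefined}
                    )
            nti_frame = pd.DataFrame(nti_rows).set_index("sample_id")
            tests = []
            for (loc, plot), grp in nti_frame.groupby(["location", "plot"]):
                vals = grp["nti"].dropna().tolist()
                if len(vals) < 2:
                    continue
                pt = phylo.plot_level_test(vals, loc, int(plot))
                tests.append(
                    {"location": loc, "plot": plot, "t": pt.t_statistic,
                     "p": pt.p_two_sided, "significant": pt.significant,
                     "zero_variance": pt.zero_variance}
                )
            summary["stages"]["nti"] = {
                "n_null": config.nti_n_null,
                "mean_by_location": nti_frame.groupby("location")["nti"].mean().to_dict(),
                "n_significant_plots": int(sum(t["significant"] for t in tests)),
                "n_plots_tested": len(tests),
            }
            if write:
                nti_frame.to_csv(outdir / "nti.tsv", sep="\t")
                pd.DataFrame(tests).to_csv(outdir / "nti_plot_tests.tsv", sep="\t", index=False)
            log.info("stage nti: %d samples (%.1fs)", len(nti_frame), time.time() - t0)

        # ---- networks ------------------------------------------------------
        if config.run_networks:
            stage = "networks"
            t0 = time.time()
            if networks is None:
                networks = {}
                for loc, samples in grouping.items():
                    sub = table.subset_samples(samples)
                    keep = [
                        t for t in sub.taxon_ids
                        if occ_counts.loc[t, loc]
                        >= config.core_thresholds.get(table.domain[t], 0)
                    ]
                    sub = OtuTable(sub.counts.loc[keep], sub.domain.loc[keep])
                    inferred = net_mod.naive_network_inference(
                        sub, threshold=config.inference_threshold
                    )
                    networks[loc] = net_mod.extract_bf_edges(inferred)
            stats_block = {}
            for loc, net in networks.items():
                st = net_mod.network_stats(net, seed=_stage_seed(config, "networks"))
                stats_block[loc] = st.to_dict()
                if write:
                    net.to_tsv(outdir / f"network_{loc}.tsv")
            summary["stages"]["networks"] = stats_block
            log.info("stage networks: %d networks (%.1fs)", len(networks), time.time() - t0)

            # ---- shared-association test --------------------------------
            stage = "shared_edges"
            t0 = time.time()
            if len(networks) >= 2 and all(n.n_edges >= 2 for n in networks.values()):
                test = net_mod.shared_edge_test(
                    networks, n=config.network_n_null,
                    null_model=config.network_null,
                    seed=_stage_seed(config, "shared"),
                )
                summary["stages"]["shared_edges"] = {
                    "observed_shared": test.observed_shared,
                    "p_empirical": test.p_empirical,
                    "null_model": test.null_model,
                    "n_null": config.network_n_null,
                }
                if write:
                    pd.DataFrame({"null_shared": test.null_counts}).to_csv(
                        outdir / "shared_null.tsv", sep="\t", index=False
                    )
            else:
                summary["stages"]["shared_edges"] = {"skipped": "too few networks or edges"}
            log.info("stage shared_edges (%.1fs)", time.time() - t0)

            # ---- NCM x network integration -------------------------------
            stage = "integrate_ncm"
            t0 = time.time()
            integration = {}
            for loc, net in networks.items():
                fit = fits.get(loc) or next(iter(fits.values()))
                att = net_mod.attach_ncm_classes(net, fit)
                integration[loc] = {
                    "class_percent_by_domain": att["class_percent_by_domain"],
                    "edge_class_pairs": {
                        "-".join(k): v for k, v in att["edge_class_pairs"].items()
                    },
                }
                if write:
                    att["contingency"].to_csv(
                        outdir / f"ncm_network_{loc}.tsv", sep="\t"
                    )
            summary["stages"]["integrate_ncm"] = integration
            log.info("stage integrate_ncm (%.1fs)", time.time() - t0)

        if write:
            with open(outdir / "summary.json", "w") as fh:
                json.dump(summary, fh, indent=1, default=str)
        return summary
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
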