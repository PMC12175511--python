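"""Published summary numbers from a four-forefield calcareous glacier survey.

These are inputs for worked examples and verification arithmetic: per-network
node/edge counts (from which linkage and edge density are recomputed) and the
survey-wide OTU and core-microbiome counts.  They are data, not results of
this package.
"""

from __future__ import annotations

# per-location bacterial-fungal network summaries
NETWORK_TABLE = {
    "Dachstein": {"n_bacteria": 1527, "n_fungi": 423, "n_edges": 10651, "n_modules": 29},
    "Griessen": {"n_bacteria": 1613, "n_fungi": 486, "n_edges": 14406, "n_modules": 27},
    "Marmolada": {"n_bacteria": 1645, "n_fungi": 551, "n_edges": 16411, "n_modules": 24},
    "Tsanfleuron": {"n_bacteria": 1920, "n_fungi": 337, "n_edges": 12825, "n_modules": 25},
}

# printed linkage density (1 d.p.), edge density (2 d.p.) and node totals
NETWORK_PRINTED = {
    "Dachstein": {"linkage_density": 10.9, "edge_density": 0.56, "n_nodes": 1950},
    "Griessen": {"linkage_density": 13.7, "edge_density": 0.65, "n_nodes": 2099},
    "Marmolada": {"linkage_density": 14.9, "edge_density": 0.68, "n_nodes": 2196},
    "Tsanfleuron": {"linkage_density": 11.4, "edge_density": 0.5, "n_nodes": 2257},
}

# survey-wide OTU bookkeeping
TOTAL_BACTERIAL_OTUS = 13_452
TOTAL_FUNGAL_OTUS = 4_312
CORE_BACTERIAL_OTUS = 474
CORE_FUNGAL_OTUS = 84     # reported core size 85; the printed ratio uses 84
CORE_BACTERIAL_PCT_PRINTED = 3.5
CORE_FUNGAL_PCT_PRINTED = 2.0
N_SAMPLES_AFTER_DEPTH_FILTER = 192
MIN_READS = 5_000
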