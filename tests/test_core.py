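import numpy as np
import pandas as pd
import pytest

from microassembly import core as core_mod
from microassembly.tables import DataError, OtuTable

from conftest import random_table


def _table_from_presence(presence, domain_label="bacteria"):
    """Build a table whose presence/absence pattern is given exactly."""
    counts = pd.DataFrame(
        np.asarray(presence, dtype=int) * 7,
        index=[f"t{i}" for i in range(len(presence))],
        columns=[f"s{j}" for j in range(len(presence[0]))],
    )
    domain = pd.Series([domain_label] * len(presence), index=counts.index)
    return OtuTable(counts, domain)


class TestOccupancy:
    def test_known_fraction(self):
        table = _table_from_presence([[1, 0, 1, 1, 0]])
        frac, count = core_mod.occupancy(table, {"L": table.sample_ids})
        assert frac.loc["t0", "L"] == 0.6
        assert count.loc["t0", "L"] == 3

    def test_absent_taxon_zero(self):
        table = _table_from_presence([[0, 0, 0], [1, 1, 1]])
        frac, _ = core_mod.occupancy(table, {"L": table.sample_ids})
        assert frac.loc["t0", "L"] == 0.0

    def test_twenty_percent_occupancy_at_10_of_50(self):
        presence = [[1] * 10 + [0] * 40]
        table = _table_from_presence(presence)
        frac, count = core_mod.occupancy(table, {"L": table.sample_ids})
        assert count.loc["t0", "L"] == 10
        assert frac.loc["t0", "L"] == pytest.approx(0.2)

    def test_invariant_to_sample_scaling(self, rng):
        table = random_table(rng, 30, 10)
        frac1, _ = core_mod.occupancy(table, {"L": table.sample_ids})
        scaled = OtuTable(table.counts * 13, table.domain)
        frac2, _ = core_mod.occupancy(scaled, {"L": scaled.sample_ids})
        assert (frac1 == frac2).all().all()

    def test_empty_location_rejected(self, small_table):
        with pytest.raises(DataError, match="no samples"):
            core_mod.occupancy(small_table, {"L": []})


class TestCorePartition:
    def _counts_from_sets(self, sets, all_taxa):
        # occurrence count 1 where retained (threshold 1), else 0
        return pd.DataFrame(
            {loc: [1 if t in s else 0 for t in all_taxa] for loc, s in sets.items()},
            index=all_taxa,
        )

    def test_three_location_core(self):
        sets = {"X": {"A", "B", "C"}, "Y": {"B", "C", "D"}, "Z": {"B", "E"}}
        taxa = sorted({"A", "B", "C", "D", "E"})
        counts = self._counts_from_sets(sets, taxa)
        domain = pd.Series(["bacteria"] * 5, index=taxa)
        summary = core_mod.core_partition(counts, domain, {"bacteria": 1})
        assert summary.core == {"B"}

    def test_zero_threshold_core_is_intersection_of_detected(self, rng):
        table = random_table(rng, 40, 12)
        grouping = {"L1": table.sample_ids[:6], "L2": table.sample_ids[6:]}
        _, counts = core_mod.occupancy(table, grouping)
        summary = core_mod.core_partition(
            counts, table.domain, {"bacteria": 1, "fungi": 1}
        )
        detected = {
            loc: set(counts.index[counts[loc] > 0]) for loc in grouping
        }
        assert summary.core == detected["L1"] & detected["L2"]

    def test_constructed_core_of_seven(self):
        # 20 taxa, 4 locations; taxa 0-6 retained everywhere, the rest
        # miss the threshold in at least one location
        taxa = [f"t{i}" for i in range(20)]
        counts = pd.DataFrame(10, index=taxa, columns=["A", "B", "C", "D"])
        for i, loc in zip(range(7, 20), ["A", "B", "C", "D"] * 4):
            counts.loc[f"t{i}", loc] = 2
        domain = pd.Series(["bacteria"] * 20, index=taxa)
        summary = core_mod.core_partition(counts, domain, {"bacteria": 5})
        # brute-force oracle by set algebra
        retained = {
            loc: set(counts.index[counts[loc] >= 5]) for loc in counts.columns
        }
        expected = set.intersection(*retained.values())
        assert summary.core == expected
        assert len(summary.core) == 7

    def test_venn_regions_partition_union(self, rng):
        for _ in range(20):
            table = random_table(rng, 30, 16)
            grouping = {
                "L1": table.sample_ids[:4],
                "L2": table.sample_ids[4:8],
                "L3": table.sample_ids[8:12],
                "L4": table.sample_ids[12:],
            }
            _, counts = core_mod.occupancy(table, grouping)
            summary = core_mod.core_partition(
                counts, table.domain, {"bacteria": 2, "fungi": 1}
            )
            union = set().union(*summary.retained.values())
            assert sum(summary.venn_counts.values()) == len(union)
            # regions are disjoint
            seen = set()
            for region in summary.venn.values():
                assert not (seen & region)
                seen |= region

    def test_unknown_domain_rejected(self):
        counts = pd.DataFrame({"A": [1]}, index=["x"])
        domain = pd.Series(["fungi"], index=["x"])
        with pytest.raises(DataError, match="threshold"):
            core_mod.core_partition(counts, domain, {"bacteria": 1})


class TestCoreAbundanceFraction:
    def test_full_core_is_one(self, small_table):
        out = core_mod.core_abundance_fraction(small_table, set(small_table.taxon_ids))
        assert np.allclose(out["per_sample"].to_numpy(), 1.0)

    def test_empty_core_is_zero_with_warning(self, small_table):
        with pytest.warns(UserWarning, match="empty core"):
            out = core_mod.core_abundance_fraction(small_table, set())
        assert np.allclose(out["per_sample"].to_numpy(), 0.0)

    def test_domain_specific_denominator(self):
        counts = pd.DataFrame({"s1": [30, 70, 10]}, index=["b_core", "b_other", "f1"])
        domain = pd.Series(
            ["bacteria", "bacteria", "fungi"], index=counts.index
        )
        table = OtuTable(counts, domain)
        out = core_mod.core_abundance_fraction(table, {"b_core"})
        assert out["per_sample"].loc["s1", "bacteria"] == pytest.approx(0.3)
        assert out["per_sample"].loc["s1", "fungi"] == pytest.approx(0.0)


class TestAbundanceOccupancy:
    def _monotone_table(self, reverse=False):
        # 3 taxa: abundance order matches (or reverses) occupancy order
        rows = [
            [1, 0, 0, 0, 0],   # rare, narrow
            [5, 5, 0, 0, 0],   # mid
            [20, 20, 20, 20, 20],  # abundant, everywhere
        ]
        counts = pd.DataFrame(
            rows, index=["t0", "t1", "t2"], columns=[f"s{j}" for j in range(5)]
        )
        return OtuTable(counts, pd.Series(["bacteria"] * 3, index=counts.index))

    def test_monotone_gives_rho_one(self):
        table = self._monotone_table()
        rel = core_mod.abundance_occupancy_relation(table, "L", table.sample_ids)
        assert rel.rho == pytest.approx(1.0)

    def test_anti_monotone_gives_rho_minus_one(self):
        # mean *relative* abundances are t0=0.49, t1=0.25625, t2=0.25375
        # while occupancy is 0.5, 0.75, 1.0: ranks exactly reversed
        counts = pd.DataFrame(
            [
                [980, 980, 0, 0],
                [15, 15, 995, 0],
                [5, 5, 5, 1000],
            ],
            index=["t0", "t1", "t2"],
            columns=["s0", "s1", "s2", "s3"],
        )
        table = OtuTable(counts, pd.Series(["bacteria"] * 3, index=counts.index))
        rel = core_mod.abundance_occupancy_relation(table, "L", table.sample_ids)
        assert rel.rho == pytest.approx(-1.0)

    def test_rho_matches_scipy_on_emitted_columns(self, rng):
        from scipy import stats

        table = random_table(rng, 40, 12)
        rel = core_mod.abundance_occupancy_relation(table, "L", table.sample_ids)
        expected = stats.spearmanr(
            rel.table["mean_relative_abundance"], rel.table["occupancy"]
        )
        assert rel.rho == pytest.approx(expected.statistic)
        assert rel.p_value == pytest.approx(expected.pvalue)

    def test_permutation_null_mean_rho_near_zero(self, rng):
        # independent abundance and occupancy ranks: mean rho over
        # replicates should vanish
        from scipy import stats

        rhos = []
        for _ in range(1000):
            x, y = rng.random(100), rng.random(100)
            rhos.append(stats.spearmanr(x, y).statistic)
        assert abs(np.mean(rhos)) < 0.05

    def test_constant_occupancy_flagged(self):
        counts = pd.DataFrame(
            [[1, 2], [3, 4], [5, 6]],
            index=["a", "b", "c"],
            columns=["s1", "s2"],
        )
        table = OtuTable(counts, pd.Series(["bacteria"] * 3, index=counts.index))
        rel = core_mod.abundance_occupancy_relation(table, "L", table.sample_ids)
        assert rel.constant_occupancy
        assert np.isnan(rel.rho)


class TestAlphaDiversity:
    def test_uniform_four_taxa(self):
        counts = pd.DataFrame({"s1": [25, 25, 25, 25]}, index=list("abcd"))
        table = OtuTable(counts, pd.Series(["bacteria"] * 4, index=counts.index))
        div = core_mod.alpha_diversity(table)
        assert div.loc["s1", "shannon"] == pytest.approx(np.log(4))
        assert div.loc["s1", "evenness"] == pytest.approx(1.0)

    def test_single_taxon_sample(self):
        counts = pd.DataFrame({"s1": [10, 0]}, index=["a", "b"])
        table = OtuTable(counts, pd.Series(["bacteria"] * 2, index=counts.index))
        div = core_mod.alpha_diversity(table)
        assert div.loc["s1", "shannon"] == 0.0
        assert div.loc["s1", "simpson"] == 0.0
        assert np.isnan(div.loc["s1", "evenness"])

    def test_shannon_maximal_iff_uniform(self, rng):
        uniform = np.full(10, 0.1)
        h_max = -(uniform * np.log(uniform)).sum()
        for _ in range(50):
            p = rng.dirichlet(np.ones(10))
            h = -(p[p > 0] * np.log(p[p > 0])).sum()
            assert h <= h_max + 1e-12

    def test_faith_pd_star_tree(self):
        import dendropy

        tree = dendropy.Tree.get(data="(a:1,b:1,c:1);", schema="newick")
        counts = pd.DataFrame({"s1": [5, 3, 0]}, index=["a", "b", "c"])
        table = OtuTable(counts, pd.Series(["bacteria"] * 3, index=counts.index))
        div = core_mod.alpha_diversity(table, tree=tree)
        assert div.loc["s1", "faith_pd"] == pytest.approx(2.0)

    def test_faith_pd_matches_skbio(self, rng):
        import dendropy
        import skbio
        from microassembly import synthetic

        tree = synthetic.simulate_tree(20, seed=5, prefix="x")
        newick = tree.as_string(schema="newick").replace("[&R] ", "")
        sk_tree = skbio.TreeNode.read([newick])
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        counts = pd.DataFrame(
            {"s1": rng.integers(0, 3, size=20)}, index=labels
        )
        counts.iloc[0, 0] = 1  # ensure non-empty
        table = OtuTable(counts, pd.Series(["bacteria"] * 20, index=labels))
        div = core_mod.alpha_diversity(table, tree=tree)
        present = [t for t in labels if counts.loc[t, "s1"] > 0]
        expected = skbio.diversity.alpha.faith_pd(
            [1] * len(present), taxa=present, tree=sk_tree
        )
        assert div.loc["s1", "faith_pd"] == pytest.approx(float(expected), rel=1e-6)
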