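"""Discordant-site predicate, summaries, binning, hotspots, co-localization."""

import numpy as np
import pandas as pd
import pytest

from ancpoly.discordance import (
    ClusterSpec,
    bin_sites,
    call_discordant_sites,
    cross_cluster_hotspot_overlap,
    discordant_site_summary,
    genes_with_discordant_sites,
    het_discordant_colocalization,
    hotspot_bins,
    propose_clusters,
)
from ancpoly.coding import CdsAnnotation
from ancpoly.tree import PhyloTree, branch_support, fitch_min_mutations

TREE = PhyloTree.from_newick("((Z1:1,Z2:1):1,(X1:1,X2:1):1,Y:1);")
CLUSTER = ClusterSpec("Z", ("Z1", "Z2"))
STRAINS = ["Z1", "Z2", "X1", "X2", "Y"]


def site(chrom, pos, calls):
    return (chrom, pos, "A", ["G"], calls)


class TestPredicate:
    def test_uniform_cluster_not_discordant(self, matrix_factory):
        m = matrix_factory(
            STRAINS,
            [site("c1", 10, {"Z1": ("hom", "G"), "Z2": ("hom", "G"), "X1": ("hom", "G")})],
        )
        assert len(call_discordant_sites(m, TREE, CLUSTER)) == 0

    def test_private_derived_allele_not_discordant(self, matrix_factory):
        # cluster split ref/alt but the alt occurs nowhere outside
        m = matrix_factory(STRAINS, [site("c1", 10, {"Z1": ("hom", "G")})])
        assert len(call_discordant_sites(m, TREE, CLUSTER)) == 0

    def test_both_alleles_outside_is_discordant(self, matrix_factory):
        m = matrix_factory(
            STRAINS,
            [site("c1", 10, {"Z1": ("hom", "G"), "X1": ("hom", "G")})],
        )
        table = call_discordant_sites(m, TREE, CLUSTER)
        assert list(table["pos"]) == [10]
        assert table.iloc[0]["alleles_in_cluster"] == "A,G"
        # and the parsimony oracle certifies >= 2 mutations
        char = {"Z1": "G", "Z2": "A", "X1": "G", "X2": "A", "Y": "A"}
        assert fitch_min_mutations(TREE, char) >= 2

    def test_het_member_makes_site_unevaluable(self, matrix_factory):
        m = matrix_factory(
            STRAINS,
            [site("c1", 10, {"Z1": ("hom", "G"), "Z2": ("het", ("A", "G")), "X1": ("hom", "G")})],
        )
        assert len(call_discordant_sites(m, TREE, CLUSTER)) == 0

    def test_outside_het_does_not_contribute_alleles(self, matrix_factory):
        m = matrix_factory(
            STRAINS,
            [site("c1", 10, {"Z1": ("hom", "G"), "X1": ("het", ("A", "G"))})],
        )
        assert len(call_discordant_sites(m, TREE, CLUSTER)) == 0

    def test_multiallelic_needs_two_shared(self, matrix_factory):
        spec = (
            "c1", 10, "A", ["G", "T"],
            {"Z1": ("hom", "G"), "Z2": ("hom", "T"), "X1": ("hom", "G"), "X2": ("hom", "C")},
        )
        # X2 carries a third allele; only G among {G, T} is shared outside
        m = matrix_factory(STRAINS, [("c1", 10, "A", ["G", "T", "C"], spec[4])])
        assert len(call_discordant_sites(m, TREE, CLUSTER)) == 0
        # add a T outside -> two shared within-cluster alleles -> discordant
        calls = dict(spec[4])
        calls["Y"] = ("hom", "T")
        m2 = matrix_factory(STRAINS, [("c1", 10, "A", ["G", "T", "C"], calls)])
        assert len(call_discordant_sites(m2, TREE, CLUSTER)) == 1

    def test_cluster_must_be_clade(self, matrix_factory):
        m = matrix_factory(STRAINS, [site("c1", 10, {})])
        with pytest.raises(ValueError, match="clade"):
            call_discordant_sites(m, TREE, ClusterSpec("bad", ("Z1", "X1")))

    def test_cluster_needs_two_members(self):
        with pytest.raises(ValueError):
            ClusterSpec("solo", ("Z1",))

    def test_monotone_in_outside_strains(self, matrix_factory):
        """Removing an outside strain can only shrink the called set."""
        rng = np.random.default_rng(71)
        kinds = [("hom", "A"), ("hom", "G"), ("het", ("A", "G")), "missing"]
        specs = [
            site("c1", p + 1, {s: kinds[rng.integers(4)] for s in STRAINS})
            for p in range(120)
        ]
        full = matrix_factory(STRAINS, specs)
        reduced_strains = [s for s in STRAINS if s != "Y"]
        reduced = matrix_factory(
            reduced_strains,
            [(c, p, r, a, {k: v for k, v in calls.items() if k != "Y"})
             for c, p, r, a, calls in specs],
        )
        small_tree = PhyloTree.from_newick("((Z1:1,Z2:1):1,(X1:1,X2:1):1);")
        full_set = set(call_discordant_sites(full, TREE, CLUSTER)["pos"])
        reduced_set = set(call_discordant_sites(reduced, small_tree, CLUSTER)["pos"])
        assert reduced_set <= full_set


class TestOracleConsistency:
    def test_called_sites_require_two_mutations(self, small_ancestral):
        from ancpoly.distance import distance_matrix
        from ancpoly.genotypes import homozygous_variant_set
        from ancpoly.nj import neighbor_joining

        config, panel, matrix = small_ancestral
        sets = [homozygous_variant_set(matrix, s) for s in matrix.strains]
        tree = neighbor_joining(distance_matrix(sets))
        hom = matrix.is_hom
        pos_index = {(s.chrom, s.pos): j for j, s in enumerate(matrix.sites)}
        for plan in config.clusters[:2]:
            cluster = ClusterSpec(plan.name, plan.members)
            table = call_discordant_sites(matrix, tree, cluster)
            sample = table.sample(n=min(60, len(table)), random_state=0)
            for row in sample.itertuples():
                j = pos_index[(row.chrom, row.pos)]
                s = matrix.sites[j]
                char = {
                    matrix.strains[i]: s.alleles[matrix.a1[i, j]]
                    for i in range(len(matrix.strains))
                    if hom[i, j]
                }
                assert fitch_min_mutations(tree, char) >= 2

    def test_converse_for_pairs_at_biallelic_sites(self, matrix_factory):
        """For 2-member clusters: variable biallelic site called iff >= 2 changes."""
        rng = np.random.default_rng(72)
        kinds = [("hom", "A"), ("hom", "G")]
        specs = [
            site("c1", p + 1, {s: kinds[rng.integers(2)] for s in STRAINS})
            for p in range(200)
        ]
        m = matrix_factory(STRAINS, specs)
        called = set(call_discordant_sites(m, TREE, CLUSTER)["pos"])
        for c, p, r, a, calls in specs:
            if calls["Z1"][1] == calls["Z2"][1]:
                continue  # not variable within the cluster
            char = {s: calls[s][1] for s in STRAINS}
            expected = fitch_min_mutations(TREE, char) >= 2
            assert (p in called) == expected


class TestSummary:
    def test_counts_and_sets(self):
        t1 = pd.DataFrame({"cluster": "a", "chrom": ["c1"] * 3, "pos": [1, 2, 3]})
        t2 = pd.DataFrame({"cluster": "b", "chrom": ["c1"] * 2, "pos": [3, 9]})
        summary = discordant_site_summary({"a": t1, "b": t2}, min_clusters=2)
        assert summary.counts == {"a": 3, "b": 2}
        assert summary.union == {("c1", 1), ("c1", 2), ("c1", 3), ("c1", 9)}
        assert summary.min_cluster_sites == {("c1", 3)}

    def test_disjoint_intersection_empty(self):
        t1 = pd.DataFrame({"cluster": "a", "chrom": ["c1"], "pos": [1]})
        t2 = pd.DataFrame({"cluster": "b", "chrom": ["c1"], "pos": [2]})
        summary = discordant_site_summary({"a": t1, "b": t2}, min_clusters=2)
        assert summary.min_cluster_sites == set()

    def test_matches_bruteforce_set_algebra(self):
        rng = np.random.default_rng(73)
        tables = {}
        memberships = {}
        for name in "abc":
            positions = sorted(rng.choice(100, size=30, replace=False))
            tables[name] = pd.DataFrame(
                {"cluster": name, "chrom": "c1", "pos": positions}
            )
            memberships[name] = {("c1", int(p)) for p in positions}
        for k in (1, 2, 3):
            summary = discordant_site_summary(tables, min_clusters=k)
            brute = {
                s
                for s in set().union(*memberships.values())
                if sum(s in mem for mem in memberships.values()) >= k
            }
            assert summary.min_cluster_sites == brute


class TestGeneDensity:
    ANNS = [
        CdsAnnotation("gA", "gA", "c1", "+", ((0, 900),)),
        CdsAnnotation("gB", "gB", "c1", "+", ((5000, 6800),)),
        CdsAnnotation("gC", "gC", "c1", "+", ((9000, 9300),)),
    ]

    def test_density_ranking(self):
        rows = [("c1", p) for p in range(1, 11)] + [("c1", p) for p in range(5001, 5011)]
        table = pd.DataFrame(
            {"cluster": "x", "chrom": [c for c, _ in rows], "pos": [p for _, p in rows]}
        )
        frame = genes_with_discordant_sites(table, self.ANNS)
        assert list(frame["gene_id"]) == ["gA", "gB"]  # 10 per 0.9 kb beats 10 per 1.8 kb
        assert frame.iloc[0]["density_per_kb"] == pytest.approx(1000 * 10 / 900)
        assert "gC" not in set(frame["gene_id"])  # zero sites -> absent

    def test_site_in_two_genes_counted_for_each(self):
        anns = self.ANNS + [CdsAnnotation("gD", "gD", "c1", "+", ((0, 300),))]  # overlaps gA
        table = pd.DataFrame({"cluster": "x", "chrom": ["c1"], "pos": [100]})
        frame = genes_with_discordant_sites(table, anns)
        assert set(frame["gene_id"]) == {"gA", "gD"}


class TestBins:
    SIZES = {"c1": 3000, "c2": 2000}

    def test_empty_table(self):
        table = pd.DataFrame({"cluster": [], "chrom": [], "pos": []})
        bins = bin_sites(table, self.SIZES, bin_size=1000)
        assert len(bins) == 5
        assert (bins["count"] == 0).all()
        assert not bins["is_hotspot"].any()

    def test_single_loaded_bin_flagged(self):
        table = pd.DataFrame({"cluster": "x", "chrom": ["c1"] * 8, "pos": range(1, 9)})
        bins = bin_sites(table, self.SIZES, bin_size=100)
        assert hotspot_bins(bins) == {("c1", 0)}

    def test_threshold_recomputed_independently(self):
        rng = np.random.default_rng(74)
        positions = rng.integers(1, 3001, size=120)
        table = pd.DataFrame({"cluster": "x", "chrom": "c1", "pos": positions})
        bins = bin_sites(table, self.SIZES, bin_size=100, hotspot_sd_multiplier=2.0)
        counts = np.zeros(30)
        for p in set(positions):
            counts[(p - 1) // 100] += 1
        threshold = counts.mean() + 2.0 * counts.std()
        expected = {("c1", int(i) * 100) for i in np.nonzero((counts >= threshold) & (counts > 0))[0]}
        assert hotspot_bins(bins) == expected

    def test_site_beyond_chromosome_end(self):
        table = pd.DataFrame({"cluster": "x", "chrom": ["c1"], "pos": [3001]})
        with pytest.raises(ValueError, match="beyond"):
            bin_sites(table, self.SIZES, bin_size=1000)

    def test_counts_conserved(self):
        rng = np.random.default_rng(75)
        positions = sorted(set(rng.integers(1, 2001, size=50)))
        table = pd.DataFrame({"cluster": "x", "chrom": "c2", "pos": positions})
        bins = bin_sites(table, self.SIZES, bin_size=300)
        assert bins["count"].sum() == len(positions)


class TestJaccard:
    def frame(self, spots, sizes={"c1": 3000}):
        table = pd.DataFrame(
            {"cluster": "x", "chrom": [c for c, _ in spots], "pos": [s + 1 for _, s in spots]}
        )
        bins = bin_sites(table, sizes, bin_size=1000)
        bins["is_hotspot"] = bins["count"] > 0
        return bins

    def test_identical_sets(self):
        b = self.frame([("c1", 0), ("c1", 2000)])
        _, mean = cross_cluster_hotspot_overlap({"a": b, "b": b.copy()})
        assert mean == 1.0

    def test_disjoint_sets(self):
        a = self.frame([("c1", 0)])
        b = self.frame([("c1", 2000)])
        _, mean = cross_cluster_hotspot_overlap({"a": a, "b": b})
        assert mean == 0.0

    def test_grid_mismatch_rejected(self):
        a = self.frame([("c1", 0)])
        b = self.frame([("c1", 0)], sizes={"c1": 4000})
        with pytest.raises(ValueError, match="grid"):
            cross_cluster_hotspot_overlap({"a": a, "b": b})


class TestColocalization:
    def test_identical_distributions_rho_one(self, matrix_factory):
        sizes = {"c1": 5000}
        specs, rows = [], []
        for b, n in enumerate([1, 3, 5, 2, 4]):
            for k in range(n):
                pos = b * 1000 + 10 * (k + 1)
                specs.append(site("c1", pos, {"Z1": ("het", ("A", "G"))}))
                rows.append(("c1", pos))
        m = matrix_factory(STRAINS, specs)
        table = pd.DataFrame({"cluster": "x", "chrom": [c for c, _ in rows], "pos": [p for _, p in rows]})
        bins, rho, used = het_discordant_colocalization(m, table, sizes, bin_size=1000)
        assert used == "Z1"
        assert rho == pytest.approx(1.0)

    def test_too_few_bins_is_nan(self, matrix_factory):
        m = matrix_factory(STRAINS, [site("c1", 10, {"Z1": ("het", ("A", "G"))})])
        table = pd.DataFrame({"cluster": "x", "chrom": ["c1"], "pos": [10]})
        _, rho, _ = het_discordant_colocalization(m, table, {"c1": 3000}, bin_size=1000)
        assert np.isnan(rho)

    def test_pooled_mode(self, matrix_factory):
        specs = [
            site("c1", 10, {"Z1": ("het", ("A", "G")), "X1": ("het", ("A", "G"))}),
        ]
        m = matrix_factory(STRAINS, specs)
        table = pd.DataFrame({"cluster": "x", "chrom": ["c1"], "pos": [10]})
        bins, _, used = het_discordant_colocalization(
            m, table, {"c1": 1000}, bin_size=500, het_mode="pooled"
        )
        assert used == "pooled"
        assert bins.loc[bins["bin_start"] == 0, "het_count"].iloc[0] == 2


class TestProposeClusters:
    def test_star_tree_proposes_nothing(self):
        from ancpoly.distance import DistanceMatrix

        star = PhyloTree.from_newick("(A:1,B:1,C:1,D:1);")
        dm = DistanceMatrix(list("ABCD"), np.full((4, 4), 2.0) - 2.0 * np.eye(4))
        support = branch_support(star, [star])
        assert propose_clusters(star, support, dm) == []

    def test_supported_cherry_proposed(self):
        from ancpoly.distance import DistanceMatrix

        tree = PhyloTree.from_newick("((A:0.1,B:0.1):5,(C:3,D:3):5,E:3);")
        values = np.array(
            [
                [0, 0.2, 8, 8, 8],
                [0.2, 0, 8, 8, 8],
                [8, 8, 0, 6, 6],
                [8, 8, 6, 0, 6],
                [8, 8, 6, 6, 0],
            ]
        )
        dm = DistanceMatrix(list("ABCDE"), values)
        support = branch_support(tree, [tree] * 5)
        proposals = propose_clusters(tree, support, dm, max_within_distance=1.0)
        assert [p.members for p in proposals] == [("A", "B")]
        assert proposals[0].source == "auto"

    def test_recovers_simulated_clusters(self, small_ancestral):
        from ancpoly.distance import distance_matrix
        from ancpoly.genotypes import homozygous_variant_set
        from ancpoly.nj import neighbor_joining

        config, panel, matrix = small_ancestral
        sets = [homozygous_variant_set(matrix, s) for s in matrix.strains]
        dm = distance_matrix(sets)
        tree = neighbor_joining(dm)
        chrom_trees = [
            neighbor_joining(distance_matrix(sets, restrict_to=c.name))
            for c in config.chromosomes
        ]
        support = branch_support(tree, chrom_trees)
        # only 6 chromosome trees on the reduced panel: one discordant tree
        # already drops an edge to 83%, so use a coarser support cutoff
        proposals = propose_clusters(tree, support, dm, min_support=60.0)
        assert {p.members for p in proposals} == {c.members for c in config.clusters}
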