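"""The panel generator: pool, fixation, splits, gene flow, emission."""

import json

import numpy as np
import pytest
from scipy import stats

from ancpoly.genotypes import homozygous_variant_set, read_vcf
from ancpoly.inbreeding import balancing_multiplier, het_retention
from ancpoly.simulate import (
    ChromSpec,
    ClusterPlan,
    GeneFlowEvent,
    LocusSpec,
    ORIGIN_ANCESTRAL,
    ORIGIN_DENOVO,
    ORIGIN_GENEFLOW,
    SimConfig,
    default_config,
    emit_panel,
    simulate_ancestral_pool,
    simulate_panel,
    simulate_retention,
)
from ancpoly.tree import PhyloTree, fitch_min_mutations


def bare_config(**overrides):
    base = dict(
        chromosomes=(ChromSpec("chr01", 200_000),),
        genes=(),
        loci=(),
        clusters=(),
        singletons=("S01", "S02"),
        reference_strain="REF",
        total_generations=50,
        mutation_rate=1e-5,
        seed=1,
    )
    base.update(overrides)
    return SimConfig(**base)


class TestConfigValidation:
    def test_locus_outside_bounds(self):
        with pytest.raises(ValueError, match="bounds"):
            bare_config(loci=(LocusSpec("l", "chr01", 100, 300_000, 2, 1e-3),))

    def test_k_below_two(self):
        with pytest.raises(ValueError, match="haplotypes"):
            bare_config(loci=(LocusSpec("l", "chr01", 0, 1000, 1, 1e-3),))

    def test_split_after_total(self):
        with pytest.raises(ValueError, match="split"):
            bare_config(clusters=(ClusterPlan("C1", ("a", "b"), 51),))

    def test_overlapping_geneflow(self):
        events = (
            GeneFlowEvent("S01", "S02", "chr01", 0, 1000),
            GeneFlowEvent("S01", "S02", "chr01", 500, 1500),
        )
        with pytest.raises(ValueError, match="overlap"):
            bare_config(gene_flow_events=events)

    def test_donor_equals_recipient(self):
        with pytest.raises(ValueError):
            bare_config(gene_flow_events=(GeneFlowEvent("S01", "S01", "chr01", 0, 10),))


class TestAncestralPool:
    def test_no_loci_no_polymorphism(self):
        config = bare_config()
        pool = simulate_ancestral_pool(config, np.random.default_rng(1))
        assert pool == []

    def test_site_count_binomial(self):
        density, length = 5e-3, 100_000
        config = bare_config(
            loci=(LocusSpec("l", "chr01", 0, length, 2, density),)
        )
        pool = simulate_ancestral_pool(config, np.random.default_rng(2))
        n = len(pool[0].offsets)
        expected = density * length
        assert abs(n - expected) <= 3 * np.sqrt(expected * (1 - density))
        # carriers are polymorphic at every site
        assert pool[0].carriers.any(axis=1).all()
        assert not pool[0].carriers.all(axis=1).any()

    def test_determinism(self):
        config = bare_config(loci=(LocusSpec("l", "chr01", 0, 50_000, 3, 1e-3),))
        p1 = simulate_ancestral_pool(config, np.random.default_rng([9, 9]))
        p2 = simulate_ancestral_pool(config, np.random.default_rng([9, 9]))
        assert np.array_equal(p1[0].offsets, p2[0].offsets)
        assert np.array_equal(p1[0].carriers, p2[0].carriers)


class TestRetention:
    @pytest.mark.parametrize("t", [10, 37, 100])
    def test_neutral_retention_matches_recurrence(self, t):
        n = 200_000
        observed = simulate_retention(t, n, multiplier=1.0, seed=5)
        p = het_retention(t)
        se = np.sqrt(max(p * (1 - p), 1e-12) / n)
        assert abs(observed - p) <= 3 * se + 1e-9

    def test_balancing_multiplier_retention(self):
        t, target = 100, 0.25
        m = balancing_multiplier(target, t)
        observed = simulate_retention(t, 100_000, multiplier=m, seed=6)
        se = np.sqrt(target * (1 - target) / 100_000)
        assert abs(observed - target) <= 3 * se


class TestDeriveAndSplit:
    def test_long_inbreeding_fixes_everything(self):
        config = bare_config(
            loci=(LocusSpec("l", "chr01", 0, 100_000, 2, 2e-3),),
            total_generations=300,
            mutation_rate=0.0,
        )
        panel = simulate_panel(config)
        assert all(len(g.het) == 0 for g in panel.genomes.values())

    def test_split_at_total_gives_identical_substrains(self):
        config = bare_config(
            clusters=(ClusterPlan("C1", ("C1a", "C1b"), 50),),
            singletons=(),
            loci=(LocusSpec("l", "chr01", 0, 50_000, 2, 2e-3, 1e9),),
        )
        panel = simulate_panel(config)
        assert panel.genomes["C1a"] == panel.genomes["C1b"]

    def test_mu_zero_no_het_identical_substrains(self):
        config = bare_config(
            clusters=(ClusterPlan("C1", ("C1a", "C1b"), 20),),
            singletons=(),
            mutation_rate=0.0,
        )
        panel = simulate_panel(config)
        assert panel.genomes["C1a"] == panel.genomes["C1b"]

    def test_post_split_fixation_is_fair_coin(self):
        """Loci heterozygous at the split fix differently in half the pairs."""
        n_loci = 400
        loci = tuple(
            LocusSpec(
                f"l{i}", "chr01", i * 400, i * 400 + 200, 2, 0.05,
                # retained surely to the split (gen 20), lost by observation
                balancing_multiplier(1.0, 20),
            )
            for i in range(n_loci)
        )
        config = bare_config(
            chromosomes=(ChromSpec("chr01", 400 * n_loci),),
            loci=loci,
            clusters=(ClusterPlan("C1", ("C1a", "C1b"), 20),),
            singletons=(),
            total_generations=200,
            mutation_rate=0.0,
            seed=8,
        )
        panel = simulate_panel(config)
        differ = same = 0
        for name in (l.name for l in loci):
            sa = panel.fixation["C1a"][name]
            sb = panel.fixation["C1b"][name]
            if sa[0] == "fixed" and sb[0] == "fixed":
                if sa[1] == sb[1]:
                    same += 1
                else:
                    differ += 1
        total = differ + same
        assert total > 350  # nearly all fixed by generation 200
        assert abs(differ / total - 0.5) <= 3 * np.sqrt(0.25 / total)

    def test_independent_fixation_between_strains(self):
        """Fixation choices of two strains from one pool are independent."""
        n_loci = 200
        loci = tuple(
            LocusSpec(f"l{i}", "chr01", i * 300, i * 300 + 150, 2, 0.05)
            for i in range(n_loci)
        )
        config = bare_config(
            chromosomes=(ChromSpec("chr01", 300 * n_loci),),
            loci=loci,
            total_generations=200,
            mutation_rate=0.0,
            seed=9,
        )
        panel = simulate_panel(config)
        table = np.zeros((2, 2))
        for name in (l.name for l in loci):
            sa = panel.fixation["S01"][name]
            sb = panel.fixation["S02"][name]
            if sa[0] == "fixed" and sb[0] == "fixed":
                table[sa[1], sb[1]] += 1
        _, p, _, _ = stats.chi2_contingency(table)
        assert p > 0.01


class TestGeneFlow:
    def test_no_events_panel_unchanged(self):
        config = bare_config(seed=3)
        p1 = simulate_panel(config)
        p2 = simulate_panel(config)
        assert p1.genomes == p2.genomes
        assert p1.geneflow_changed == set()

    def test_whole_chromosome_transfer(self):
        config = bare_config(
            gene_flow_events=(GeneFlowEvent("S01", "S02", "chr01", 0, 200_000),),
            seed=4,
        )
        panel = simulate_panel(config)
        assert panel.genomes["S02"] == panel.genomes["S01"]

    def test_changed_sites_match_diff_oracle(self):
        config = bare_config(seed=5)
        before = simulate_panel(config)
        seg = (40_000, 120_000)
        config2 = bare_config(
            seed=5,
            gene_flow_events=(GeneFlowEvent("S01", "S02", "chr01", seg[0], seg[1]),),
        )
        after = simulate_panel(config2)
        lo, hi = seg[0], seg[1] - 1  # offsets are 0-based here (chr01 starts at 0)
        donor, recipient = before.genomes["S01"], before.genomes["S02"]
        expected = set()
        for off in set(donor.hom) | set(recipient.hom):
            if lo <= off <= hi and donor.hom.get(off) != recipient.hom.get(off):
                expected.add(off)
        for off in set(donor.het) | set(recipient.het):
            if lo <= off <= hi and donor.het.get(off) != recipient.het.get(off):
                expected.add(off)
        assert after.geneflow_changed == expected


class TestTruthLabels:
    def test_every_site_labeled_and_ancestral_inside_loci(self, small_ancestral):
        config, panel, matrix = small_ancestral
        truth = panel.truth()
        assert len(truth["origins"]) == len(matrix.sites)
        loci = [(l.chrom, l.start, l.end) for l in config.loci]
        for key, origin in truth["origins"].items():
            chrom, pos = key.split(":")
            pos = int(pos)
            inside = any(c == chrom and s < pos <= e for c, s, e in loci)
            if origin == ORIGIN_ANCESTRAL:
                assert inside
            elif origin == ORIGIN_DENOVO:
                assert not inside or True  # de novo may fall in a locus interval

    def test_null_scenario_characters_tree_concordant(self):
        """Without loci or gene flow every site fits the true genealogy."""
        config = default_config(
            "null", seed=17, n_chromosomes=4, chromosome_length=150_000,
            genes_per_chromosome=4,
        )
        panel = simulate_panel(config)
        matrix = panel.genotype_matrix()
        clusters = {c.name: c.members for c in config.clusters}
        inner = ",".join(
            "(" + ",".join(f"{m}:1" for m in members) + "):1"
            for members in clusters.values()
        )
        others = ",".join(
            f"{s}:1" for s in matrix.strains
            if not any(s in mem for mem in clusters.values())
        )
        genealogy = PhyloTree.from_newick(f"({inner},{others});")
        hom = matrix.is_hom
        for j in range(len(matrix.sites)):
            site = matrix.sites[j]
            character = {
                matrix.strains[i]: site.alleles[matrix.a1[i, j]]
                for i in range(len(matrix.strains))
                if hom[i, j]
            }
            assert fitch_min_mutations(genealogy, character) <= 1


class TestEmission:
    def test_round_trip_matrix_identity(self, small_ancestral, tmp_path):
        config, panel, matrix = small_ancestral
        paths = emit_panel(panel, tmp_path / "panel")
        back = read_vcf(paths["vcf"])
        assert back.strains == matrix.strains
        assert back.sites == matrix.sites
        assert np.array_equal(back.a1, matrix.a1)
        assert np.array_equal(back.a2, matrix.a2)

    def test_reference_strain_is_all_reference(self, small_ancestral):
        config, panel, matrix = small_ancestral
        assert homozygous_variant_set(matrix, "REF").mutations == frozenset()

    def test_byte_identical_reruns(self, tmp_path):
        config = default_config(
            "ancestral", seed=23, n_chromosomes=3, chromosome_length=120_000,
            genes_per_chromosome=3, n_ordinary_loci=2, locus_length=20_000,
            ordinary_blocks=2, mhc_block_length=6_000,
        )
        out1 = emit_panel(simulate_panel(config), tmp_path / "a")
        out2 = emit_panel(simulate_panel(config), tmp_path / "b")
        for key in out1:
            assert open(out1[key], "rb").read() == open(out2[key], "rb").read()

    def test_identical_strains_zero_records(self):
        config = bare_config(mutation_rate=0.0)
        matrix = simulate_panel(config).genotype_matrix()
        assert len(matrix.sites) == 0

    def test_truth_json_loads(self, small_ancestral, tmp_path):
        config, panel, _ = small_ancestral
        paths = emit_panel(panel, tmp_path / "panel")
        truth = json.load(open(paths["truth"]))
        assert truth["designated_gene"] == "geneMHC"
        assert set(truth["clusters"]) == {c.name for c in config.clusters}
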