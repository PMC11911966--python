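"""Diversity (richness, PD, FD) and Helmus-style variability (PSV) on
phylogenies, functional dendrograms and taxonomic-distinctness trees."""

import json
import shutil
import subprocess

import dendropy
import numpy as np
import pandas as pd
import pytest

from seasonstruct.biodiversity import (
    community_metrics,
    functional_dendrogram,
    functional_diversity,
    hill_taxa,
    phylo_diversity,
    standardize_traits,
    taxonomic_distinctness_tree,
    variability_psv,
)


def tree_from(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick")


@pytest.fixture
def three_taxon_tree():
    return tree_from("((A:1,B:1):1,C:2);")


class TestHillTaxa:
    def test_richness(self):
        assert hill_taxa([1, 2, 0, 5], q=0) == 4 - 1

    def test_q1_equal_abundances(self):
        assert hill_taxa([3, 3, 3, 3], q=1) == pytest.approx(4.0)

    def test_q2_shares(self):
        assert hill_taxa([0.8, 0.2], q=2) == pytest.approx(1 / 0.68, rel=1e-6)

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            hill_taxa([0, 0])


class TestPhyloDiversity:
    def test_pair_includes_stem(self, three_taxon_tree):
        assert phylo_diversity(three_taxon_tree, ["A", "B"]) == pytest.approx(3.0)

    def test_full_community_is_total_length(self, three_taxon_tree):
        # edges A:1 + B:1 + internal:1 + C:2
        assert phylo_diversity(three_taxon_tree, ["A", "B", "C"]) == pytest.approx(5.0)

    def test_single_species_root_to_tip(self, three_taxon_tree):
        assert phylo_diversity(three_taxon_tree, ["C"]) == pytest.approx(2.0)

    def test_monotone_in_community(self, three_taxon_tree):
        pd_ab = phylo_diversity(three_taxon_tree, ["A", "B"])
        pd_abc = phylo_diversity(three_taxon_tree, ["A", "B", "C"])
        assert pd_abc >= pd_ab

    def test_unknown_species_is_error(self, three_taxon_tree):
        with pytest.raises(ValueError, match="Z"):
            phylo_diversity(three_taxon_tree, ["A", "Z"])


class TestFunctionalDiversity:
    def test_two_species_ordered_pairs(self):
        traits = pd.DataFrame({"t1": [0.0, 2.0]}, index=["A", "B"])
        assert functional_diversity(traits, ["A", "B"], standardized=True) == 4.0

    def test_identical_traits_zero(self):
        traits = pd.DataFrame({"t1": [1.0, 1.0], "t2": [2.0, 2.0]}, index=["A", "B"])
        assert functional_diversity(traits, ["A", "B"], standardized=True) == 0.0

    def test_three_equidistant(self):
        # equilateral triangle with unit side
        traits = pd.DataFrame(
            {"t1": [0.0, 1.0, 0.5], "t2": [0.0, 0.0, np.sqrt(3) / 2]},
            index=["A", "B", "C"],
        )
        fd = functional_diversity(traits, ["A", "B", "C"], standardized=True)
        assert fd == pytest.approx(6.0, rel=1e-9)

    def test_matches_brute_force_double_sum(self, pool):
        traits = standardize_traits(pool.traits)
        community = pool.species[:5]
        fd = functional_diversity(pool.traits, community)
        sub = traits.loc[community].to_numpy()
        brute = sum(
            np.linalg.norm(sub[i] - sub[j])
            for i in range(len(sub))
            for j in range(len(sub))
        )
        assert fd == pytest.approx(brute, rel=1e-12)

    def test_singleton_warns_and_returns_zero(self, pool):
        with pytest.warns(UserWarning, match="singleton"):
            assert functional_diversity(pool.traits, [pool.species[0]]) == 0.0

    def test_dendrogram_convention(self, pool):
        fd = functional_diversity(
            pool.traits, pool.species[:4], convention="dendrogram"
        )
        assert fd > 0


class TestPSV:
    @pytest.mark.parametrize("n", range(2, 13))
    def test_star_tree_is_one(self, n):
        tips = ",".join(f"S{i}:1.0" for i in range(n))
        star = tree_from(f"({tips});")
        psv = variability_psv(star, [f"S{i}" for i in range(n)])
        assert psv == pytest.approx(1.0, abs=1e-12)

    def test_half_shared_depth(self):
        t = tree_from("((A:1,B:1):1,C:2);")
        assert variability_psv(t, ["A", "B"]) == pytest.approx(0.5)

    def test_three_taxon_worked_example(self, three_taxon_tree):
        # correlations {0.5, 0, 0}: psv = 1 - mean = 0.8333
        psv = variability_psv(three_taxon_tree, ["A", "B", "C"])
        assert psv == pytest.approx(5.0 / 6.0, abs=1e-9)

    def test_branch_length_scale_invariance(self, three_taxon_tree):
        scaled = tree_from("((A:7.3,B:7.3):7.3,C:14.6);")
        assert variability_psv(scaled, ["A", "B", "C"]) == pytest.approx(
            variability_psv(three_taxon_tree, ["A", "B", "C"]), abs=1e-12
        )

    def test_identical_pair_zero(self):
        traits = pd.DataFrame(
            {"t1": [0.0, 0.0, 3.0], "t2": [1.0, 1.0, -1.0]}, index=["A", "A2", "C"]
        )
        tree = functional_dendrogram(traits, standardized=True)
        assert variability_psv(tree, ["A", "A2"]) == pytest.approx(0.0, abs=1e-9)

    def test_monoculture_is_error(self, three_taxon_tree):
        with pytest.raises(ValueError):
            variability_psv(three_taxon_tree, ["A"])


class TestDendrograms:
    def test_two_species_cherry(self):
        traits = pd.DataFrame({"t1": [0.0, 3.0]}, index=["A", "B"])
        tree = functional_dendrogram(traits, standardized=True)
        for leaf in tree.leaf_node_iter():
            assert leaf.edge.length == pytest.approx(1.5)

    def test_closest_pair_joins_first(self):
        traits = pd.DataFrame({"t1": [0.0, 1.0, 5.0]}, index=["A", "B", "C"])
        tree = functional_dendrogram(traits, standardized=True)
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        assert pdm.distance(taxa["A"], taxa["B"]) < pdm.distance(taxa["A"], taxa["C"])

    def test_dendrogram_is_ultrametric(self, pool):
        tree = functional_dendrogram(pool.traits)
        depths = [leaf.distance_from_root() for leaf in tree.leaf_node_iter()]
        assert max(depths) - min(depths) < 1e-9

    def test_cophenetic_distances_match_linkage(self):
        traits = pd.DataFrame({"t1": [0.0, 1.0, 5.0]}, index=["A", "B", "C"])
        tree = functional_dendrogram(traits, standardized=True)
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        assert pdm.distance(taxa["A"], taxa["B"]) == pytest.approx(1.0)
        # UPGMA: C joins (A,B) at the average distance (4+5)/2
        assert pdm.distance(taxa["A"], taxa["C"]) == pytest.approx(4.5)


class TestTaxonomicDistinctness:
    @pytest.fixture
    def taxonomy(self):
        return pd.DataFrame(
            {
                "order": ["O1", "O1", "O1", "O1", "O2"],
                "family": ["F1", "F1", "F1", "F2", "F3"],
                "genus": ["G1", "G1", "G2", "G3", "G4"],
            },
            index=["A", "B", "C", "D", "E"],
        )

    def test_congeners_one_step(self, taxonomy):
        tree = taxonomic_distinctness_tree(taxonomy)
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        assert pdm.distance(taxa["A"], taxa["B"]) == pytest.approx(1.0)

    def test_confamilial_two_steps(self, taxonomy):
        tree = taxonomic_distinctness_tree(taxonomy)
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        assert pdm.distance(taxa["A"], taxa["C"]) == pytest.approx(2.0)

    def test_congeners_less_variable_than_confamilials(self, taxonomy):
        tree = taxonomic_distinctness_tree(taxonomy)
        psv_congener = variability_psv(tree, ["A", "B"])
        psv_confamilial = variability_psv(tree, ["A", "C"])
        assert psv_congener < psv_confamilial

    def test_duplicate_species_rejected(self, taxonomy):
        dup = pd.concat([taxonomy, taxonomy.iloc[[0]]])
        with pytest.raises(ValueError, match="duplicated"):
            taxonomic_distinctness_tree(dup)


class TestCommunityMetrics:
    def test_diversity_rises_with_richness_variability_does_not(self, pool):
        from seasonstruct.synthetic import generate_design

        design = generate_design(
            pool, n_blocks=3, plots_per_richness=1, mixtures_per_richness=40, seed=11
        )
        communities = {
            pid: list(design.proportions(pid).index)
            for pid in design.plots["plot_id"]
        }
        plots = design.plots[["plot_id", "richness"]].rename(
            columns={"richness": "richness_planted"}
        )
        table = community_metrics(
            communities, pool.tree, pool.traits, pool.taxonomy
        ).merge(plots, on="plot_id")
        by_r = table.groupby("richness_planted")[["pd", "fd"]].mean()
        assert by_r["pd"].is_monotonic_increasing
        assert by_r["fd"].is_monotonic_increasing
        # variability must not be a richness proxy: no systematic increase
        mix = table[table["richness_planted"] > 1]
        for col in ("var_phylo", "var_func", "var_taxo"):
            rho = mix["richness_planted"].corr(mix[col], method="spearman")
            assert rho < 0.3
        rho_phylo = mix["richness_planted"].corr(mix["var_phylo"], method="spearman")
        assert abs(rho_phylo) < 0.3

    def test_monocultures_have_nan_variability(self, pool, design):
        communities = {
            pid: list(design.proportions(pid).index)
            for pid in design.plots["plot_id"]
        }
        table = community_metrics(communities, pool.tree, pool.traits, pool.taxonomy)
        monos = table[table["richness"] == 1]
        assert monos["var_phylo"].isna().all()


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not on PATH")
class TestAgainstPicante:
    """Independent oracle: picante's psv/pd on a random tree and community."""

    def test_psv_and_pd_match_picante(self, tmp_path, pool):
        tree_path = tmp_path / "tree.nwk"
        pool.tree.write(path=str(tree_path), schema="newick", suppress_rooting=True)
        community = pool.species[2:8]
        comm_row = ",".join("1" if s in community else "0" for s in pool.species)
        script = tmp_path / "oracle.R"
        script.write_text(
            f"""
            suppressMessages(library(picante)); suppressMessages(library(ape))
            tree <- read.tree("{tree_path}")
            ones <- rep(1, length(tree$tip.label))
            comm <- rbind(c({comm_row}), ones)
            colnames(comm) <- c({", ".join(repr(s) for s in pool.species)})
            rownames(comm) <- c("plot", "all")
            res <- psv(comm, tree)
            pdres <- pd(comm, tree, include.root=TRUE)
            cat(sprintf('{{"psv": %.10f, "pd": %.10f}}', res$PSVs[1], pdres$PD[1]))
            """
        )
        out = subprocess.run(
            ["Rscript", "--vanilla", str(script)], capture_output=True, text=True,
            timeout=300,
        )
        assert out.returncode == 0, out.stderr
        oracle = json.loads(out.stdout.strip().splitlines()[-1])
        assert variability_psv(pool.tree, community) == pytest.approx(
            oracle["psv"], abs=1e-8
        )
        assert phylo_diversity(pool.tree, community) == pytest.approx(
            oracle["pd"], abs=1e-8
        )
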