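"""Synthetic experiment generator: species pool, design, inventories and
point clouds, with the determinism and phenology contracts."""

import numpy as np
import pandas as pd
import pytest

from seasonstruct import synthetic
from seasonstruct.metrics import fractional_cover
from seasonstruct.pointcloud import NOISE, PlotPolygon, clip_plot
from seasonstruct.synthetic import (
    cover_stability_score,
    generate_design,
    generate_inventories,
    generate_point_cloud,
    generate_species_pool,
    phenology_curve,
    temporal_complementarity,
)


class TestSpeciesPool:
    def test_default_pool_composition(self, pool):
        assert len(pool.species) == 12
        habits = pool.table["leaf_habit"].value_counts()
        assert habits["evergreen"] == 4 and habits["deciduous"] == 8
        assert np.isfinite(pool.traits.to_numpy()).all()

    def test_tree_is_ultrametric(self, pool):
        depths = [leaf.distance_from_root() for leaf in pool.tree.leaf_node_iter()]
        assert max(depths) - min(depths) < 1e-6

    def test_deep_split_separates_habits(self, pool):
        # the two children of the root must be the pure evergreen and pure
        # deciduous clades
        root_children = pool.tree.seed_node.child_nodes()
        assert len(root_children) == 2
        habit = pool.table["leaf_habit"]
        for child in root_children:
            tips = [l.taxon.label for l in child.leaf_iter()]
            assert habit.loc[tips].nunique() == 1

    def test_two_species_pool(self):
        small = generate_species_pool(2, 1, seed=7)
        depths = [leaf.distance_from_root() for leaf in small.tree.leaf_node_iter()]
        assert len(depths) == 2
        assert depths[0] == pytest.approx(depths[1], abs=1e-9)

    def test_deterministic_under_seed(self):
        a = generate_species_pool(12, 4, seed=3)
        b = generate_species_pool(12, 4, seed=3)
        pd.testing.assert_frame_equal(a.table, b.table)
        assert a.tree.as_string(schema="newick") == b.tree.as_string(schema="newick")

    def test_phenology_ordering(self, pool):
        dec = pool.table[pool.table["leaf_habit"] == "deciduous"]
        assert (dec["flush_doy"] < dec["senesce_doy"]).all()

    @pytest.mark.parametrize("n,e", [(1, 0), (5, 0), (5, 5), (3, 4)])
    def test_invalid_counts(self, n, e):
        with pytest.raises(ValueError):
            generate_species_pool(n, e, seed=0)


class TestDesign:
    def test_monocultures_for_all_species(self, pool, design):
        comp = design.composition
        richness = comp.groupby("plot_id").size()
        monos = comp[comp["plot_id"].map(richness) == 1]
        counts = monos.groupby("species_id").size()
        assert set(counts.index) == set(pool.species)
        assert (counts >= 2).all()

    def test_proportions_sum_to_one(self, design):
        sums = design.composition.groupby("plot_id")["proportion"].sum()
        np.testing.assert_allclose(sums, 1.0, rtol=1e-12)

    def test_deterministic_under_seed(self, pool):
        a = generate_design(pool, seed=9)
        b = generate_design(pool, seed=9)
        pd.testing.assert_frame_equal(a.plots, b.plots)
        pd.testing.assert_frame_equal(a.composition, b.composition)

    def test_blocks_present(self, design):
        assert design.plots["block"].nunique() >= 2

    def test_richness_above_pool_is_error(self):
        small = generate_species_pool(4, 2, seed=0)
        with pytest.raises(ValueError, match="richness"):
            generate_design(small, seed=0)


class TestInventories:
    def test_deterministic_under_seed(self, design, pool):
        a, _ = generate_inventories(design, pool, seed=4)
        b, _ = generate_inventories(design, pool, seed=4)
        pd.testing.assert_frame_equal(a, b)

    def test_dead_trees_zeroed(self, inventories):
        trees, _ = inventories
        dead = trees[~trees["alive_2022"].astype(bool)]
        assert len(dead) > 0
        assert (dead["height_2022"] == 0).all()
        assert (dead["d_rc_2022"] == 0).all()

    def test_dbh_present_iff_tall(self, inventories):
        trees, _ = inventories
        alive = trees[trees["alive_2021"].astype(bool)]
        tall = alive["height_2021"] > 1.3
        assert alive.loc[tall, "dbh_2021"].notna().all()
        assert alive.loc[~tall, "dbh_2021"].isna().all()

    def test_null_generator_centres_nbe_on_zero(self, pool):
        # no injected effect: mean NBE within 2 SE of 0 over >= 100 mixtures
        from seasonstruct.inventory import productivity_table

        design = generate_design(
            pool, plots_per_richness=2, mixtures_per_richness=30, seed=21
        )
        trees, _ = generate_inventories(
            design, pool, complementarity_strength=0.0, seed=21
        )
        prod = productivity_table(
            trees[trees["interior"]], design.design_table(), 2021, 2022
        )
        nbe = prod["nbe"].dropna()
        assert len(nbe) >= 100
        assert abs(nbe.mean()) < 2 * nbe.std(ddof=1) / np.sqrt(len(nbe))

    def test_injected_effect_recovered_downstream(self, pool):
        # positive multiplier -> positive rank correlation with realized NBE
        from seasonstruct.inventory import productivity_table

        design = generate_design(
            pool, plots_per_richness=2, mixtures_per_richness=30, seed=22
        )
        trees, truth = generate_inventories(
            design, pool, complementarity_strength=0.5, seed=22
        )
        prod = productivity_table(
            trees[trees["interior"]], design.design_table(), 2021, 2022
        ).set_index("plot_id")
        mix = prod.dropna(subset=["nbe"])
        mult = pd.Series(truth.plot_multiplier).reindex(mix.index)
        rho = mix["nbe"].corr(mult, method="spearman")
        assert rho > 0.3
        assert mix["nbe"].mean() > 0


class TestPhenology:
    def test_curve_bounds_and_anchors(self):
        doys = np.arange(60, 330)
        curve = phenology_curve(doys, 120.0, 280.0, 6.0)
        assert (curve >= 0).all() and (curve <= 1).all()
        assert phenology_curve(120 - 18, 120.0, 280.0, 6.0) == 0.0
        assert phenology_curve(90, 120.0, 280.0, 6.0) == 0.0
        assert phenology_curve(200, 120.0, 280.0, 6.0) == pytest.approx(1.0)

    def test_evergreen_constant(self):
        curve = phenology_curve(np.arange(60, 330), np.nan, np.nan, np.nan)
        assert (curve == 1.0).all()

    def test_temporal_complementarity_zero_for_monoculture(self, pool):
        sp = pool.species[0]
        assert temporal_complementarity({sp: 1.0}, pool)[sp] == pytest.approx(0.0)

    def test_cross_habit_benefit_positive(self, pool):
        ever = pool.table[pool.table["leaf_habit"] == "evergreen"].index[0]
        dec = pool.table[pool.table["leaf_habit"] == "deciduous"].index[0]
        b = temporal_complementarity({ever: 0.5, dec: 0.5}, pool)
        assert b[ever] > 0  # evergreen gains while deciduous is dormant

    def test_cover_stability_ranks_habits(self, pool):
        ever = pool.table[pool.table["leaf_habit"] == "evergreen"].index[0]
        dec = pool.table[pool.table["leaf_habit"] == "deciduous"].index[0]
        s_e = cover_stability_score({ever: 1.0}, pool)
        s_d = cover_stability_score({dec: 1.0}, pool)
        s_mix = cover_stability_score({ever: 0.5, dec: 0.5}, pool)
        assert s_e > s_mix > s_d


class TestPointClouds:
    @pytest.fixture(scope="class")
    def scene(self, pool, design, inventories):
        trees, _ = inventories
        return pool, design, trees

    def _mono_plot(self, pool, design, habit):
        comp = design.composition
        richness = comp.groupby("plot_id").size()
        monos = comp[comp["plot_id"].map(richness) == 1]
        habits = monos["species_id"].map(pool.table["leaf_habit"])
        return monos[habits == habit]["plot_id"].iloc[0]

    def test_deterministic_under_seed(self, scene):
        pool, design, trees = scene
        pid = design.plots["plot_id"].iloc[0]
        a = generate_point_cloud(design, pool, trees, pid, 188, density=30, seed=5)
        b = generate_point_cloud(design, pool, trees, pid, 188, density=30, seed=5)
        np.testing.assert_array_equal(a.x, b.x)
        np.testing.assert_array_equal(a.return_number, b.return_number)

    def test_return_numbering_no_gaps(self, scene):
        pool, design, trees = scene
        pid = design.plots["plot_id"].iloc[0]
        cloud = generate_point_cloud(design, pool, trees, pid, 215, density=50, seed=6)
        assert (cloud.return_number >= 1).all()
        assert (cloud.return_number <= cloud.number_of_returns).all()
        # no-gap numbering: for every pulse size k, each rank 1..k is
        # equally represented
        df = pd.DataFrame({"rn": cloud.return_number, "nor": cloud.number_of_returns})
        for k, sub in df.groupby("nor"):
            counts = sub.groupby("rn").size()
            assert set(counts.index) == set(range(1, k + 1))
            assert counts.nunique() == 1

    def test_deciduous_cover_rises_with_season(self, scene):
        pool, design, trees = scene
        pid = self._mono_plot(pool, design, "deciduous")
        fc = {}
        for doy in (100, 215):
            cloud = generate_point_cloud(
                design, pool, trees, pid, doy, density=60, seed=7
            )
            veg = (cloud.z > 0.25).sum()
            fc[doy] = veg / len(cloud)
        assert fc[100] < fc[215]

    def test_evergreen_cover_stable(self, scene):
        pool, design, trees = scene
        pid = self._mono_plot(pool, design, "evergreen")
        fracs = []
        for doy in (100, 188, 297):
            cloud = generate_point_cloud(
                design, pool, trees, pid, doy, density=60, seed=8
            )
            fracs.append(fractional_cover(cloud))
        assert max(fracs) - min(fracs) < 0.05

    def test_pulse_count_matches_density(self, scene):
        pool, design, trees = scene
        pid = design.plots["plot_id"].iloc[0]
        cloud = generate_point_cloud(design, pool, trees, pid, 215, density=200, seed=9)
        clipped = clip_plot(cloud, PlotPolygon.square("p", buffer_m=-0.5))
        pulses = int((clipped.return_number == 1).sum())
        assert pulses == pytest.approx(200 * 81, rel=0.05)

    def test_noise_points_above_canopy(self, scene):
        pool, design, trees = scene
        pid = design.plots["plot_id"].iloc[0]
        cloud = generate_point_cloud(
            design, pool, trees, pid, 215, density=50, noise_fraction=0.01, seed=10
        )
        noise = cloud.classification == NOISE
        assert noise.sum() > 0
        canopy_top = cloud.z[~noise].max()
        assert cloud.z[noise].min() >= canopy_top + 2.0 - 1e-9

    def test_ground_offset_variant(self, scene):
        pool, design, trees = scene
        pid = design.plots["plot_id"].iloc[0]
        shifted = generate_point_cloud(
            design, pool, trees, pid, 188, density=30, ground_offset=37.2, seed=11
        )
        flat = generate_point_cloud(
            design, pool, trees, pid, 188, density=30, ground_offset=0.0, seed=11
        )
        np.testing.assert_allclose(shifted.z, flat.z + 37.2, rtol=0, atol=1e-9)

    def test_unknown_plot_is_error(self, scene):
        pool, design, trees = scene
        with pytest.raises(ValueError, match="unknown plot"):
            generate_point_cloud(design, pool, trees, "nope", 188, seed=0)
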