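"""Stand summary statistics: shade tolerance index, basal area, cover."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sectorgap import (
    StandState,
    allocate_light,
    basal_area,
    canopy_cover,
    crown_symmetry,
    equilibrium_summary,
    shade_tolerance_index,
)
from sectorgap.metrics import annual_record, stand_crown_symmetry
from conftest import make_tree


class TestShadeToleranceIndex:
    def test_single_species_stand_equals_its_rank(self, species_pair):
        _, hemlock = species_pair
        trees = [make_tree(i, hemlock, 1, 1, 10 + i) for i in range(4)]
        assert shade_tolerance_index(trees) == pytest.approx(1.0)

    def test_equal_weights_average_the_ranks(self, species_pair):
        pine, hemlock = species_pair
        trees = [make_tree(0, pine, 1, 1, 15.0), make_tree(1, hemlock, 1, 1, 15.0)]
        assert shade_tolerance_index(trees) == pytest.approx(0.5)

    def test_basal_area_weighting_hand_computation(self, species_pair):
        # (400*1 + 100*0) / 500 = 0.8 with dbh^2-proportional weights
        pine, hemlock = species_pair
        trees = [make_tree(0, hemlock, 1, 1, 20.0), make_tree(1, pine, 1, 1, 10.0)]
        assert shade_tolerance_index(trees) == pytest.approx(0.8)

    def test_empty_stand_is_missing_not_zero(self):
        assert np.isnan(shade_tolerance_index([]))

    def test_invariant_under_weight_rescaling(self, species_pair):
        """Doubling every dbh doubles all weights' scale; basal-area sti is
        a weighted mean, so uniform rescaling leaves it unchanged."""
        pine, hemlock = species_pair
        trees = [make_tree(0, pine, 1, 1, 10.0), make_tree(1, hemlock, 1, 1, 25.0)]
        doubled = [make_tree(0, pine, 1, 1, 20.0), make_tree(1, hemlock, 1, 1, 50.0)]
        assert shade_tolerance_index(trees) == pytest.approx(
            shade_tolerance_index(doubled)
        )

    def test_bounded_by_extreme_ranks_present(self, species_pair):
        pine, hemlock = species_pair
        rng = np.random.default_rng(0)
        trees = [
            make_tree(i, (pine, hemlock)[i % 2], 1, 1, rng.uniform(3, 60))
            for i in range(20)
        ]
        for w in ("basal_area", "count", "biomass_proxy"):
            sti = shade_tolerance_index(trees, w)
            assert 0.0 <= sti <= 1.0

    def test_alternative_weightings_rank_correlated(self, species_pair):
        """Basal-area, count and biomass weightings order stands the same way."""
        pine, hemlock = species_pair
        rng = np.random.default_rng(7)
        stis = {"basal_area": [], "count": [], "biomass_proxy": []}
        for s in range(12):
            n = rng.integers(5, 25)
            trees = [
                make_tree(i, pine if rng.random() < 0.3 + 0.04 * s else hemlock,
                          1, 1, float(rng.uniform(3, 50)))
                for i in range(n)
            ]
            for w in stis:
                stis[w].append(shade_tolerance_index(trees, w))
        assert stats.spearmanr(stis["basal_area"], stis["count"]).statistic > 0
        assert stats.spearmanr(stis["basal_area"], stis["biomass_proxy"]).statistic > 0


class TestBasalArea:
    def test_empty_stand(self):
        assert basal_area([], 0.25) == 0.0

    def test_single_tree_closed_form(self, species_pair):
        # pi * (20/200)^2 / 0.25 ha = 0.12566 m2/ha
        t = make_tree(0, species_pair[0], 1, 1, 20.0)
        assert basal_area([t], 0.25) == pytest.approx(np.pi * 0.01 / 0.25)

    def test_strata_partition_exactly(self, species_pair):
        pine, _ = species_pair
        trees = [make_tree(i, pine, 1, 1, 10.0 + i) for i in range(6)]
        for i, t in enumerate(trees):
            t.canopy_flag = i % 2 == 0
        total = basal_area(trees, 0.1, "all")
        assert basal_area(trees, 0.1, "canopy") + basal_area(
            trees, 0.1, "understory"
        ) == pytest.approx(total)


class TestCanopyCover:
    def test_empty_stand_has_zero_cover(self, small_stand):
        claims, _ = allocate_light(small_stand)
        assert canopy_cover(claims) == 0.0

    def test_single_crown_covers_its_disc(self, small_stand, species_pair):
        small_stand.add_tree(make_tree(0, species_pair[0], 1.0, 1.0, 5.0))
        claims, _ = allocate_light(small_stand)
        t = small_stand.trees[0]
        R = t.species.rho_crown * t.dbh
        k = sum(
            np.hypot((i + 0.5) * 0.1 - 1.0, (j + 0.5) * 0.1 - 1.0) <= R
            for i in range(20) for j in range(20)
        )
        assert canopy_cover(claims) == pytest.approx(k / 400)

    def test_union_semantics_disjoint_adds_nested_does_not(self, species_pair):
        pine, _ = species_pair

        def cover_of(stems):
            stand = StandState(plot_width=4, plot_height=4, water_content=1,
                               rng=np.random.default_rng(0))
            for k, (x, y, d) in enumerate(stems):
                stand.add_tree(make_tree(k, pine, x, y, d))
            claims, _ = allocate_light(stand)
            return canopy_cover(claims)

        lone = cover_of([(1.0, 1.0, 6.0)])
        disjoint = cover_of([(1.0, 1.0, 6.0), (3.0, 3.0, 6.0)])
        nested = cover_of([(1.0, 1.0, 6.0), (1.05, 1.0, 3.0)])
        assert disjoint == pytest.approx(2 * lone, rel=0.01)
        assert nested == pytest.approx(lone, rel=0.01)

    def test_monotone_under_adding_trees(self, species_pair):
        pine, _ = species_pair
        stand = StandState(plot_width=4, plot_height=4, water_content=1,
                           rng=np.random.default_rng(0))
        covers = []
        for k in range(4):
            stand.add_tree(make_tree(k, pine, 0.8 + 0.8 * k, 2.0, 8.0))
            claims, _ = allocate_light(stand)
            covers.append(canopy_cover(claims))
        assert all(b >= a - 1e-12 for a, b in zip(covers, covers[1:]))


class TestCrownSymmetry:
    def test_equal_radii_are_perfectly_symmetric(self, species_pair):
        t = make_tree(0, species_pair[0], 1, 1, 10.0)
        assert crown_symmetry(t) == 1.0

    def test_min_over_max_example(self, species_pair):
        t = make_tree(0, species_pair[0], 1, 1, 10.0,
                      radii=[1, 1, 1, 1, 2, 2, 2, 2])
        assert crown_symmetry(t) == pytest.approx(0.5)

    def test_never_exceeds_one(self, species_pair):
        rng = np.random.default_rng(0)
        for _ in range(20):
            t = make_tree(0, species_pair[0], 1, 1, 10.0,
                          radii=rng.uniform(0.1, 3.0, 8))
            assert crown_symmetry(t) <= 1.0

    def test_all_zero_radii_rejected(self, species_pair):
        t = make_tree(0, species_pair[0], 1, 1, 10.0, radii=[0.0] * 8)
        with pytest.raises(ValueError):
            crown_symmetry(t)

    def test_stand_value_is_nan_without_canopy_trees(self, species_pair):
        t = make_tree(0, species_pair[0], 1, 1, 10.0)
        t.canopy_flag = False
        assert np.isnan(stand_crown_symmetry([t]))


class TestEquilibriumSummary:
    @staticmethod
    def _frame(values):
        return pd.DataFrame({"year": np.arange(1, len(values) + 1), "m": values})

    def test_constant_series(self):
        summ = equilibrium_summary(self._frame([3.5] * 100))
        assert summ.loc["m", "mean"] == pytest.approx(3.5)
        assert summ.loc["m", "sd"] == pytest.approx(0.0)

    def test_year_index_series_mean(self):
        # mean of 751..1500 = 1125.5
        summ = equilibrium_summary(self._frame(np.arange(1, 1501)), T=1500)
        assert summ.loc["m", "mean"] == pytest.approx(1125.5)

    def test_invariant_under_permutation_of_second_half(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=200)
        df = self._frame(vals)
        shuffled = df.copy()
        half = shuffled["year"] > 100
        shuffled.loc[half, "m"] = rng.permutation(vals[100:])
        a = equilibrium_summary(df, T=200)
        b = equilibrium_summary(shuffled, T=200)
        assert a.loc["m", "mean"] == pytest.approx(b.loc["m", "mean"])
        assert a.loc["m", "sd"] == pytest.approx(b.loc["m", "sd"])

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            equilibrium_summary(self._frame([1.0] * 10), T=100)


class TestAnnualRecord:
    def test_guild_split_is_exhaustive(self, species_pair):
        pine, hemlock = species_pair
        stand = StandState(plot_width=4, plot_height=4, water_content=1,
                           rng=np.random.default_rng(0))
        stand.add_tree(make_tree(0, pine, 1, 1, 15.0))
        stand.add_tree(make_tree(1, hemlock, 3, 3, 22.0))
        claims, _ = allocate_light(stand)
        rec = annual_record(stand, claims)
        assert rec["ba_shade_tolerant"] + rec["ba_shade_intolerant"] == pytest.approx(
            rec["basal_area_total"]
        )
        assert rec["n_trees_per_ha"] == pytest.approx(2 / stand.area_ha / 1)
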