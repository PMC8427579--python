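"""Recruitment counting, stand attributes, SCA and threshold harmonization."""

import logging
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ingrowth.inventory import (
    CensusPair,
    TreeRecord,
    basal_area_m2,
    build_observations,
    count_recruits,
    harmonize_threshold,
    plot_sca,
    recruit_ids,
    stand_attributes,
)


def tree(tid, species, dbh, census=1, plot="P1"):
    return TreeRecord(
        plot_id=plot, census_id=census, tree_id=tid, species=species, dbh=dbh
    )


PAIR = CensusPair(
    plot_id="P1", census_1=1, census_2=2, period_length=10.0, plot_area=0.05
)


class TestCountRecruits:
    def test_first_exceedance_counted(self):
        t1 = [tree("a", "sp1", 3.9)]
        t2 = [tree("a", "sp1", 4.2, census=2)]
        obs = count_recruits(PAIR, t1, t2, dbh_threshold=4.0)
        assert [(o.species, o.count) for o in obs] == [("sp1", 1)]

    def test_new_tree_above_threshold_counted(self):
        obs = count_recruits(PAIR, [], [tree("b", "sp1", 5.0, census=2)], 4.0)
        assert obs[0].count == 1

    def test_already_above_not_counted(self):
        t1 = [tree("a", "sp1", 4.5)]
        t2 = [tree("a", "sp1", 6.0, census=2)]
        obs = count_recruits(PAIR, t1, t2, 4.0, species_universe=["sp1"])
        assert obs[0].count == 0

    def test_dead_trees_never_recruit(self):
        t1 = [tree("a", "sp1", 3.0)]
        obs = count_recruits(PAIR, t1, [], 4.0, species_universe=["sp1"])
        assert obs[0].count == 0

    def test_zero_rows_for_universe(self):
        obs = count_recruits(
            PAIR, [], [tree("b", "sp1", 9.0, census=2)], 4.0,
            species_universe=["sp1", "sp2", "sp3"],
        )
        assert {o.species: o.count for o in obs} == {"sp1": 1, "sp2": 0, "sp3": 0}

    def test_six_tree_exhaustive_enumeration(self):
        # Brute-force oracle: walk every tree by hand.
        t1 = [
            tree("a", "sp1", 3.0),
            tree("b", "sp1", 4.5),
            tree("c", "sp2", 3.9),
            tree("d", "sp3", 2.0),
        ]
        t2 = [
            tree("a", "sp1", 4.1, census=2),   # crossed -> recruit
            tree("b", "sp1", 5.0, census=2),   # already above -> no
            tree("c", "sp2", 4.0, census=2),   # crossed -> recruit
            tree("d", "sp3", 3.5, census=2),   # still below -> no
            tree("e", "sp3", 7.0, census=2),   # new, above -> recruit
            tree("f", "sp2", 2.5, census=2),   # new, below -> no
        ]
        expected = {}
        dbh1 = {t.tree_id: t.dbh for t in t1}
        for t in t2:
            if t.dbh >= 4.0 and dbh1.get(t.tree_id, 0.0) < 4.0:
                expected[t.species] = expected.get(t.species, 0) + 1
        obs = count_recruits(PAIR, t1, t2, 4.0, species_universe=["sp1", "sp2", "sp3"])
        assert {o.species: o.count for o in obs} == {
            "sp1": 1, "sp2": 1, "sp3": 1,
        } == {**{"sp1": 0, "sp2": 0, "sp3": 0}, **expected}

    def test_bad_threshold(self):
        with pytest.raises(ValueError):
            count_recruits(PAIR, [], [], 0.0)

    def test_wrong_plot_rejected(self):
        with pytest.raises(ValueError, match="does not belong"):
            count_recruits(PAIR, [tree("a", "sp1", 5.0, plot="P9")], [], 4.0)

    @given(st.lists(st.floats(0.1, 30.0), min_size=1, max_size=15))
    @settings(max_examples=50, deadline=None)
    def test_recruits_respect_dbh_bound(self, dbhs):
        t2 = [tree(f"t{i}", "sp1", d, census=2) for i, d in enumerate(dbhs)]
        ids = recruit_ids([], t2, 7.0)
        for t in t2:
            if t.tree_id in ids:
                assert t.dbh >= 7.0


class TestStandAttributes:
    def test_single_tree(self):
        pair = CensusPair(
            plot_id="P1", census_1=1, census_2=2, period_length=10, plot_area=0.02
        )
        t2 = [tree("a", "sp1", 20.0, census=2)]
        ba, density = stand_attributes(t2, set(), pair, 4.0)
        assert ba == pytest.approx(math.pi * 0.1**2 / 0.02)
        assert density == pytest.approx(50.0)

    def test_all_recruits_gives_zero_with_warning(self, caplog):
        t2 = [tree("a", "sp1", 10.0, census=2)]
        with caplog.at_level(logging.WARNING):
            ba, density = stand_attributes(t2, {"a"}, PAIR, 4.0)
        assert (ba, density) == (0.0, 0.0)
        assert "recruits" in caplog.text

    def test_hand_summed_oracle(self):
        rng = np.random.default_rng(3)
        dbhs = rng.uniform(5, 40, 10)
        t2 = [tree(f"t{i}", "sp1", d, census=2) for i, d in enumerate(dbhs)]
        ba, density = stand_attributes(t2, set(), PAIR, 4.0)
        expected = sum(math.pi * (d / 200.0) ** 2 for d in dbhs) / PAIR.plot_area
        assert ba == pytest.approx(expected)
        assert density == pytest.approx(10 / PAIR.plot_area)

    def test_additive_over_subsets(self):
        rng = np.random.default_rng(4)
        dbhs = rng.uniform(5, 40, 12)
        trees = [tree(f"t{i}", "sp1", d, census=2) for i, d in enumerate(dbhs)]
        ba_all, _ = stand_attributes(trees, set(), PAIR, 4.0)
        ba_a, _ = stand_attributes(trees[:5], set(), PAIR, 4.0)
        ba_b, _ = stand_attributes(trees[5:], set(), PAIR, 4.0)
        assert ba_all == pytest.approx(ba_a + ba_b)

    def test_permutation_invariant(self):
        rng = np.random.default_rng(5)
        dbhs = rng.uniform(5, 40, 8)
        trees = [tree(f"t{i}", "sp1", d, census=2) for i, d in enumerate(dbhs)]
        shuffled = list(trees)
        rng.shuffle(shuffled)
        ba1, dens1 = stand_attributes(trees, set(), PAIR, 4.0)
        ba2, dens2 = stand_attributes(shuffled, set(), PAIR, 4.0)
        assert ba1 == pytest.approx(ba2)
        assert dens1 == dens2


class TestPlotSca:
    def test_weighted_mean(self):
        # Species A: SCA 5, BA 10; species B: SCA 1, BA 30 -> (50+30)/40 = 2.
        # DBH giving basal area 10 m^2 on a 1-ha basis: area = pi (d/200)^2.
        d_a = 200.0 * math.sqrt(10.0 / math.pi)
        d_b = 200.0 * math.sqrt(30.0 / math.pi)
        trees = [tree("a", "A", d_a), tree("b", "B", d_b)]
        assert plot_sca(trees, {"A": 5.0, "B": 1.0}) == pytest.approx(2.0)

    def test_monoculture(self):
        trees = [tree(f"t{i}", "A", 10.0 + i) for i in range(5)]
        assert plot_sca(trees, {"A": 4.0}) == pytest.approx(4.0)

    def test_three_species_oracle(self):
        rng = np.random.default_rng(6)
        sca = {"A": 1.5, "B": 3.0, "C": 4.5}
        trees = [
            tree(f"t{i}", rng.choice(["A", "B", "C"]), float(rng.uniform(5, 30)))
            for i in range(12)
        ]
        ba = {}
        for t in trees:
            ba[t.species] = ba.get(t.species, 0.0) + basal_area_m2(t.dbh)
        expected = sum(sca[s] * b for s, b in ba.items()) / sum(ba.values())
        assert plot_sca(trees, sca) == pytest.approx(expected)

    def test_within_species_range(self):
        rng = np.random.default_rng(7)
        sca = {"A": 1.0, "B": 5.0}
        trees = [
            tree(f"t{i}", rng.choice(["A", "B"]), float(rng.uniform(5, 30)))
            for i in range(10)
        ]
        value = plot_sca(trees, sca)
        assert 1.0 <= value <= 5.0

    def test_empty_stand_flagged_missing(self):
        assert plot_sca([], {"A": 3.0}) is None

    def test_missing_sca_raises(self):
        with pytest.raises(KeyError, match="B"):
            plot_sca([tree("a", "B", 10.0)], {"A": 3.0})


def toy_tables():
    """12-tree, 2-plot inventory exercising recruits, growth and new stems."""
    rows = []

    def add(plot, census, date, tid, sp, dbh):
        rows.append(
            {
                "plot_id": plot,
                "census_id": census,
                "census_date": date,
                "tree_id": tid,
                "species": sp,
                "dbh_cm": dbh,
            }
        )

    add("P1", 1, "2000-06-01", "a", "sp1", 5.0)
    add("P1", 1, "2000-06-01", "b", "sp1", 6.5)
    add("P1", 1, "2000-06-01", "c", "sp2", 3.0)
    add("P1", 2, "2010-06-01", "a", "sp1", 8.0)
    add("P1", 2, "2010-06-01", "b", "sp1", 13.0)   # crosses 12 at census 2
    add("P1", 2, "2010-06-01", "c", "sp2", 7.5)    # crosses 7
    add("P1", 2, "2010-06-01", "d", "sp2", 14.0)   # new, above both
    add("P2", 1, "2001-06-01", "e", "sp1", 20.0)
    add("P2", 1, "2001-06-01", "f", "sp2", 6.9)
    add("P2", 2, "2013-06-01", "e", "sp1", 24.0)
    add("P2", 2, "2013-06-01", "f", "sp2", 9.0)    # crosses 7
    add("P2", 2, "2013-06-01", "g", "sp1", 7.2)    # new, above 7 only
    trees = pd.DataFrame(rows)
    plots = pd.DataFrame(
        [{"plot_id": "P1", "plot_area_ha": 0.05}, {"plot_id": "P2", "plot_area_ha": 0.1}]
    )
    sca = {"sp1": 2.0, "sp2": 4.0}
    return trees, plots, sca


class TestBuildObservations:
    def test_counts_and_offsets(self):
        trees, plots, sca = toy_tables()
        obs, stand = build_observations(trees, plots, sca, dbh_threshold=7.0)
        obs = obs.set_index(["plot_id", "species"])
        assert obs.loc[("P1", "sp1"), "count"] == 2  # a (5 -> 8) and b (6.5 -> 13)
        assert obs.loc[("P1", "sp2"), "count"] == 2  # c, d
        assert obs.loc[("P2", "sp1"), "count"] == 1  # g
        assert obs.loc[("P2", "sp2"), "count"] == 1  # f
        assert obs.loc[("P1", "sp1"), "period_length_yr"] == pytest.approx(
            10.0, abs=0.02
        )
        assert len(stand) == 2

    def test_stand_excludes_recruits(self):
        trees, plots, sca = toy_tables()
        _, stand = build_observations(trees, plots, sca, dbh_threshold=7.0)
        p1 = stand.set_index("plot_id").loc["P1"]
        # Only tree "a" (8 cm, crossed nothing: 5 -> 8, threshold 7... ) wait:
        # a crosses 7 between censuses (5 -> 8) so it is also a recruit.
        # Non-recruit standing trees at P1: none above 7 that were above 7 before.
        assert p1["basal_area"] == pytest.approx(0.0)

    def test_missing_plot_raises(self):
        trees, plots, sca = toy_tables()
        with pytest.raises(KeyError):
            build_observations(trees, plots.iloc[:1], sca, 7.0)


class TestHarmonizeThreshold:
    def test_identity_at_native_threshold(self):
        trees, plots, sca = toy_tables()
        obs_native, stand_native = build_observations(trees, plots, sca, 7.0)
        obs_h, stand_h = harmonize_threshold(trees, plots, sca, 7.0, 7.0)
        pd.testing.assert_frame_equal(obs_native, obs_h)
        pd.testing.assert_frame_equal(stand_native, stand_h)

    def test_tree_crossing_12_becomes_recruit(self):
        trees, plots, sca = toy_tables()
        obs, _ = harmonize_threshold(trees, plots, sca, 7.0, 12.0)
        obs = obs.set_index(["plot_id", "species"])
        assert obs.loc[("P1", "sp1"), "count"] == 1  # b: 6.5 -> 13
        assert obs.loc[("P1", "sp2"), "count"] == 1  # d: new at 14
        assert obs.loc[("P2", "sp1"), "count"] == 0

    def test_equals_full_rerun_at_12(self):
        trees, plots, sca = toy_tables()
        obs_h, stand_h = harmonize_threshold(trees, plots, sca, 7.0, 12.0)
        obs_r, stand_r = build_observations(trees, plots, sca, 12.0)
        pd.testing.assert_frame_equal(obs_h, obs_r)
        pd.testing.assert_frame_equal(stand_h, stand_r)

    def test_explanatory_only_keeps_native_response(self):
        trees, plots, sca = toy_tables()
        obs_native, _ = build_observations(trees, plots, sca, 7.0)
        _, stand_12 = build_observations(trees, plots, sca, 12.0)
        obs_h, stand_h = harmonize_threshold(
            trees, plots, sca, 7.0, 12.0, mode="explanatory"
        )
        pd.testing.assert_frame_equal(obs_h, obs_native)
        pd.testing.assert_frame_equal(stand_h, stand_12)

    def test_lower_threshold_rejected(self):
        trees, plots, sca = toy_tables()
        with pytest.raises(ValueError, match="below"):
            harmonize_threshold(trees, plots, sca, 7.0, 4.0)
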