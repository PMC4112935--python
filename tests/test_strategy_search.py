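import itertools

import pytest

from cass import fixtures as fx
from cass.fg_database import build_database
from cass.strategy_search import (
    Strategy,
    baseline_performance,
    beam_search,
    signature,
    strategy_performance,
    theoretical_ceiling,
    transform_count,
)


@pytest.fixture(scope="module")
def testbed(library):
    mols, truth = fx.planted_database("strategy_testbed")
    db = build_database(mols, library)
    yield db, truth
    db.close()


@pytest.fixture(scope="module")
def isomer_db(library):
    mols, _ = fx.planted_database("isomer_pairs")
    db = build_database(mols, library)
    yield db
    db.close()


class TestTransforms:
    def test_pseudostoichiometric_saturates_at_three(self):
        outs = [transform_count(c, "pseudostoichiometric")
                for c in (0, 1, 2, 3, 5)]
        assert outs == [0, 1, 2, "3+", "3+"]

    def test_non_stoichiometric_is_presence(self):
        assert [transform_count(c, "non_stoichiometric")
                for c in (0, 1, 4)] == [0, 1, 1]

    def test_stoichiometric_identity(self):
        assert transform_count(7, "stoichiometric") == 7


class TestSignature:
    def test_acetone_ketone_signature(self, testbed):
        db, _ = testbed
        rec = db.get_entry("T000")  # acetone
        sig = signature(rec, Strategy(groups=frozenset({"ketone"})), db)
        assert sig == ("C3H6O1", 1)

    def test_empty_strategy_is_bare_formula(self, testbed):
        db, _ = testbed
        rec = db.get_entry("T000")
        assert signature(rec, Strategy(groups=frozenset()), db) == (
            "C3H6O1",
        )

    def test_unknown_group_rejected(self, testbed):
        db, _ = testbed
        rec = db.get_entry("T000")
        with pytest.raises(KeyError):
            signature(rec, Strategy(groups=frozenset({"nitro"})), db)


class TestPerformance:
    def test_isomer_pair_separated_by_one_group(self, library):
        db = build_database(
            [fx.build_compound("acetone", mol_id="A"),
             fx.build_compound("propanal", mol_id="B")],
            library,
        )
        assert strategy_performance(
            db, Strategy(groups=frozenset({"ketone"}))
        ) == pytest.approx(100.0)
        assert strategy_performance(
            db, Strategy(groups=frozenset())
        ) == 0.0

    def test_baseline_counts_unique_formulae(self, library):
        db = build_database(
            [fx.build_compound(n, mol_id=f"B{i}") for i, n in
             enumerate(["ethanol", "dimethyl ether", "methane"])],
            library,
        )
        assert baseline_performance(db) == pytest.approx(100 / 3)

    def test_all_unique_database_scores_100(self, library):
        db = build_database(
            [fx.build_compound(n, mol_id=f"U{i}") for i, n in
             enumerate(["methane", "glycerol"])],
            library,
        )
        assert baseline_performance(db) == 100.0
        assert strategy_performance(
            db, Strategy(groups=frozenset({"alcohol"}))
        ) == 100.0

    def test_ceiling_excludes_stereo_pairs(self, library):
        mols, _ = fx.planted_database("stereo_pairs")
        db = build_database(mols, library)
        assert theoretical_ceiling(db) == pytest.approx(80.0)

    def test_ceiling_without_stereo_pairs_is_100(self, testbed):
        db, _ = testbed
        assert theoretical_ceiling(db) == 100.0

    def test_monotone_in_strategy_size(self, testbed):
        db, truth = testbed
        names = sorted(g.name for g in db.load_library())
        for scope in ("distinct", "distinct+subgraph+overlapping"):
            for size in (0, 1):
                for base in itertools.combinations(names[:6], size):
                    perf = strategy_performance(
                        db, Strategy(groups=frozenset(base), scope=scope)
                    )
                    for extra in names[:6]:
                        if extra in base:
                            continue
                        bigger = strategy_performance(
                            db, Strategy(groups=frozenset(base) | {extra},
                                         scope=scope)
                        )
                        assert bigger >= perf

    def test_mode_ordering_is_monotone_coarsening(self, library):
        # Alcohol counts 2 vs 1 (glycol pair) need at least pseudo
        # resolution; counts 4 vs 3 (tetraol pair) need full stoichiometry.
        db = build_database(
            [fx.build_compound(n, mol_id=f"M{i}") for i, n in enumerate(
                ["ethylene glycol", "methoxymethanol",
                 "pentane-1,2,3,4-tetraol", "2-methoxybutane-1,3,4-triol",
                 "glycerol"]
            )],
            library,
        )
        s = {m: strategy_performance(
            db, Strategy(groups=frozenset({"alcohol"}), mode=m))
            for m in ("stoichiometric", "pseudostoichiometric",
                      "non_stoichiometric")}
        assert s["stoichiometric"] > s["pseudostoichiometric"]
        assert s["pseudostoichiometric"] > s["non_stoichiometric"]

    def test_mode_ordering_holds_on_every_fixture_db(self, library, testbed,
                                                     isomer_db):
        db_t, _ = testbed
        for db in (db_t, isomer_db):
            for groups in ({"ketone"}, {"alcohol", "carboxylic acid"},
                           {"methyl"}):
                perfs = [
                    strategy_performance(
                        db, Strategy(groups=frozenset(groups), mode=m)
                    )
                    for m in ("stoichiometric", "pseudostoichiometric",
                              "non_stoichiometric")
                ]
                assert perfs[0] >= perfs[1] >= perfs[2]


class TestBeamSearch:
    def test_recovers_planted_separating_groups(self, testbed):
        db, truth = testbed
        scope = truth["scope"]
        planted = Strategy(groups=frozenset(truth["separating_groups"]),
                           scope=scope)
        assert strategy_performance(db, planted) == 100.0
        ranked = beam_search(db, scope=scope, iterations=4)
        assert ranked[0].performance == 100.0

    def test_matches_exhaustive_optimum_on_small_library(self, testbed):
        db, truth = testbed
        scope = truth["scope"]
        names = sorted(g.name for g in db.load_library())[:6]
        best_exhaustive = max(
            strategy_performance(
                db, Strategy(groups=frozenset(combo), scope=scope)
            )
            for size in (1, 2, 3)
            for combo in itertools.combinations(names, size)
        )
        ranked = beam_search(db, scope=scope, iterations=3)
        assert ranked[0].performance >= best_exhaustive - 1e-9

    def test_huge_cutoff_stops_after_singletons(self, testbed):
        db, _ = testbed
        ranked = beam_search(db, cutoff=100.0, iterations=5)
        assert all(len(s.groups) == 1 for s in ranked)

    def test_no_isomers_ties_break_lexicographically(self, library):
        db = build_database(
            [fx.build_compound(n, mol_id=f"L{i}") for i, n in
             enumerate(["methane", "glycerol"])],
            library,
        )
        ranked = beam_search(db, iterations=2)
        assert all(s.performance == 100.0 for s in ranked)
        singles = [s for s in ranked if len(s.groups) == 1]
        names = [s.sorted_groups()[0] for s in singles]
        assert names == sorted(names)

    def test_empty_library_rejected(self, library):
        db = build_database([], library)
        db.conn.execute("DELETE FROM library")
        with pytest.raises(Exception):
            beam_search(db)

    def test_deterministic_ranking(self, testbed):
        db, _ = testbed
        r1 = beam_search(db, iterations=3)
        r2 = beam_search(db, iterations=3)
        assert [(s.sorted_groups(), s.performance) for s in r1] == [
            (s.sorted_groups(), s.performance) for s in r2
        ]
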