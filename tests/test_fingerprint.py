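"""Compatibility rule, partition enumeration, MNI ranges, age structure."""

import itertools
import random

import networkx as nx
import pytest

from zygochron import (
    AssemblageConfig,
    ColumnNoise,
    CompatibilityParams,
    IndividualConfig,
    SizeCapError,
    age_structure,
    brute_force_partitions,
    build_graph,
    compatible,
    enumerate_admissible_partitions,
    mni_bracket,
    mni_range,
    simulate_assemblage,
)
from conftest import make_vertebra

PARAMS = CompatibilityParams()  # age margin 1, 2 sigma, cv 12.7


def vert(rid, count, centrum=None, lot="L"):
    return make_vertebra(record_id=rid, lot_id=lot, left=count, right=count,
                         centrum=centrum)


class TestCompatible:
    def test_adjacent_counts_within_size_envelope(self):
        # the published nine- vs eight-line pair: within 2 sigma
        assert compatible(vert("a", 9, 10.67), vert("b", 8, 10.41), PARAMS)

    def test_count_gap_beyond_margin(self):
        assert not compatible(vert("a", 10, 10.63), vert("b", 12, 8.61), PARAMS)

    def test_missing_length_passes_by_default(self):
        assert compatible(vert("a", 11, None), vert("b", 10, 9.66), PARAMS)

    def test_missing_length_policy_fail(self):
        strict = CompatibilityParams(missing_length_policy="fail")
        assert not compatible(vert("a", 11, None), vert("b", 10, 9.66), strict)

    def test_self_compatible(self):
        v = vert("a", 9, 10.67)
        assert compatible(v, v, PARAMS)

    def test_size_envelope_rejects_large_gap(self):
        # equal counts but relative gap 66.7% of the mean > 2 * 12.7%
        assert not compatible(vert("a", 5, 10.0), vert("b", 5, 20.0), PARAMS)

    def test_symmetric(self):
        u, v = vert("a", 9, 10.67), vert("b", 10, 9.66)
        assert compatible(u, v, PARAMS) == compatible(v, u, PARAMS)

    def test_spacing_threshold_enforced_when_set(self):
        u = make_vertebra(record_id="u", left=2, right=2, centrum=5.0,
                          left_positions=(0.5, 0.95))
        v = make_vertebra(record_id="v", left=2, right=2, centrum=5.0,
                          left_positions=(0.8, 0.99))
        loose = CompatibilityParams(spacing_threshold=0.5)
        tight = CompatibilityParams(spacing_threshold=0.05)
        assert compatible(u, v, loose)
        assert not compatible(u, v, tight)


class TestBuildGraph:
    def test_fossil_lot_2770_structure(self, lot_2770):
        g = build_graph(lot_2770, PARAMS)
        assert g.number_of_nodes() == 8
        assert g.number_of_edges() == 9
        comps = sorted(len(c) for c in nx.connected_components(g))
        assert comps == [1, 1, 6]  # 6- and 13-line vertebrae isolated

    def test_fossil_lot_3752_edgeless(self, lot_3752):
        g = build_graph(lot_3752, PARAMS)
        assert g.number_of_nodes() == 4 and g.number_of_edges() == 0

    def test_single_record(self):
        g = build_graph([vert("a", 5, 4.0)], PARAMS)
        assert g.number_of_nodes() == 1 and g.number_of_edges() == 0

    def test_per_lot_blocks_cross_lot_edges(self):
        u, v = vert("a", 5, 4.0, lot="L1"), vert("b", 5, 4.0, lot="L2")
        assert build_graph([u, v], PARAMS).number_of_edges() == 0
        assert build_graph([u, v], PARAMS, per_lot=False).number_of_edges() == 1

    def test_unscorable_records_excluded(self, caplog):
        from zygochron import Condition
        bad = make_vertebra(record_id="bad", lot_id="L",
                            left_condition=Condition.DAMAGED,
                            right_condition=Condition.MISSING)
        g = build_graph([vert("a", 5, 4.0), bad], PARAMS)
        assert "bad" not in g.nodes


def graph_from_edges(n, edges):
    g = nx.Graph()
    g.add_nodes_from(f"n{i}" for i in range(n))
    g.add_edges_from((f"n{a}", f"n{b}") for a, b in edges)
    return g


class TestPartitionEnumeration:
    def test_triangle_single_partition(self):
        g = graph_from_edges(3, [(0, 1), (1, 2), (0, 2)])
        parts = enumerate_admissible_partitions(g)
        assert parts == [(frozenset({"n0", "n1", "n2"}),)]

    def test_path_two_partitions_no_singleton_reading(self):
        # u-v-w with u,w incompatible: v joins one neighbour or the other,
        # never stays alone (brute-force over all 5 set partitions agrees)
        g = graph_from_edges(3, [(0, 1), (1, 2)])
        parts = enumerate_admissible_partitions(g)
        expected = sorted([
            (frozenset({"n0", "n1"}), frozenset({"n2"})),
            (frozenset({"n0"}), frozenset({"n1", "n2"})),
        ], key=lambda p: [sorted(b) for b in p])
        assert sorted(parts, key=lambda p: [sorted(b) for b in p]) == expected
        assert parts == brute_force_partitions(g)

    def test_edgeless_graph_all_singletons(self):
        g = graph_from_edges(4, [])
        parts = enumerate_admissible_partitions(g)
        assert len(parts) == 1 and len(parts[0]) == 4
        assert brute_force_partitions(g) == parts

    def test_complete_graph_single_block(self):
        g = nx.complete_graph(4)
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in range(4)})
        parts = enumerate_admissible_partitions(g)
        assert len(parts) == 1 and len(parts[0]) == 1
        assert brute_force_partitions(g) == parts

    def test_size_cap_enforced(self):
        g = graph_from_edges(17, [])
        with pytest.raises(SizeCapError):
            enumerate_admissible_partitions(g)
        with pytest.raises(SizeCapError):
            brute_force_partitions(graph_from_edges(13, []))

    @pytest.mark.parametrize("trial", range(40))
    def test_matches_brute_force_on_random_graphs(self, trial):
        rnd = random.Random(1000 + trial)
        n = rnd.randint(2, 8)
        edges = [(a, b) for a, b in itertools.combinations(range(n), 2)
                 if rnd.random() < rnd.choice((0.2, 0.5, 0.8))]
        g = graph_from_edges(n, edges)
        assert enumerate_admissible_partitions(g) == brute_force_partitions(g)

    @pytest.mark.parametrize("trial", range(10))
    def test_min_blocks_is_minimum_clique_cover(self, trial):
        # oracle: the smallest clique partition overall (not only the
        # coarsest ones) — merging mergeable blocks never increases count,
        # so the minima must coincide
        from sympy.utilities.iterables import multiset_partitions
        rnd = random.Random(2000 + trial)
        n = rnd.randint(2, 7)
        edges = [(a, b) for a, b in itertools.combinations(range(n), 2)
                 if rnd.random() < 0.5]
        g = graph_from_edges(n, edges)
        adj = {u: set(g.neighbors(u)) for u in g.nodes}

        def is_clique(b):
            return all(y in adj[x] for x, y in itertools.combinations(b, 2))

        cover_min = min(len(p) for p in multiset_partitions(sorted(g.nodes))
                        if all(is_clique(b) for b in p))
        ours = min(len(p) for p in enumerate_admissible_partitions(g))
        assert ours == cover_min


class TestMNIRange:
    def test_fossil_lot_2770_range(self, boavus_records):
        result = mni_range(boavus_records, PARAMS)
        lot = result.lot("YPM VP 2770")
        assert (lot.min_individuals, lot.max_individuals) == (4, 5)

    def test_fossil_lot_3752_range(self, boavus_records):
        result = mni_range(boavus_records, PARAMS)
        lot = result.lot("YPM VP 3752")
        assert (lot.min_individuals, lot.max_individuals) == (4, 4)

    def test_fossil_totals(self, boavus_records):
        result = mni_range(boavus_records, PARAMS)
        assert (result.total_min, result.total_max) == (8, 9)

    def test_empty_input(self):
        result = mni_range([], PARAMS)
        assert (result.total_min, result.total_max) == (0, 0)

    def test_cv_bracket_identical_on_fossils(self, boavus_records):
        results = mni_bracket(boavus_records)
        assert set(results) == {12.7, 19.5}
        by_cv = {cv: [(l.lot_id, l.min_individuals, l.max_individuals,
                       l.partitions) for l in r.lots]
                 for cv, r in results.items()}
        assert by_cv[12.7] == by_cv[19.5]

    def test_invariant_under_reordering_and_lot_renaming(self, boavus_records):
        import dataclasses
        base = mni_range(boavus_records, PARAMS)
        shuffled = list(boavus_records)[::-1]
        assert mni_range(shuffled, PARAMS) == base
        renamed = [dataclasses.replace(v, lot_id="Z-" + v.lot_id)
                   for v in boavus_records]
        res = mni_range(renamed, PARAMS)
        assert (res.total_min, res.total_max) == (base.total_min, base.total_max)
        assert [(l.min_individuals, l.max_individuals) for l in res.lots] == \
            [(l.min_individuals, l.max_individuals) for l in base.lots]

    def test_ambiguity_reproduces_published_assignments(self, boavus_records):
        # the "2, 3"-style individual-count entries for both fossil lots
        result = mni_range(boavus_records, PARAMS)
        assert result.lot("YPM VP 2770").ambiguity == {
            "59189": (1,), "59190-1": (2,), "59190-2": (2,),
            "59191-1": (2, 3), "59191-2": (2, 3), "59191-3": (3,),
            "59192": (3, 4), "59193": (5,),
        }
        assert result.lot("YPM VP 3752").ambiguity == {
            "59194": (1,), "59195": (2,), "59196": (3,), "59197": (4,),
        }

    def test_blocks_respect_margin_and_envelope_post_hoc(self, boavus_records):
        result = mni_range(boavus_records, PARAMS)
        for lot in result.lots:
            counts = {r: m[0] for r, m in lot.nodes.items()}
            for p in lot.partitions:
                for block in p:
                    spread = max(counts[r] for r in block) - \
                        min(counts[r] for r in block)
                    assert spread <= PARAMS.age_margin * max(len(block) - 1, 0)

    def test_pooling_merges_lots(self):
        u, v = vert("a", 5, 4.0, lot="L1"), vert("b", 5, 4.0, lot="L2")
        per_lot = mni_range([u, v], PARAMS, per_lot=True)
        pooled = mni_range([u, v], PARAMS, per_lot=False)
        assert (per_lot.total_min, per_lot.total_max) == (2, 2)
        assert (pooled.total_min, pooled.total_max) == (1, 1)


class TestAgeStructure:
    def test_fossil_age_distribution(self, boavus_records):
        ast = age_structure(boavus_records)
        assert (ast.min_age, ast.median_age, ast.max_age) == (6, 10.0, 19)
        assert sum(ast.tallies.values()) == 12

    def test_single_record(self):
        ast = age_structure([vert("a", 7)])
        assert (ast.min_age, ast.median_age, ast.max_age) == (7, 7.0, 7)

    def test_even_n_midpoint_median(self):
        ast = age_structure([vert("a", 2), vert("b", 4)])
        assert ast.median_age == 3.0


class TestSyntheticRecovery:
    def test_separated_ages_give_exact_count(self):
        # two individuals with a count gap of 2 can never share a block
        quiet = ColumnNoise(0.0, 0.0, 0.0, cl_cv_percent=2.0)
        cfg = AssemblageConfig(
            individuals=(IndividualConfig(6, 6, 8.0, noise=quiet),
                         IndividualConfig(13, 6, 10.5, noise=quiet)),
            fragmentation_prob=0.0, seed=5)
        recs, truth = simulate_assemblage(cfg)
        result = mni_range(recs, PARAMS)
        assert (result.total_min, result.total_max) == (2, 2)

    def test_recovered_partition_matches_truth(self):
        quiet = ColumnNoise(0.0, 0.0, 0.0, cl_cv_percent=2.0)
        cfg = AssemblageConfig(
            individuals=(IndividualConfig(3, 5, 4.0, noise=quiet),
                         IndividualConfig(8, 5, 7.0, noise=quiet),
                         IndividualConfig(15, 5, 11.0, noise=quiet)),
            fragmentation_prob=0.0, seed=17)
        recs, truth = simulate_assemblage(cfg)
        result = mni_range(recs, PARAMS, max_exact=20)
        (partition,) = result.lots[0].partitions
        truth_blocks = {
            frozenset(grp["record_id"])
            for _, grp in truth.groupby("individual_label")
        }
        assert set(partition) == truth_blocks
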