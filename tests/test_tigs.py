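import random

import pytest

from simpletigs import (Graph, GraphError, Walk, brute_force_simple_omnitigs,
                        core_decomposition, generate_random_graph,
                        is_core_of_maximal, is_subwalk, maximal_simple_omnitigs,
                        maximal_unitigs, univocal_extension)

from conftest import by_name, node_names


def path_graph(n):
    g = Graph()
    for _ in range(n):
        g.add_node()
    for i in range(n - 1):
        g.add_arc(i, i + 1)
    return g


def cycle_graph(n):
    g = Graph()
    for _ in range(n):
        g.add_node()
    for i in range(n):
        g.add_arc(i, (i + 1) % n)
    return g


def walk_by_names(g, names):
    ids = by_name(g)
    nodes = tuple(ids[x] for x in names)
    arcs = []
    for u, v in zip(nodes, nodes[1:]):
        arcs.append(next(a for a in g.out_arcs(u) if g.arc(a).head == v))
    return Walk(nodes, tuple(arcs))


class TestMaximalUnitigs:
    def test_branch_free_path_is_one_unitig(self):
        tigs = maximal_unitigs(path_graph(3))
        assert len(tigs) == 1
        assert tigs[0].walk.nodes == (0, 1, 2)
        assert not tigs[0].circular

    def test_repeat_fixture_partition(self, g1):
        got = {node_names(g1, u.walk) for u in maximal_unitigs(g1)}
        assert got == {("a1", "a2", "r1"), ("r1", "r2"),
                       ("r2", "b1", "b2", "r1"), ("r2", "c1", "c2")}

    def test_isolated_cycle_reported_once_circular(self):
        tigs = maximal_unitigs(cycle_graph(3))
        assert len(tigs) == 1
        assert tigs[0].circular
        assert tigs[0].walk.nodes == (0, 1, 2, 0)

    def test_every_arc_in_exactly_one_unitig(self):
        for seed in range(30):
            g = generate_random_graph(8, 15, seed)
            counts = {}
            for u in maximal_unitigs(g):
                for a in u.walk.arcs:
                    counts[a] = counts.get(a, 0) + 1
            assert counts == {a: 1 for a in range(g.m)}

    def test_deterministic_order(self):
        g = generate_random_graph(10, 20, 3)
        first = [u.walk for u in maximal_unitigs(g)]
        second = [u.walk for u in maximal_unitigs(g)]
        assert first == second


class TestCoreDecomposition:
    def test_unitig_core_is_whole_walk(self, g1):
        w = walk_by_names(g1, ("a1", "a2", "r1"))
        cd = core_decomposition(w, g1)
        assert cd.has_core and cd.core == w
        assert (cd.j, cd.i) == (1, 3)

    def test_split_after_join_means_no_core(self, g1):
        w = walk_by_names(g1, ("a1", "a2", "r1", "r2", "b1"))
        cd = core_decomposition(w, g1)
        assert (cd.i, cd.j) == (3, 4)
        assert not cd.has_core

    def test_repeat_spanning_walk_core(self, g1):
        w = walk_by_names(g1, ("r1", "r2", "b1", "b2", "r1", "r2"))
        cd = core_decomposition(w, g1)
        assert (cd.j, cd.i) == (2, 5)
        assert node_names(g1, cd.core) == ("r2", "b1", "b2", "r1")

    def test_single_node_walk_has_no_core(self, g1):
        cd = core_decomposition(Walk((0,)), g1)
        assert not cd.has_core


class TestCoreOfMaximal:
    def test_source_anchored_unitig_is_core(self, g1):
        assert is_core_of_maximal(walk_by_names(g1, ("a1", "a2", "r1")), g1)

    def test_join_to_split_bridge_is_not_core(self, g1):
        # r1 has one outgoing arc but two incoming: condition (b) fails
        assert not is_core_of_maximal(walk_by_names(g1, ("r1", "r2")), g1)

    def test_unitig_into_split_is_not_core(self, g2):
        # a2 has one incoming arc and two outgoing: condition (c) fails
        assert not is_core_of_maximal(walk_by_names(g2, ("a1", "a2")), g2)

    def test_non_unitig_input_rejected(self, g1):
        with pytest.raises(GraphError):
            is_core_of_maximal(
                walk_by_names(g1, ("a1", "a2", "r1", "r2", "b1")), g1)


class TestUnivocalExtension:
    def test_forward_extension_stops_at_split(self, g1):
        got = univocal_extension(walk_by_names(g1, ("a1", "a2", "r1")), g1)
        assert node_names(g1, got) == ("a1", "a2", "r1", "r2")

    def test_repeat_core_extends_through_both_copies(self, g1):
        got = univocal_extension(walk_by_names(g1, ("r2", "b1", "b2", "r1")), g1)
        assert node_names(g1, got) == ("r1", "r2", "b1", "b2", "r1", "r2")

    def test_cycle_guard_terminates(self):
        g = Graph()
        a, b = g.add_node(), g.add_node()
        g.add_arc(a, b)
        g.add_arc(b, a)
        got = univocal_extension(Walk((a,)), g)
        # each cycle arc traversed once forward and once backward
        assert got.nodes == (a, b, a, b, a)

    def test_contains_input_as_subwalk(self):
        for seed in range(20):
            g = generate_random_graph(8, 14, seed)
            for u in maximal_unitigs(g):
                if u.circular:
                    continue
                assert is_subwalk(u.walk, univocal_extension(u.walk, g))


class TestMaximalSimpleOmnitigs:
    def test_repeat_fixture(self, g1):
        got = {node_names(g1, t.walk) for t in maximal_simple_omnitigs(g1)}
        assert got == {("a1", "a2", "r1", "r2"),
                       ("r1", "r2", "b1", "b2", "r1", "r2"),
                       ("r1", "r2", "c1", "c2")}

    def test_bubble_fixture(self, g2):
        got = {node_names(g2, t.walk) for t in maximal_simple_omnitigs(g2)}
        assert got == {("a1", "a2", "b1", "b2", "c1", "c2"),
                       ("a1", "a2", "d1", "d2", "c1", "c2")}

    def test_branch_free_path(self):
        tigs = maximal_simple_omnitigs(path_graph(3))
        assert [t.walk.nodes for t in tigs] == [(0, 1, 2)]

    def test_recorded_core_is_generating_unitig(self, g1):
        units = {(u.walk.nodes, u.walk.arcs) for u in maximal_unitigs(g1)}
        for t in maximal_simple_omnitigs(g1):
            assert (t.core.nodes, t.core.arcs) in units
            assert is_subwalk(t.core, t.walk)

    def test_isolated_cycle_passes_through(self):
        tigs = maximal_simple_omnitigs(cycle_graph(4))
        assert len(tigs) == 1 and tigs[0].circular
        assert tigs[0].walk.nodes == (0, 1, 2, 3, 0)


class TestBruteForceOracle:
    def test_fixtures_match_algorithm(self, g1, g2):
        for g in (g1, g2):
            algo = {(t.walk.nodes, t.walk.arcs)
                    for t in maximal_simple_omnitigs(g)}
            oracle = {(w.nodes, w.arcs)
                      for w in brute_force_simple_omnitigs(g, max_len=8)}
            assert algo == oracle

    def test_edgeless_graph(self):
        g = Graph()
        g.add_node()
        assert brute_force_simple_omnitigs(g) == []

    def test_budget_exceeded_raises(self):
        g = generate_random_graph(8, 20, 0)
        with pytest.raises(GraphError, match="budget"):
            brute_force_simple_omnitigs(g, max_steps=3)


class TestOracleEquivalence:
    """The linear-time algorithm agrees with exhaustive enumeration."""

    @pytest.mark.parametrize("batch", range(4))
    def test_random_graphs(self, batch):
        for i in range(50):
            seed = batch * 50 + i
            r = random.Random(10_000 + seed)
            n, m = r.randint(1, 12), r.randint(0, 25)
            g = generate_random_graph(n, m, seed)
            algo = {(t.walk.nodes, t.walk.arcs)
                    for t in maximal_simple_omnitigs(g)}
            oracle = {(w.nodes, w.arcs)
                      for w in brute_force_simple_omnitigs(g)}
            assert algo == oracle, f"seed={seed} n={n} m={m}"


class TestStructuralInvariants:
    @pytest.mark.parametrize("seed", range(40))
    def test_subsumption_and_core_validity(self, seed):
        r = random.Random(20_000 + seed)
        g = generate_random_graph(r.randint(2, 10), r.randint(1, 20), seed)
        units = maximal_unitigs(g)
        tigs = maximal_simple_omnitigs(g)
        walks = [t.walk for t in tigs]
        # every maximal non-circular unitig is inside some simple omnitig
        for u in units:
            if u.circular:
                continue
            assert any(is_subwalk(u.walk, w) for w in walks), (seed, u)
        # each omnitig's recorded core passes the core-of-maximal test
        for t in tigs:
            if not t.circular:
                assert is_core_of_maximal(t.core, g)

    @pytest.mark.parametrize("seed", range(20))
    def test_length_dominance_on_genome_graphs(self, seed):
        """Summed omnitig length dominates summed unitig length on de
        Bruijn graphs of genomes (the model the guarantee is stated for;
        on arbitrary cyclic graphs the cycle guard can truncate
        extensions below the unitig total)."""
        from simpletigs import Genome, build_dbg, k_spectrum
        r = random.Random(30_000 + seed)
        seqs = ["".join(r.choice("ACGT") for _ in range(r.randint(80, 250)))
                for _ in range(r.randint(1, 3))]
        g = build_dbg(k_spectrum(Genome.from_sequences(seqs), r.choice([5, 7])))
        total_u = sum(len(u.walk) for u in maximal_unitigs(g))
        total_t = sum(len(t.walk) for t in maximal_simple_omnitigs(g))
        assert total_t >= total_u
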