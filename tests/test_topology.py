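"""Directed-clique counting, kernel/core selection and breakdowns."""

import math

import numpy as np
import pandas as pd
import pytest

from striatopy import network as N
from striatopy import topology as T


def _tournament(n):
    return T.DirectedGraph(range(n), {i: "dSPN" for i in range(n)},
                           [(i, j, 1) for i in range(n)
                            for j in range(n) if i < j])


def _random_digraph(n, p, seed):
    rng = np.random.default_rng(seed)
    edges = [(a, b, 1) for a in range(n) for b in range(n)
             if a != b and rng.random() < p]
    return T.DirectedGraph(range(n), None, edges)


class TestDirectedGraph:
    def test_synapse_multiplicity_collapses_to_weight(self):
        df = pd.DataFrame({
            "pre_id": [0] * 4, "post_id": [1] * 4,
            "pre_type": "dSPN", "post_type": "iSPN",
            "x": 0.0, "y": 0.0, "z": 0.0, "post_dist": 0.0,
            "post_node": 2, "cond": 0.5})
        g = T.digraph_from_synapses(N.SynapseTable(df))
        assert g.n_edges == 1
        assert g.weight(0, 1) == 4

    def test_reciprocal_pairs_give_two_edges(self):
        df = pd.DataFrame({
            "pre_id": [0, 1], "post_id": [1, 0],
            "pre_type": "dSPN", "post_type": "dSPN",
            "x": 0.0, "y": 0.0, "z": 0.0, "post_dist": 0.0,
            "post_node": 2, "cond": 0.5})
        g = T.digraph_from_synapses(N.SynapseTable(df))
        assert g.n_edges == 2

    def test_feedforward_triple_forms_a_2_clique(self):
        # FS drives both SPNs, dSPN drives iSPN: one directed 2-clique
        df = pd.DataFrame({
            "pre_id": [0, 0, 1], "post_id": [1, 2, 2],
            "pre_type": ["FS", "FS", "dSPN"],
            "post_type": ["dSPN", "iSPN", "iSPN"],
            "x": 0.0, "y": 0.0, "z": 0.0, "post_dist": 0.0,
            "post_node": 2, "cond": 0.5})
        g = T.digraph_from_synapses(N.SynapseTable(df))
        cc = T.count_directed_cliques(g)
        assert cc.counts[2] == 1

    def test_empty_table_keeps_vertices(self):
        inst = [N.NeuronInstance(i, "dSPN", None, np.zeros(3), np.eye(3))
                for i in range(4)]
        empty = N.SynapseTable(pd.DataFrame(columns=[
            "pre_id", "post_id", "pre_type", "post_type", "x", "y", "z",
            "post_dist", "post_node", "cond"]))
        g = T.digraph_from_synapses(empty, inst, include_isolated=True)
        assert g.n_vertices == 4 and g.n_edges == 0

    def test_self_loops_rejected(self):
        with pytest.raises(ValueError, match="self-loop"):
            T.DirectedGraph([0, 1], None, [(0, 0, 1)])


class TestCliqueCounting:
    @pytest.mark.parametrize("n", [3, 4, 5, 6, 7, 8])
    def test_transitive_tournament_counts_are_binomial(self, n):
        cc = T.count_directed_cliques(_tournament(n))
        expected = [math.comb(n, k + 1) for k in range(n)]
        assert cc.counts.tolist() == expected
        assert cc.top_dimension == n - 1

    def test_three_cycle_has_no_2_clique(self):
        g = T.DirectedGraph(range(3), None, [(0, 1, 1), (1, 2, 1), (2, 0, 1)])
        cc = T.count_directed_cliques(g)
        assert cc.counts.tolist() == [3, 3]

    def test_reciprocal_pair_counts(self):
        g = T.DirectedGraph([0, 1], None, [(0, 1, 1), (1, 0, 1)])
        cc, cliques = T.brute_force_cliques(g)
        assert cc.counts.tolist() == [2, 2]

    def test_complete_symmetric_triangle_orderings(self):
        g = T.DirectedGraph(range(3), None,
                            [(a, b, 1) for a in range(3)
                             for b in range(3) if a != b])
        assert T.count_directed_cliques(g).counts[2] == 6
        # the set convention counts the vertex set once
        assert T.count_directed_cliques(g, convention="set").counts[2] == 1

    @pytest.mark.parametrize("seed", range(50))
    def test_flag_counter_equals_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 11))
        g = _random_digraph(n, 0.3, seed + 1000)
        fast = T.count_directed_cliques(g)
        slow, _ = T.brute_force_cliques(g)
        assert fast.counts.tolist() == slow.counts.tolist()

    def test_enumeration_agrees_with_counts(self):
        g = _random_digraph(8, 0.4, 5)
        cc = T.count_directed_cliques(g)
        by_dim = {}
        for tup in T.enumerate_directed_cliques(g):
            by_dim[len(tup) - 1] = by_dim.get(len(tup) - 1, 0) + 1
        assert [by_dim.get(d, 0) for d in range(len(cc.counts))] == \
            cc.counts.tolist()

    def test_kernel_filter_counts_cliques_meeting_kernel(self):
        g = _tournament(6)
        cc = T.count_directed_cliques(g, kernel=[0])
        assert cc.counts.tolist() == [math.comb(5, k) for k in range(6)]
        # brute-force cross-check of the kernel filter
        _, cliques = T.brute_force_cliques(g)
        expect = [0] * 6
        for tup in cliques:
            if 0 in tup:
                expect[len(tup) - 1] += 1
        assert cc.counts.tolist() == expect

    def test_vertex_removal_never_increases_counts(self):
        g = _random_digraph(10, 0.4, 9)
        full = T.count_directed_cliques(g).counts
        sub = g.subgraph([v for v in range(10) if v != 3])
        reduced = T.count_directed_cliques(sub).counts
        for d in range(len(reduced)):
            assert reduced[d] <= full[d]
        assert len(reduced) <= len(full)


class TestCompositionAndWeights:
    def test_classification_rules(self):
        assert T.classify_composition(["iSPN"] * 3) == "all_iSPN"
        assert T.classify_composition(["dSPN", "dSPN"]) == "all_dSPN"
        # interneuron takes precedence over mixed SPN membership
        assert T.classify_composition(["FS", "dSPN", "iSPN"]) == \
            "contains_interneuron"
        assert T.classify_composition(["dSPN", "iSPN"]) == "mixed_dSPN_iSPN"
        with pytest.raises(ValueError):
            T.classify_composition(["dSPN", "martian"])

    def test_class_counts_partition_total(self):
        g = _random_digraph(9, 0.45, 3)
        types = {v: ["dSPN", "iSPN", "FS"][v % 3] for v in range(9)}
        cliques = list(T.enumerate_directed_cliques(g, min_dim=1))
        table = T.classify_cliques(cliques, types)
        cc = T.count_directed_cliques(g)
        for dim in range(1, len(cc.counts)):
            got = table[table.dimension == dim]["count"].sum()
            assert got == cc.counts[dim]

    def test_synapse_histogram_totals(self):
        g = T.DirectedGraph(range(3), None,
                            [(0, 1, 4), (0, 2, 1), (1, 2, 2)])
        cliques = [t for t in T.enumerate_directed_cliques(g)
                   if len(t) == 3]
        hist = T.synapse_count_histogram(cliques, g, 2)
        assert hist.to_dict() == {7: 1}

    def test_unit_weights_concentrate_at_edge_count(self):
        n = 6
        g = _tournament(n)
        dim = 3
        cliques = [t for t in T.enumerate_directed_cliques(g)
                   if len(t) == dim + 1]
        hist = T.synapse_count_histogram(cliques, g, dim)
        assert hist.to_dict() == {dim * (dim + 1) // 2: math.comb(n, dim + 1)}

    def test_histogram_mass_equals_clique_count(self):
        g = _random_digraph(8, 0.5, 11)
        cc = T.count_directed_cliques(g)
        for dim in (2, 3):
            if dim >= len(cc.counts):
                continue
            cliques = [t for t in T.enumerate_directed_cliques(g)
                       if len(t) == dim + 1]
            hist = T.synapse_count_histogram(cliques, g, dim)
            assert hist.sum() == cc.counts[dim]


class TestKernelCore:
    def test_kernel_core_on_desk_network(self, desk_network):
        d = desk_network
        g = T.digraph_from_synapses(d.pd0, d.instances)
        sel = T.select_kernel_core(d.instances, g, k=8)
        assert len(sel.kernel) == 8
        types = {i.id: i.cell_type for i in d.instances}
        kernel_types = sorted(types[v] for v in sel.kernel)
        assert kernel_types == ["dSPN"] * 4 + ["iSPN"] * 4
        # every non-kernel core vertex is adjacent to the kernel
        edge_pairs = {(u, v) for u, v, _ in g.edge_list()}
        for v in sel.core - sel.kernel:
            assert any((v, k) in edge_pairs or (k, v) in edge_pairs
                       for k in sel.kernel)

    def test_isolated_kernel_vertex_contributes_only_itself(self):
        inst = [N.NeuronInstance(i, "dSPN" if i < 2 else "iSPN", None,
                                 np.array([float(i), 0, 0]), np.eye(3))
                for i in range(4)]
        df = pd.DataFrame({
            "pre_id": [0], "post_id": [2], "pre_type": "dSPN",
            "post_type": "iSPN", "x": 0.0, "y": 0.0, "z": 0.0,
            "post_dist": 0.0, "post_node": 2, "cond": 0.5})
        g = T.digraph_from_synapses(N.SynapseTable(df), inst,
                                    include_isolated=True)
        sel = T.select_kernel_core(inst, g, k=2,
                                   composition={"dSPN": 1, "iSPN": 1})
        assert sel.core >= sel.kernel

    def test_insufficient_candidates_raise(self):
        inst = [N.NeuronInstance(0, "dSPN", None, np.zeros(3), np.eye(3))]
        g = T.DirectedGraph([0], {0: "dSPN"}, [])
        with pytest.raises(ValueError, match="not enough"):
            T.select_kernel_core(inst, g, k=8)


class TestErosionCurves:
    def test_endpoints_and_monotone_totals(self, desk_network):
        d = desk_network
        curves = T.erosion_curves(d.pd0, d.instances, [0.0, 0.5, 1.0],
                                  reps=2, seed=3, max_dim=8)
        tot = curves.groupby("fraction").mean_count.sum()
        assert tot.loc[0.0] >= tot.loc[0.5] >= tot.loc[1.0]
        # full erosion leaves vertices only
        top = curves[curves.fraction == 1.0]
        assert set(top[top.mean_count > 0].dimension) == {0}
        # zero fraction reproduces the baseline
        g = T.digraph_from_synapses(d.pd0, d.instances,
                                    include_isolated=True)
        base = T.count_directed_cliques(g, max_dim=8)
        zero = curves[curves.fraction == 0.0].set_index("dimension")
        for dim, c in enumerate(base.counts):
            assert zero.mean_count.get(dim, 0.0) == pytest.approx(c)


from hypothesis import given, settings, strategies as st


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(3, 8), st.floats(0.1, 0.6), st.integers(0, 10_000))
def test_property_flag_counter_matches_brute_force(n, p, seed):
    """The flag-complex counter is exact on arbitrary small digraphs."""
    g = _random_digraph(n, p, seed)
    fast = T.count_directed_cliques(g)
    slow, _ = T.brute_force_cliques(g)
    assert fast.counts.tolist() == slow.counts.tolist()


@settings(max_examples=15, deadline=None, derandomize=True)
@given(st.integers(3, 9), st.floats(0.2, 0.7), st.integers(0, 10_000))
def test_property_kernel_filter_counts_subset_of_total(n, p, seed):
    """Kernel-filtered counts never exceed the unfiltered counts."""
    g = _random_digraph(n, p, seed)
    full = T.count_directed_cliques(g).counts
    part = T.count_directed_cliques(g, kernel=[0, 1]).counts
    for d in range(len(part)):
        assert part[d] <= full[d]
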