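"""Hierarchy and structure analyses: greedy DAG, levels, transitive
reduction, motifs, hub removal, subsampling and correlation enrichment."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from cpnet.netbuild import CausalNetwork, Subnetwork
from cpnet.synthio import ProteinPanel
from cpnet.topology import (
    assign_levels,
    classify_reintroduced_edges,
    count_motifs,
    greedy_dag,
    hub_robustness,
    regulator_subgraph,
    subsample_robustness,
    target_correlation_enrichment,
    transitive_reduction,
)


def random_digraph(rng, n_nodes, p_edge):
    nodes = [f"n{i}" for i in range(n_nodes)]
    return [
        (u, v) for u in nodes for v in nodes if u != v and rng.random() < p_edge
    ]


def random_dag(rng, n_nodes, p_edge):
    nodes = [f"n{i}" for i in range(n_nodes)]
    return [
        (nodes[i], nodes[j])
        for i in range(n_nodes)
        for j in range(i + 1, n_nodes)
        if rng.random() < p_edge
    ]


class TestRegulatorSubgraph:
    def test_empty_network(self):
        net = CausalNetwork(pd.DataFrame(columns=["a", "b", "pp"]), 0.01, 0.0)
        assert len(regulator_subgraph(net)) == 0

    def test_definitional_filter_matches_oracle(self, rng):
        rows = [("r1", "r2", 0.9), ("r1", "t1", 0.8), ("r2", "t2", 0.7), ("r2", "r1", 0.6)]
        net = CausalNetwork(pd.DataFrame(rows, columns=["a", "b", "pp"]), 0.01, 0.0)
        sub = regulator_subgraph(net)
        regs = set(net.regulators)
        oracle = {(a, b) for a, b, _ in rows if a in regs and b in regs}
        assert set(zip(sub["a"], sub["b"])) == oracle


class TestGreedyDag:
    def test_cycle_example_keeps_most_significant(self):
        dag = greedy_dag([("X", "Y", 0.99), ("Y", "X", 0.95), ("Y", "Z", 0.9)])
        assert [(a, b) for a, b, _ in dag.kept] == [("X", "Y"), ("Y", "Z")]
        assert [(a, b) for a, b, _ in dag.removed] == [("Y", "X")]

    def test_acyclic_input_untouched(self, rng):
        edges = [(u, v, rng.random()) for u, v in random_dag(rng, 8, 0.4)]
        dag = greedy_dag(edges)
        assert dag.removed == []
        assert len(dag.kept) == len(edges)

    def test_kept_plus_removed_equals_input_and_kept_acyclic(self, rng):
        for _ in range(30):
            edges = [(u, v, round(rng.random(), 3)) for u, v in random_digraph(rng, 6, 0.35)]
            dag = greedy_dag(edges)
            assert len(dag.kept) + len(dag.removed) == len(edges)
            g = nx.DiGraph((a, b) for a, b, _ in dag.kept)
            assert nx.is_directed_acyclic_graph(g)

    def test_matches_maximal_prefix_oracle(self, rng):
        # oracle: independently walk the sorted edge list with networkx,
        # keeping each edge iff the graph stays acyclic
        for _ in range(20):
            edges = [(u, v, round(rng.random(), 3)) for u, v in random_digraph(rng, 6, 0.4)]
            dag = greedy_dag(edges)
            g = nx.DiGraph()
            kept_oracle = []
            for a, b, pp in sorted(edges, key=lambda e: (-e[2], e[0], e[1])):
                g.add_edge(a, b)
                if nx.is_directed_acyclic_graph(g):
                    kept_oracle.append((a, b, pp))
                else:
                    g.remove_edge(a, b)
            assert dag.kept == kept_oracle


class TestAssignLevels:
    def test_chain_levels(self):
        dag = greedy_dag([("A", "B", 0.9), ("B", "C", 0.8)])
        assert assign_levels(dag) == {"A": 0, "B": 1, "C": 2}

    def test_diamond_levels(self):
        dag = greedy_dag(
            [("A", "B", 0.9), ("A", "C", 0.9), ("B", "D", 0.8), ("C", "D", 0.8)]
        )
        levels = assign_levels(dag)
        assert levels["A"] == 0 and levels["D"] == 2

    def test_matches_shortest_path_oracle(self, rng):
        for _ in range(20):
            edges = [(u, v, rng.random()) for u, v in random_dag(rng, 10, 0.3)]
            if not edges:
                continue
            dag = greedy_dag(edges)
            levels = assign_levels(dag)
            g = nx.DiGraph((a, b) for a, b, _ in dag.kept)
            roots = [n for n in g.nodes if g.in_degree(n) == 0]
            for node in g.nodes:
                oracle = min(
                    (
                        nx.shortest_path_length(g, r, node)
                        for r in roots
                        if nx.has_path(g, r, node)
                    ),
                )
                assert levels[node] == oracle

    def test_cyclic_input_raises(self):
        from cpnet.topology import DagLayout

        dag = DagLayout(kept=[("A", "B", 1.0), ("B", "A", 1.0)], removed=[])
        with pytest.raises(ValueError):
            assign_levels(dag)

    def test_reintroduced_edge_classes_partition(self, rng):
        edges = [(u, v, round(rng.random(), 3)) for u, v in random_digraph(rng, 8, 0.4)]
        dag = greedy_dag(edges)
        assign_levels(dag)
        classes = classify_reintroduced_edges(dag)
        assert set(classes) == {(a, b) for a, b, _ in dag.removed}
        for (a, b), label in classes.items():
            diff = dag.levels[b] - dag.levels[a]
            if diff == 0:
                assert label == "same-level"
            elif diff == -1:
                assert label == "one-above"
            elif diff == -2:
                assert label == "two-above"
            elif diff >= 1:
                assert label == "below"


class TestTransitiveReduction:
    def test_shortcut_removed(self):
        kept = transitive_reduction([("A", "B"), ("B", "C"), ("A", "C")])
        assert ("A", "C") not in kept and len(kept) == 2

    def test_tree_is_identity(self):
        tree = [("r", "a"), ("r", "b"), ("a", "c"), ("a", "d")]
        assert sorted(transitive_reduction(tree)) == sorted(tree)

    def test_preserves_reachability_on_random_dags(self, rng):
        # brute-force reachability oracle plus networkx cross-check
        for _ in range(50):
            edges = random_dag(rng, 12, 0.3)
            if not edges:
                continue
            reduced = transitive_reduction(edges)
            g_in = nx.DiGraph(edges)
            g_out = nx.DiGraph(reduced)
            g_out.add_nodes_from(g_in.nodes)
            for u in g_in.nodes:
                assert nx.descendants(g_in, u) == nx.descendants(g_out, u)
            nx_reduced = nx.transitive_reduction(g_in)
            assert set(nx_reduced.edges) == set(reduced)

    def test_cyclic_input_raises(self):
        with pytest.raises(ValueError):
            transitive_reduction([("A", "B"), ("B", "A")])


class TestCountMotifs:
    def test_ffl_triangle(self):
        counts = count_motifs([("x", "y"), ("y", "z"), ("x", "z")])
        assert counts == {"feedback_2": 0, "feedback_3": 0, "feedforward": 1}

    def test_two_node_feedback(self):
        counts = count_motifs([("x", "y"), ("y", "x")])
        assert counts["feedback_2"] == 1

    def test_three_cycle(self):
        counts = count_motifs([("x", "y"), ("y", "z"), ("z", "x")])
        assert counts["feedback_3"] == 1 and counts["feedforward"] == 0

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(25):
            edges = random_digraph(rng, 8, 0.25)
            eset = set(edges)
            nodes = sorted({n for e in edges for n in e})
            ffl = sum(
                1
                for x, y, z in itertools.permutations(nodes, 3)
                if (x, y) in eset and (y, z) in eset and (x, z) in eset
            )
            fb2 = sum(
                1 for x, y in itertools.combinations(nodes, 2)
                if (x, y) in eset and (y, x) in eset
            )
            fb3 = (
                sum(
                    1
                    for x, y, z in itertools.permutations(nodes, 3)
                    if (x, y) in eset and (y, z) in eset and (z, x) in eset
                )
                // 3
            )
            got = count_motifs(edges)
            assert got == {"feedback_2": fb2, "feedback_3": fb3, "feedforward": ffl}


class TestHubRobustness:
    def test_star_collapses_after_hub_removal(self):
        edges = [("hub", f"t{i}") for i in range(20)]
        table = hub_robustness(edges, k_max=1)
        assert table.loc[0, "largest_wcc_fraction"] == 1.0
        assert table.loc[1, "largest_wcc_fraction"] == pytest.approx(1 / 21)

    def test_disconnected_pairs_unaffected(self):
        edges = [("a", "b"), ("c", "d"), ("e", "f")]
        table = hub_robustness(edges, k_max=1)
        assert table.loc[1, "largest_wcc_fraction"] == pytest.approx(2 / 6)

    def test_matches_union_find_oracle(self, rng):
        def largest_cc_fraction(edges, removed, n0):
            nodes = {n for e in edges for n in e} - removed
            parent = {n: n for n in nodes}

            def find(x):
                while parent[x] != x:
                    parent[x] = parent[parent[x]]
                    x = parent[x]
                return x

            for u, v in edges:
                if u in nodes and v in nodes:
                    parent[find(u)] = find(v)
            from collections import Counter

            sizes = Counter(find(n) for n in nodes)
            return (max(sizes.values()) if sizes else 0) / n0

        for _ in range(10):
            edges = random_digraph(rng, 12, 0.15)
            if not edges:
                continue
            table = hub_robustness(edges, k_max=5)
            n0 = len({n for e in edges for n in e})
            for _, row in table.iterrows():
                frac = largest_cc_fraction(edges, set(row["removed"]), n0)
                assert row["largest_wcc_fraction"] == pytest.approx(frac)


class TestSubsampleAndEnrichment:
    def test_full_sample_subsample_gives_auc_one(self, small_run):
        # against the selection-stage network (the exact top-pp prefix),
        # re-scoring the full sample reproduces the selection perfectly
        from cpnet.netbuild import select_edges_global_fdr

        model, res = small_run
        n = res.panel.n_samples
        selection = select_edges_global_fdr(res.scores, model.config["edge_fdr"])
        rob = subsample_robustness(
            res.panel, model.snp_panel, res.instruments, selection,
            sizes=(n,), reps=1, seed=0,
        )
        assert rob["auc"].iloc[0] == 1.0

    def test_oversized_subsample_raises(self, small_run):
        model, res = small_run
        with pytest.raises(ValueError):
            subsample_robustness(
                res.panel, model.snp_panel, res.instruments, res.network,
                sizes=(res.panel.n_samples + 1,), reps=1,
            )

    def test_truth_driven_targets_more_correlated(self, small_run):
        model, res = small_run
        subs = [s for s in res.subnetworks if s.size >= 3]
        out = target_correlation_enrichment(subs, res.panel, n_random=30, seed=0)
        assert out["p"] < 0.01
        assert out["observed_median"] > out["random_median"]

    def test_null_panel_not_enriched(self, rng):
        n, p = 400, 40
        levels = rng.normal(0, 1, (n, p))
        ids = [f"A{j}" for j in range(p)]
        ann = pd.DataFrame(
            {"aptamer_id": ids, "gene": ids, "chrom": ["1"] * p, "tss": range(p)}
        )
        panel = ProteinPanel([f"S{i}" for i in range(n)], ids, levels, ann)
        subs = [Subnetwork("A0", set(ids[1:6])), Subnetwork("A6", set(ids[7:12]))]
        out = target_correlation_enrichment(subs, panel, n_random=50, seed=1)
        assert out["p"] > 1e-3

    def test_identical_groups_boundary(self, rng):
        n, p = 100, 6
        levels = rng.normal(0, 1, (n, p))
        ids = [f"A{j}" for j in range(p)]
        ann = pd.DataFrame(
            {"aptamer_id": ids, "gene": ids, "chrom": ["1"] * p, "tss": range(p)}
        )
        panel = ProteinPanel([f"S{i}" for i in range(n)], ids, levels, ann)
        subs = [Subnetwork("A0", set(ids))]

        # with the whole panel as the only group, every random draw is the
        # same group: degenerate comparison reports p = 1
        out = target_correlation_enrichment(subs, panel, n_random=3, seed=2)
        assert out["p"] == 1.0
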