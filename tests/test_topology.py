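"""Centralities, global stats, rewiring null, power-law fit, U test, top-k."""

import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

import omicsnet as on
from omicsnet.datatypes import ValidationError
from omicsnet.topology import (NullEnsembleConfig, null_global_stats,
                               rewire_once)
from conftest import random_gnp_graph
from oracles import (brute_centralities, brute_global_stats, mw_exact,
                     topk_sort_intersect)


class TestCentralities:
    def test_star_center_betweenness(self):
        g = on.new_network([("hub", f"leaf{i}") for i in range(5)])
        c = on.centralities(g)
        assert c.loc["hub", "betweenness"] == 10  # C(5,2)
        assert (c.loc[[f"leaf{i}" for i in range(5)], "betweenness"] == 0).all()

    def test_path_interior_betweenness(self):
        g = on.new_network([("a", "b"), ("b", "c"), ("c", "d")])
        c = on.centralities(g)
        assert c.loc["b", "betweenness"] == 2  # {a,c}, {a,d}

    def test_matches_enumeration_oracle_on_random_graphs(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 13))
            g = random_gnp_graph(n, float(rng.uniform(0.15, 0.35)), rng)
            c = on.centralities(g)
            oracle = brute_centralities(list(g.nodes()), list(g.edges()))
            for node in g.nodes():
                assert c.loc[node, "degree"] == oracle["degree"][node]
                assert c.loc[node, "closeness"] == pytest.approx(
                    oracle["closeness"][node], abs=1e-9)
                assert c.loc[node, "betweenness"] == pytest.approx(
                    oracle["betweenness"][node], abs=1e-9)

    def test_isolated_node_closeness_zero(self):
        g = on.new_network([("a", "b")], nodes=["c"])
        assert on.centralities(g).loc["c", "closeness"] == 0.0

    def test_empty_network_rejected(self):
        with pytest.raises(ValidationError):
            on.centralities(on.new_network())

    def test_permutation_symmetry(self, rng):
        g = random_gnp_graph(12, 0.3, rng)
        perm = {n: f"z{i:02d}" for i, n in enumerate(rng.permutation(sorted(g.nodes())))}
        h = nx.relabel_nodes(g, perm)
        cg, ch = on.centralities(g), on.centralities(h)
        for n in g.nodes():
            for f in ("degree", "closeness", "betweenness"):
                assert cg.loc[n, f] == pytest.approx(ch.loc[perm[n], f], abs=1e-12)


class TestGlobalStats:
    def test_triangle(self):
        gs = on.global_stats(on.new_network([("a", "b"), ("b", "c"), ("a", "c")]))
        assert gs.average_path_length == 1.0
        assert gs.clustering_coefficient == 1.0

    def test_three_node_path(self):
        gs = on.global_stats(on.new_network([("a", "b"), ("b", "c")]))
        assert gs.average_path_length == pytest.approx(4.0 / 3.0)
        assert gs.clustering_coefficient == 0.0

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(15):
            n = int(rng.integers(4, 13))
            g = random_gnp_graph(n, float(rng.uniform(0.2, 0.4)), rng)
            gs = on.global_stats(g)
            apl, trans, pairs = brute_global_stats(list(g.nodes()), list(g.edges()))
            assert gs.n_reachable_pairs == pairs
            if pairs:
                assert gs.average_path_length == pytest.approx(apl, abs=1e-12)
            assert gs.clustering_coefficient == pytest.approx(trans, abs=1e-12)

    def test_edgeless_network_flagged(self):
        gs = on.global_stats(on.new_network(nodes=["a", "b"]))
        assert not gs.apl_defined and math.isnan(gs.average_path_length)

    def test_global_stats_invariant_under_relabeling(self, rng):
        g = random_gnp_graph(14, 0.25, rng)
        h = nx.relabel_nodes(g, {n: f"q{n}" for n in g.nodes()})
        a, b = on.global_stats(g), on.global_stats(h)
        assert a.average_path_length == pytest.approx(b.average_path_length)
        assert a.clustering_coefficient == pytest.approx(b.clustering_coefficient)


class TestRewiringNull:
    def test_triangle_has_no_legal_swap(self, caplog):
        g = on.new_network([("a", "b"), ("b", "c"), ("a", "c")])
        with caplog.at_level("WARNING"):
            reps = list(on.degree_preserving_null(g, NullEnsembleConfig(n_random=3, seed=1)))
        for r in reps:
            assert set(r.edges()) == set(g.edges())
        assert any("zero accepted swaps" in rec.message for rec in caplog.records)

    def test_degree_sequence_and_edge_count_conserved(self):
        g = nx.relabel_nodes(nx.barabasi_albert_graph(120, 2, seed=4),
                             {i: f"n{i:03d}" for i in range(120)})
        orig_deg = sorted(d for _, d in g.degree())
        for rep in on.degree_preserving_null(g, NullEnsembleConfig(n_random=20, seed=9)):
            assert sorted(d for _, d in rep.degree()) == orig_deg
            assert rep.number_of_edges() == g.number_of_edges()
            assert not list(nx.selfloop_edges(rep))

    def test_two_disjoint_edges_reach_both_swap_outcomes(self):
        g = on.new_network([("a", "b"), ("c", "d")])
        seen = set()
        for i in range(1000):
            edges, _ = rewire_once(g, seed=3, replicate=i)
            seen.add(tuple(sorted(edges)))
        assert (("a", "d"), ("b", "c")) in {tuple(s) for s in seen} or \
               (("a", "d"), ("c", "b")) in {tuple(s) for s in seen}
        assert {tuple(s) for s in seen} >= {(("a", "c"), ("b", "d")),
                                            (("a", "d"), ("b", "c"))}

    def test_replicate_deterministic_in_seed_and_index(self):
        g = nx.relabel_nodes(nx.barabasi_albert_graph(50, 2, seed=1),
                             {i: f"n{i:02d}" for i in range(50)})
        e1, _ = rewire_once(g, seed=5, replicate=7)
        e2, _ = rewire_once(g, seed=5, replicate=7)
        e3, _ = rewire_once(g, seed=5, replicate=8)
        assert e1 == e2 and e1 != e3

    def test_actually_randomizes(self):
        g = nx.relabel_nodes(nx.barabasi_albert_graph(50, 2, seed=1),
                             {i: f"n{i:02d}" for i in range(50)})
        edges, accepted = rewire_once(g, seed=0, replicate=0)
        assert accepted > 0
        assert set(edges) != {tuple(sorted(e)) for e in g.edges()}

    def test_null_global_stats_agrees_with_graph_route(self):
        g = nx.relabel_nodes(nx.barabasi_albert_graph(40, 3, seed=2),
                             {i: f"n{i:02d}" for i in range(40)})
        cfg = NullEnsembleConfig(n_random=5, seed=11)
        fast = null_global_stats(g, cfg)
        slow = [on.global_stats(r) for r in on.degree_preserving_null(g, cfg)]
        for i, gs in enumerate(slow):
            assert fast.loc[i, "average_path_length"] == pytest.approx(
                gs.average_path_length, abs=1e-12)
            assert fast.loc[i, "clustering_coefficient"] == pytest.approx(
                gs.clustering_coefficient, abs=1e-12)


class TestEmpiricalP:
    def test_counting_oracle(self):
        assert on.empirical_p(3.5, [1, 2, 3, 4, 5], tail="greater") == pytest.approx(0.4)
        assert on.empirical_p(3.5, [1, 2, 3, 4, 5], tail="less") == pytest.approx(0.6)

    def test_observed_above_all_nulls_strict_zero(self):
        null = list(range(1000))
        assert on.empirical_p(2000.0, null, tail="greater") == 0.0

    def test_tie_boundary_strict_vs_smoothed(self):
        null = [5.0] * 100
        assert on.empirical_p(5.0, null, tail="greater") == 0.0
        assert on.empirical_p(5.0, null, tail="greater", smoothed=True) == 1.0

    def test_empty_null_rejected(self):
        with pytest.raises(ValidationError):
            on.empirical_p(1.0, [])


class TestPowerLaw:
    def test_single_degree_value_rejected(self):
        with pytest.raises(ValidationError, match="distinct"):
            on.fit_power_law([4] * 50)

    def test_exact_k_minus_2_counts(self):
        degrees = []
        for k in (1, 2, 4, 8, 16, 32):
            degrees += [k] * (32 // k) ** 2
        fit = on.fit_power_law(degrees)
        assert fit.slope == pytest.approx(-2.0, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_preferential_attachment_slope_range(self):
        g = nx.barabasi_albert_graph(1000, 2, seed=13)
        fit = on.fit_power_law([d for _, d in g.degree()])
        assert -3.5 <= fit.slope <= -1.5


class TestMannWhitney:
    def test_identical_multisets_u_half(self):
        vals = [1, 2, 3, 4]
        u, p = on.mann_whitney_u(vals, vals)
        assert u == len(vals) ** 2 / 2
        assert p == pytest.approx(1.0)

    def test_all_wins_exact_two_sided(self):
        u, p = on.mann_whitney_u([10, 11, 12], [1, 2, 3])
        assert u == 9
        assert p == pytest.approx(0.1)  # 2 / C(6,3)

    def test_exact_matches_independent_enumeration(self, rng):
        for _ in range(10):
            x = rng.normal(size=int(rng.integers(3, 6)))
            y = rng.normal(size=int(rng.integers(3, 6)))
            _, p = on.mann_whitney_u(x, y, method="exact")
            assert p == pytest.approx(mw_exact(x, y), abs=1e-12)

    def test_asymptotic_near_exact_for_6v6(self, rng):
        for _ in range(10):
            x, y = rng.normal(size=6), rng.normal(size=6)
            _, p_asym = on.mann_whitney_u(x, y, method="asymptotic")
            _, p_exact = on.mann_whitney_u(x, y, method="exact")
            assert abs(p_asym - p_exact) <= 0.02

    def test_compare_risk_vs_background(self, rng):
        g = random_gnp_graph(30, 0.2, rng)
        for i, n in enumerate(sorted(g.nodes())):
            g.nodes[n]["is_risk"] = i < 8
        report = on.centralities(g)
        cmp = on.compare_risk_vs_background(report, g)
        assert set(cmp.index) == {"degree", "closeness", "betweenness"}
        assert ((cmp["p_value"] >= 0) & (cmp["p_value"] <= 1)).all()
        assert (cmp["n_risk"] == 8).all() and (cmp["n_background"] == 22).all()


class TestTopK:
    def test_star_top1_all_features(self):
        g = on.new_network([("hub", f"l{i}") for i in range(6)])
        res = on.top_k_intersection(on.centralities(g), k=1)
        assert res.candidates == ["hub"]

    def test_k_equals_network_size_gives_all(self, rng):
        g = random_gnp_graph(12, 0.3, rng)
        res = on.top_k_intersection(on.centralities(g), k=12)
        assert res.candidates == sorted(g.nodes())

    def test_restricts_to_risk_flags(self, rng):
        g = random_gnp_graph(20, 0.3, rng)
        risky = sorted(g.nodes())[:4]
        for n in risky:
            g.nodes[n]["is_risk"] = True
        res = on.top_k_intersection(on.centralities(g), k=20)
        assert res.candidates == risky

    def test_k_out_of_range_rejected(self, rng):
        g = random_gnp_graph(5, 0.5, rng)
        with pytest.raises(ValidationError):
            on.top_k_intersection(on.centralities(g), k=6)

    def test_matches_sort_and_intersect_oracle(self, rng):
        g = random_gnp_graph(60, 0.08, rng)
        report = on.centralities(g)
        res = on.top_k_intersection(report, k=15, restrict_to_risk=False)
        oracle = topk_sort_intersect(
            {f: report[f].to_dict() for f in ("degree", "closeness", "betweenness")},
            k=15, risk=None)
        assert res.candidates == oracle
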