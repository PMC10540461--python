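"""Optimal and heuristic capping, Hall completion and search-space bounds."""

import itertools
import math

import pytest

from ffortho.capping import (
    CappingConfig,
    PerfectSharedContentGraph,
    SharedContentGraph,
    bregman_minc_bound,
    build_shared_content_graph,
    capping_search_space_bound,
    complete_to_perfect,
    evaluate_capping,
    find_hall_violator,
    has_perfect_matching,
    heuristic_capping,
    induced_capping,
    iter_capping_sets,
    iter_perfect_matchings,
    maximum_bipartite_matching,
    min_capping_cost,
    optimal_capping,
    prune_non_matchable,
)
from ffortho.ffr import SIDE_A, SIDE_B, build_ffr, induce_decomposition
from ffortho.fixtures import load_fixture
from ffortho.genomes import genome_from_lists
from ffortho.similarity import GeneSimilarityGraph
from ffortho.simulate import random_instance_pair


def _one_gene_genomes(n_a, n_b):
    a = genome_from_lists("A", {f"a{i:03d}": [f"a{i}"] for i in range(n_a)})
    b = genome_from_lists("B", {f"b{i:03d}": [f"b{i}"] for i in range(n_b)})
    return a, b, GeneSimilarityGraph(a, b)


class TestOptimalCapping:
    def test_worked_example_dimensions(self):
        fx = load_fixture("fig2")
        capped = optimal_capping(fx["ffr"])
        assert capped.p == fx["p_star"] == 2
        assert capped.n_cap_vertices_per_side == 4
        assert len(capped.dummy_adjacencies[SIDE_A]) == 0
        assert len(capped.dummy_adjacencies[SIDE_B]) == 1
        assert capped.n_cap_edges == 16
        assert sum(1 for _ in iter_capping_sets(capped)) == math.factorial(4)

    def test_single_segment_genomes(self):
        a, b, sim = _one_gene_genomes(1, 1)
        capped = optimal_capping(build_ffr(a, b, sim))
        assert capped.n_cap_edges == 4
        assert not capped.dummy_adjacencies[SIDE_A]
        assert not capped.dummy_adjacencies[SIDE_B]

    def test_fly_scale_cap_edge_count(self):
        a, b, sim = _one_gene_genomes(507, 507)
        capped = optimal_capping(build_ffr(a, b, sim))
        assert capped.n_cap_edges == 1_028_196


class TestSharedContentGraph:
    def _instance(self, omega_rows):
        """Build genomes + similarity so that Omega matches omega_rows."""
        segs_a = sorted({r[0] for r in omega_rows})
        segs_b = sorted({r[1] for r in omega_rows})
        genes_a, genes_b, edges = {}, {}, []
        for k, (sa, sb, w) in enumerate(omega_rows):
            ga, gb = f"x{k}", f"y{k}"
            genes_a.setdefault(sa, []).append(ga)
            genes_b.setdefault(sb, []).append(gb)
            edges.append((ga, gb, w))
        a = genome_from_lists("A", {s: genes_a.get(s, [f"fill{s}"]) for s in segs_a})
        b = genome_from_lists("B", {s: genes_b.get(s, [f"fill{s}"]) for s in segs_b})
        sim = GeneSimilarityGraph(a, b)
        for ga, gb, w in edges:
            sim.add_edge(ga, gb, min(w, 1.0))
        return a, b, sim

    def test_omega_sums_similarity_scores(self):
        a, b, sim = self._instance([("s1", "t1", 0.9)])
        g = build_shared_content_graph(a, b, sim, CappingConfig(tau=5, eps=0.01))
        assert g.omega("s1", "t1") == pytest.approx(0.9)

    def test_tau_filter_drops_rank_three_edge(self):
        # one A-segment with incident scores 1.0, 0.5, 0.1; tau=2 keeps two
        rows = [("s1", "t1", 1.0), ("s1", "t2", 0.5), ("s1", "t3", 0.1)]
        a, b, sim = self._instance(rows)
        g = build_shared_content_graph(a, b, sim, CappingConfig(tau=2, eps=0.01))
        assert ("s1", "t3") not in g.edges
        assert {("s1", "t1"), ("s1", "t2")} <= set(g.edges)

    def test_tau_filter_keeps_ties_at_rank(self):
        rows = [("s1", "t1", 1.0), ("s1", "t2", 0.5), ("s1", "t3", 0.5)]
        a, b, sim = self._instance(rows)
        g = build_shared_content_graph(a, b, sim, CappingConfig(tau=2, eps=0.01))
        assert len(g.edges) == 3  # both rank-2 ties survive

    def test_eps_filter_on_surviving_scores(self):
        # 0.5 >= 0.1 * 1.0 -> kept; 0.09 < 0.1 * 1.0 -> removed
        keep = self._instance([("s1", "t1", 1.0), ("s1", "t2", 0.5)])
        g = build_shared_content_graph(*keep, CappingConfig(tau=5, eps=0.1))
        assert len(g.edges) == 2
        drop = self._instance([("s1", "t1", 1.0), ("s1", "t2", 0.09)])
        g = build_shared_content_graph(*drop, CappingConfig(tau=5, eps=0.1))
        assert set(g.edges) == {("s1", "t1")}


class TestHallViolator:
    def test_star_violator(self):
        # three leaves share one center: whichever leaf is unsaturated, the
        # alternating reachability adds the matched leaf, certifying
        # |N(S)| = 1 < |S| = 2
        adj = {"a1": ["b"], "a2": ["b"], "a3": ["b"]}
        m = maximum_bipartite_matching(["a1", "a2", "a3"], adj)
        unsat = next(u for u in ("a1", "a2", "a3") if u not in m)
        s = find_hall_violator([], adj, {b: a for a, b in m.items()}, unsat)
        assert unsat in s
        assert s == {unsat} | set(m)
        assert len({n for u in s for n in adj[u]}) < len(s)

    def test_saturated_vertex_rejected(self):
        adj = {"a1": ["b1"]}
        with pytest.raises(ValueError):
            find_hall_violator([], adj, {"b1": "a1"}, "a1")


class TestCompletion:
    def test_fig4_completion(self):
        chat = complete_to_perfect(load_fixture("fig4"))
        assert sorted(chat.dummies_a) == ["phi:A:1"]
        assert sorted(chat.dummies_b) == ["phi:B:1"]
        # the completed left component is not a complete bipartite subgraph
        left = next(
            c for c in chat.components() if "A1" in c[0]
        )
        assert left == ({"A1", "A2", "A3"}, {"B1", "B2", "phi:B:1"})
        n_component_edges = sum(
            1 for (a, b) in chat.edges if a in left[0] and b in left[1]
        )
        assert n_component_edges < len(left[0]) * len(left[1])
        # the non-matchable edge was removed
        assert ("A4", "B4") not in chat.edges
        assert chat.has_perfect_matching()

    def test_already_perfect_graph_only_pruned(self):
        g = SharedContentGraph(
            ["A1", "A2"], ["B1", "B2"],
            {("A1", "B1"): 1.0, ("A2", "B1"): 0.5, ("A2", "B2"): 1.0},
        )
        chat = complete_to_perfect(g)
        assert not chat.dummies_a and not chat.dummies_b
        # A2-B1 lies in no perfect matching and is pruned
        assert set(chat.edges) == {("A1", "B1"), ("A2", "B2")}

    def test_two_left_one_right_gets_one_dummy(self):
        g = SharedContentGraph(
            ["A1", "A2"], ["B1"], {("A1", "B1"): 1.0, ("A2", "B1"): 1.0}
        )
        chat = complete_to_perfect(g)
        assert len(chat.dummies_b) == 1 and not chat.dummies_a
        dummy = next(iter(chat.dummies_b))
        assert {("A1", dummy), ("A2", dummy)} <= chat.edges

    def test_hall_condition_holds_everywhere_after_completion(self, rng):
        for _ in range(20):
            na, nb = int(rng.integers(1, 5)), int(rng.integers(1, 5))
            edges = {
                (f"A{i}", f"B{j}"): 1.0
                for i in range(na)
                for j in range(nb)
                if rng.random() < 0.4
            }
            g = SharedContentGraph(
                [f"A{i}" for i in range(na)], [f"B{j}" for j in range(nb)], edges
            )
            chat = complete_to_perfect(g)
            adj = chat._adj()
            radj = {}
            for a, bs in adj.items():
                for b in bs:
                    radj.setdefault(b, []).append(a)
            for side_nodes, side_adj in ((chat.order_a, adj), (chat.order_b, radj)):
                for r in range(1, len(side_nodes) + 1):
                    for subset in itertools.combinations(side_nodes, r):
                        nbh = {v for u in subset for v in side_adj.get(u, ())}
                        assert len(nbh) >= len(subset)

    def test_prune_matches_brute_force_enumeration(self, rng):
        for _ in range(25):
            n = int(rng.integers(1, 6))
            edges = {
                (f"A{i}", f"B{j}")
                for i in range(n)
                for j in range(n)
                if rng.random() < 0.5
            }
            adj = {f"A{i}": sorted(b for a, b in edges if a == f"A{i}") for i in range(n)}
            if not has_perfect_matching(
                [f"A{i}" for i in range(n)], [f"B{j}" for j in range(n)], adj
            ):
                continue
            g = PerfectSharedContentGraph(
                [f"A{i}" for i in range(n)], [f"B{j}" for j in range(n)], [], [], edges
            )
            pruned = prune_non_matchable(g)
            brute = set()
            for pm in iter_perfect_matchings(g.order_a, adj):
                brute.update(pm)
            assert pruned.edges == brute


class TestHeuristicCapping:
    def _capped_from_edges(self, n_a, n_b, seg_edges):
        a, b, sim = _one_gene_genomes(n_a, n_b)
        ffr = build_ffr(a, b, sim)
        g = SharedContentGraph(
            ffr.segment_order[SIDE_A],
            ffr.segment_order[SIDE_B],
            {e: 1.0 for e in seg_edges},
        )
        chat = complete_to_perfect(g)
        return ffr, chat, heuristic_capping(ffr, chat)

    def test_single_real_edge_gives_four_cap_edges(self):
        _, _, capped = self._capped_from_edges(1, 1, [("a000", "b000")])
        assert capped.n_cap_edges == 4

    def test_lone_dummy_component_gives_two_cap_edges(self):
        # segments a000-b000 share content; a001 has no partner -> B dummy
        _, chat, capped = self._capped_from_edges(2, 1, [("a000", "b000")])
        assert len(chat.dummies_b) == 1
        # 4 cap edges for the real pair + 2 for the optimized dummy pair
        assert capped.n_cap_edges == 6
        assert capped.is_valid()

    def test_cap_edge_count_formula_on_fig4(self):
        fx = load_fixture("fig4")
        a = genome_from_lists("A", [[f"g{s}"] for s in sorted(fx.segments_a)])
        b = genome_from_lists("B", [[f"h{s}"] for s in sorted(fx.segments_b)])
        # rename segments to match the fixture ids
        a = genome_from_lists("A", {s: [f"g{s}"] for s in sorted(fx.segments_a)})
        b = genome_from_lists("B", {s: [f"h{s}"] for s in sorted(fx.segments_b)})
        ffr = build_ffr(a, b, GeneSimilarityGraph(a, b))
        chat = complete_to_perfect(fx)
        capped = heuristic_capping(ffr, chat)
        lone_dummy = sum(
            1
            for (x, y) in chat.edges
            if chat.degree(SIDE_A, x) == 1
            and chat.degree(SIDE_B, y) == 1
            and (chat.is_dummy(SIDE_A, x) or chat.is_dummy(SIDE_B, y))
        )
        assert capped.n_cap_edges == 4 * len(chat.edges) - 2 * lone_dummy

    def test_heuristic_never_exceeds_optimal_cap_edges(self, rng):
        for _ in range(10):
            a, b, sim = random_instance_pair(rng)
            ffr = build_ffr(a, b, sim)
            opt = optimal_capping(ffr)
            scg = build_shared_content_graph(a, b, sim, CappingConfig())
            capped = heuristic_capping(ffr, complete_to_perfect(scg))
            if capped.p == opt.p:
                assert capped.n_cap_edges <= opt.n_cap_edges

    def test_component_independence(self, rng):
        """Caps of segments in different components never share a cap edge."""
        for _ in range(10):
            a, b, sim = random_instance_pair(rng)
            ffr = build_ffr(a, b, sim)
            scg = build_shared_content_graph(a, b, sim, CappingConfig())
            chat = complete_to_perfect(scg)
            capped = heuristic_capping(ffr, chat)
            comp_of = {}
            for k, (ca, cb) in enumerate(chat.components()):
                for s in ca:
                    comp_of[(SIDE_A, s)] = k
                for s in cb:
                    comp_of[(SIDE_B, s)] = k
            pos_a = {i + 1: s for i, s in enumerate(chat.order_a)}
            pos_b = {j + 1: s for j, s in enumerate(chat.order_b)}
            for i, j in capped.cap_edges():
                sa = pos_a[(i + 1) // 2]
                sb = pos_b[(j + 1) // 2]
                assert comp_of[(SIDE_A, sa)] == comp_of[(SIDE_B, sb)]


class TestValidity:
    def test_perfect_matching_iff_valid_capping_small(self):
        """Lemma-style equivalence on all 3+3 segment graphs."""
        a, b, sim = _one_gene_genomes(3, 3)
        ffr = build_ffr(a, b, sim)
        segs_a, segs_b = ffr.segment_order[SIDE_A], ffr.segment_order[SIDE_B]
        pairs = [(x, y) for x in segs_a for y in segs_b]
        for mask in range(1 << len(pairs)):
            edges = [pairs[k] for k in range(len(pairs)) if mask >> k & 1]
            adj = {}
            for x, y in edges:
                adj.setdefault(x, []).append(y)
            pm = has_perfect_matching(segs_a, segs_b, adj)
            assert pm == induced_capping(ffr, edges).is_valid()


class TestSearchSpace:
    def test_complete_graphs_are_tight(self):
        k22 = PerfectSharedContentGraph(
            ["A1", "A2"], ["B1", "B2"], [], [],
            {(a, b) for a in ("A1", "A2") for b in ("B1", "B2")},
        )
        out = capping_search_space_bound(k22)
        assert out["exact"] == 2 and out["bound"] == pytest.approx(2.0)
        k33 = PerfectSharedContentGraph(
            [f"A{i}" for i in range(3)], [f"B{i}" for i in range(3)], [], [],
            {(f"A{i}", f"B{j}") for i in range(3) for j in range(3)},
        )
        out = capping_search_space_bound(k33)
        assert out["exact"] == 6 and out["bound"] == pytest.approx(6.0)

    def test_diagonal_graph_has_one_matching(self):
        diag = PerfectSharedContentGraph(
            ["A1", "A2"], ["B1", "B2"], [], [], {("A1", "B1"), ("A2", "B2")}
        )
        out = capping_search_space_bound(diag)
        assert out["exact"] == 1 and out["bound"] == pytest.approx(1.0)

    def test_non_square_rejected(self):
        g = PerfectSharedContentGraph.__new__(PerfectSharedContentGraph)
        g.order_a, g.order_b = ["A1"], ["B1", "B2"]
        with pytest.raises(ValueError):
            capping_search_space_bound(g)

    def test_bound_dominates_exact_on_random_graphs(self, rng):
        for _ in range(20):
            n = int(rng.integers(1, 6))
            edges = {
                (f"A{i}", f"B{j}")
                for i in range(n)
                for j in range(n)
                if rng.random() < 0.6
            }
            g = PerfectSharedContentGraph(
                [f"A{i}" for i in range(n)], [f"B{j}" for j in range(n)], [], [], edges
            )
            out = capping_search_space_bound(g)
            assert out["exact"] <= out["bound"] + 1e-9


def test_bregman_minc_zero_degree_row():
    assert bregman_minc_bound([2, 0]) == 0.0
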