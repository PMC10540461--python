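"""Relational-graph construction, decompositions and DCJ-indel distances."""

import numpy as np
import pytest

from ffortho.brute import bfs_dcj_indel_distance
from ffortho.ffr import (
    DistanceReport,
    InconsistentSiblingSetError,
    SIDE_A,
    SIDE_B,
    SiblingSet,
    build_ffr,
    dcj_indel_distance,
    induce_decomposition,
    iter_matchings,
    weighted_distance,
)
from ffortho.fixtures import identity_matching, load_fixture
from ffortho.genomes import genome_from_lists
from ffortho.similarity import GeneSimilarityGraph
from ffortho.simulate import random_instance_pair


class TestConstruction:
    def test_worked_example_counts(self, fig1):
        ffr = build_ffr(fig1["genome_a"], fig1["genome_b"], fig1["sim"])
        assert ffr.n_vertices == 26
        assert ffr.n_indel_edges == (6, 7)
        # a segment of k genes contributes k-1 adjacency edges
        assert ffr.n_adjacency_edges(SIDE_A) == 3 + 1
        assert ffr.n_adjacency_edges(SIDE_B) == 6
        # every similarity edge contributes exactly one sibling pair
        assert len(ffr.sibling_pairs) == fig1["sim"].n_edges

    def test_single_gene_pair(self):
        a = genome_from_lists("A", [["x"]])
        b = genome_from_lists("B", [["y"]])
        sim = GeneSimilarityGraph(a, b)
        sim.add_edge("x", "y", 1.0)
        ffr = build_ffr(a, b, sim)
        assert ffr.n_vertices == 4
        assert len(ffr.sibling_pairs) == 1
        assert ffr.n_adjacency_edges(SIDE_A) == ffr.n_adjacency_edges(SIDE_B) == 0

    def test_empty_similarity_graph(self):
        a = genome_from_lists("A", [["x"]])
        b = genome_from_lists("B", [["y"]])
        ffr = build_ffr(a, b, GeneSimilarityGraph(a, b))
        assert ffr.sibling_pairs == []


class TestDecomposition:
    def test_worked_example_census(self, fig1):
        ffr = build_ffr(fig1["genome_a"], fig1["genome_b"], fig1["sim"])
        d = induce_decomposition(ffr, fig1["black_ortholog_set"])
        assert d.census() == {"cycles": 1, "AA": 1, "BB": 0, "AB": 2}

    def test_empty_matching_has_kappa_paths(self, rng):
        for _ in range(10):
            a, b, sim = random_instance_pair(rng)
            ffr = build_ffr(a, b, sim)
            d = induce_decomposition(ffr, [])
            census = d.census()
            assert census["AA"] + census["BB"] + census["AB"] == a.kappa + b.kappa

    def test_path_count_invariant_over_all_sibling_sets(self, rng):
        for _ in range(5):
            a, b, sim = random_instance_pair(rng, max_genes=3)
            ffr = build_ffr(a, b, sim)
            for matching in iter_matchings(sim.sorted_edges()):
                census = induce_decomposition(ffr, matching).census()
                n_paths = census["AA"] + census["BB"] + census["AB"]
                assert n_paths == a.kappa + b.kappa

    def test_identical_two_gene_genomes_census(self):
        a = genome_from_lists("A", [["1", "2"]])
        b = genome_from_lists("B", [["1", "2"]])
        sim = GeneSimilarityGraph(a, b)
        sim.add_edge("1", "1", 1.0)
        sim.add_edge("2", "2", 1.0)
        ffr = build_ffr(a, b, sim)
        d = induce_decomposition(ffr, [("1", "1"), ("2", "2")])
        # hand enumeration: the two outer telomere pairs give AB-paths, the
        # inner adjacency pair closes one cycle
        assert d.census() == {"cycles": 1, "AA": 0, "BB": 0, "AB": 2}

    def test_invalid_sibling_sets_rejected(self, fig1):
        ffr = build_ffr(fig1["genome_a"], fig1["genome_b"], fig1["sim"])
        with pytest.raises(InconsistentSiblingSetError):
            induce_decomposition(ffr, [("1", "7"), ("1", "8")])  # incident
        with pytest.raises(InconsistentSiblingSetError):
            SiblingSet.from_extremity_edges(
                ffr, [((SIDE_A, "1", "t"), (SIDE_B, "7", "t"))]  # lone edge
            )


class TestDistances:
    def test_identity_matching_distance_zero(self):
        a = genome_from_lists("A", [["1", "2"]])
        b = genome_from_lists("B", [["1", "2"]])
        assert dcj_indel_distance(a, b, [("1", "1"), ("2", "2")]) == 0

    def test_translocation_example_is_one_operation(self, background):
        a, a2 = background["translocation"]
        o = identity_matching(a, a2)
        assert dcj_indel_distance(a, a2, o) == 1
        assert bfs_dcj_indel_distance(a, a2, o) == 1

    def test_block_deletion_example_is_one_operation(self, background):
        d1, d2 = background["deletion"]
        o = identity_matching(d1, d2)
        assert dcj_indel_distance(d1, d2, o) == 1
        assert bfs_dcj_indel_distance(d1, d2, o) == 1

    def test_non_matching_rejected(self):
        a = genome_from_lists("A", [["1", "2"]])
        b = genome_from_lists("B", [["1"]])
        with pytest.raises(InconsistentSiblingSetError):
            dcj_indel_distance(a, b, [("1", "1"), ("2", "1")])

    def test_distance_agrees_with_state_space_oracle(self, rng):
        """Capped-decomposition cost equals the exhaustive operation count."""
        checked = 0
        for _ in range(25):
            a, b, sim = random_instance_pair(rng, max_genes=3, max_segments=2)
            matchings = list(iter_matchings(sim.sorted_edges()))
            pick = rng.permutation(len(matchings))[:2]
            for k in pick:
                o = matchings[int(k)]
                assert dcj_indel_distance(a, b, o) == bfs_dcj_indel_distance(
                    a, b, o, max_ops=9
                )
                checked += 1
        assert checked >= 25


class TestWeightedDistance:
    def test_report_formula(self):
        r = DistanceReport(d=3, o_size=2, sigma_o=1.5, w_comp=0.7)
        assert r.wd == pytest.approx(4.2)

    def test_identical_genomes_full_matching_wd_zero(self):
        a = genome_from_lists("A", [["1", "2"]])
        b = genome_from_lists("B", [["1", "2"]])
        sim = GeneSimilarityGraph(a, b)
        sim.add_edge("1", "1", 1.0)
        sim.add_edge("2", "2", 1.0)
        r = weighted_distance(a, b, sim, [("1", "1"), ("2", "2")])
        assert r.wd == 0.0

    def test_empty_matching_wd_is_distance_plus_all_weights(self):
        a = genome_from_lists("A", [["1"]])
        b = genome_from_lists("B", [["2"]])
        sim = GeneSimilarityGraph(a, b)
        sim.add_edge("1", "2", 0.4)
        r = weighted_distance(a, b, sim, [])
        assert r.o_size == 0 and r.sigma_o == 0
        assert r.w_comp == pytest.approx(0.8)
        assert r.wd == pytest.approx(r.d + 0.8)

    def test_pair_outside_similarity_graph_rejected(self):
        a = genome_from_lists("A", [["1"]])
        b = genome_from_lists("B", [["2"]])
        with pytest.raises(InconsistentSiblingSetError):
            weighted_distance(a, b, GeneSimilarityGraph(a, b), [("1", "2")])

    def test_wd_invariant_under_relabeling_and_segment_reversal(self, rng):
        for _ in range(5):
            a, b, sim = random_instance_pair(rng, max_genes=3, max_segments=2)
            matchings = list(iter_matchings(sim.sorted_edges()))
            o = matchings[int(rng.integers(0, len(matchings)))]
            base = weighted_distance(a, b, sim, o).wd

            # relabel genes of A
            mapping = {g: f"r_{g}" for g in a.gene_ids}
            a2 = genome_from_lists(
                "A",
                [
                    [
                        ("-" if s.genes[i].orientation < 0 else "")
                        + mapping[s.genes[i].gene_id]
                        for i in range(len(s.genes))
                    ]
                    for s in a.segments
                ],
            )
            sim2 = GeneSimilarityGraph(a2, b)
            for (x, y), v in sim.edges.items():
                sim2.add_edge(mapping[x], y, v)
            o2 = [(mapping[x], y) for x, y in o]
            assert weighted_distance(a2, b, sim2, o2).wd == pytest.approx(base)

            # reverse a whole segment of A (orientation flip)
            segs = []
            for si, s in enumerate(a.segments):
                tokens = [
                    ("-" if g.orientation < 0 else "") + g.gene_id for g in s.genes
                ]
                if si == 0:
                    tokens = [
                        (t[1:] if t.startswith("-") else "-" + t)
                        for t in reversed(tokens)
                    ]
                segs.append(tokens)
            a3 = genome_from_lists("A", segs)
            sim3 = GeneSimilarityGraph(a3, b)
            for (x, y), v in sim.edges.items():
                sim3.add_edge(x, y, v)
            assert weighted_distance(a3, b, sim3, o).wd == pytest.approx(base)
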