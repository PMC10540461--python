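"""Worked-example fixtures used throughout the tests and documentation.

All fixtures are generated programmatically.  The two-genome example
(``fig1``/``fig2``) uses genomes A = {[1 2 3 4], [5 -6]} and
B = {[7 -8 -9 -10 11 12 13]}; its similarity-edge scores are a synthetic,
documented, plausible assignment (the worked example defines the edge
structure visually, not numerically), so tests built on it assert
structure — component census, ranking consistency — never the scores
themselves.  The ``fig4`` shared-content graph is likewise a synthetic
stand-in constructed to satisfy every documented property of the
completion example: one Hall violator of deficiency 1 per side, one dummy
segment per side, a completed component that is not complete bipartite and
at least one non-matchable dummy edge.
"""

from __future__ import annotations

from .capping import SharedContentGraph
from .ffr import build_ffr
from .genomes import Genome, genome_from_lists
from .similarity import GeneSimilarityGraph

#: the "black" ortholog-set of the two-genome worked example
FIG1_BLACK_ORTHOLOG_SET = [("1", "7"), ("3", "10"), ("4", "9"), ("5", "13")]

#: synthetic, plausible similarity scores for the worked example
FIG1_SIMILARITY_EDGES = [
    ("1", "7", 0.9),
    ("2", "8", 0.8),
    ("3", "10", 0.9),
    ("4", "9", 0.9),
    ("5", "11", 0.6),
    ("5", "13", 0.7),
    ("6", "8", 0.5),
]


def fig1() -> dict:
    genome_a = genome_from_lists("A", {"S1": ["1", "2", "3", "4"], "S2": ["5", "-6"]})
    genome_b = genome_from_lists(
        "B", {"S1": ["7", "-8", "-9", "-10", "11", "12", "13"]}
    )
    sim = GeneSimilarityGraph(genome_a, genome_b)
    for a, b, s in FIG1_SIMILARITY_EDGES:
        sim.add_edge(a, b, s)
    return {
        "genome_a": genome_a,
        "genome_b": genome_b,
        "sim": sim,
        "black_ortholog_set": list(FIG1_BLACK_ORTHOLOG_SET),
    }


def fig2() -> dict:
    """The same instance, prepared for capping: p* = 2, one dummy adjacency in B."""
    fx = fig1()
    fx["ffr"] = build_ffr(fx["genome_a"], fx["genome_b"], fx["sim"])
    fx["p_star"] = max(fx["genome_a"].kappa, fx["genome_b"].kappa)
    return fx


def fig4() -> SharedContentGraph:
    """Synthetic 5+5-segment shared-content graph needing one dummy per side.

    Left component: A1..A3 vs B1,B2 — the violator {A1,A2,A3} has
    deficiency 1 and demands a dummy segment connected to all three; the
    completed component is connected but not complete bipartite.  Right
    component: A4,A5 vs B3,B4 plus the isolated B5, which demands the
    dummy on the A side; the completed graph contains one non-matchable
    edge (A4-B4) that the final pruning removes.
    """
    edges = {
        ("A1", "B1"): 1.0,
        ("A2", "B1"): 1.0,
        ("A2", "B2"): 1.0,
        ("A3", "B2"): 1.0,
        ("A4", "B3"): 1.0,
        ("A4", "B4"): 1.0,
        ("A5", "B4"): 1.0,
    }
    return SharedContentGraph(
        [f"A{i}" for i in range(1, 6)], [f"B{i}" for i in range(1, 6)], edges
    )


def background_dcj() -> dict:
    """The translocation and deletion examples of the rearrangement model."""
    translocation_from = genome_from_lists(
        "A", {"c1": ["-6", "1", "8", "9", "-4"], "c2": ["3", "-5", "-7", "2"]}
    )
    translocation_to = genome_from_lists(
        "A'", {"c1": ["-6", "1", "2"], "c2": ["3", "-5", "-7", "8", "9", "-4"]}
    )
    deletion_from = genome_from_lists("D", {"c1": ["3", "-5", "-7", "8", "9", "-4"]})
    deletion_to = genome_from_lists("D'", {"c1": ["3", "-5", "-4"]})
    return {
        "translocation": (translocation_from, translocation_to),
        "deletion": (deletion_from, deletion_to),
    }


_FIXTURES = {
    "fig1": fig1,
    "fig2": fig2,
    "fig4": fig4,
    "background_dcj": background_dcj,
}


def load_fixture(name: str):
    try:
        return _FIXTURES[name]()
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(_FIXTURES)}"
        ) from None


def identity_matching(genome_a: Genome, genome_b: Genome) -> list[tuple[str, str]]:
    """Match equal gene ids across two genomes (for renamed copies)."""
    common = genome_a.gene_ids & genome_b.gene_ids
    return sorted((g, g) for g in common)
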