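"""Gene-family integration, classification, MCL refinement and scoring.

Pairwise ortholog-sets over n genomes are integrated into an n-partite
graph whose connected components are the inferred gene families.  A family
is *ambiguous* when some genome contributes more than one gene, otherwise
*resolved*: *complete* with exactly one gene from every genome, else
*incomplete*.  Ambiguous families can be refined by Markov clustering of
their similarity-weighted subgraph.  Family sets are scored against a
reference by 2-subset (gene-pair) precision, recall and F1.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .genomes import FamilySet

AMBIGUOUS = "ambiguous"
RESOLVED_COMPLETE = "resolved-complete"
RESOLVED_INCOMPLETE = "resolved-incomplete"


class FamilyGraph:
    """n-partite graph: vertices are genes tagged by genome, edges orthologs."""

    def __init__(self, genome_of: dict[str, str]):
        self.genome_of = dict(genome_of)
        self.graph = nx.Graph()
        self.graph.add_nodes_from(self.genome_of)

    def add_ortholog_pair(self, g1: str, g2: str, sigma: float = 1.0) -> None:
        if self.genome_of[g1] == self.genome_of[g2]:
            raise ValueError(f"within-genome pair ({g1!r},{g2!r}) is not allowed")
        self.graph.add_edge(g1, g2, sigma=sigma)

    def connected_components(self) -> list[set[str]]:
        return sorted(nx.connected_components(self.graph), key=lambda c: sorted(c)[0])


@dataclass
class Family:
    genes: frozenset[str]
    family_class: str

    def __len__(self) -> int:
        return len(self.genes)


def integrate_ortholog_sets(
    pairwise: list[tuple[str, str, list[tuple[str, str, float]]]],
    genome_of: dict[str, str],
) -> FamilyGraph:
    """Union the pairwise ortholog-sets into one n-partite graph.

    ``pairwise`` holds ``(genome_id_1, genome_id_2, [(gene1, gene2, sigma)])``
    entries; every entry must be a matching between two distinct genomes.
    Genes listed in ``genome_of`` but matched nowhere stay isolated and are
    reported as unclassified singletons downstream.
    """
    fg = FamilyGraph(genome_of)
    for gid1, gid2, pairs in pairwise:
        if gid1 == gid2:
            raise ValueError(f"ortholog-set within a single genome {gid1!r}")
        seen1: set[str] = set()
        seen2: set[str] = set()
        for g1, g2, sigma in pairs:
            if genome_of.get(g1) != gid1 or genome_of.get(g2) != gid2:
                raise ValueError(f"pair ({g1!r},{g2!r}) does not span {gid1}/{gid2}")
            if g1 in seen1 or g2 in seen2:
                raise ValueError(f"gene matched twice in the {gid1}/{gid2} ortholog-set")
            seen1.add(g1)
            seen2.add(g2)
            fg.add_ortholog_pair(g1, g2, sigma)
    return fg


def classify_families(fg: FamilyGraph, n_genomes: int) -> list[Family]:
    """Label every connected component of two or more genes."""
    out: list[Family] = []
    for comp in fg.connected_components():
        if len(comp) < 2:
            continue
        genomes = [fg.genome_of[g] for g in comp]
        if len(genomes) != len(set(genomes)):
            cls = AMBIGUOUS
        elif len(set(genomes)) == n_genomes:
            cls = RESOLVED_COMPLETE
        else:
            cls = RESOLVED_INCOMPLETE
        out.append(Family(frozenset(comp), cls))
    return out


def unclassified_singletons(fg: FamilyGraph) -> set[str]:
    return {g for g in fg.graph.nodes if fg.graph.degree(g) == 0}


# ---------------------------------------------------------------------------
# Markov clustering
# ---------------------------------------------------------------------------

def markov_cluster(
    nodes: list[str],
    weights: dict[tuple[str, str], float],
    inflation: float = 1.4,
    prune: float = 1e-5,
    max_iter: int = 100,
    self_loop: str = "max",
) -> list[set[str]]:
    """Markov clustering of a small weighted graph (dense implementation).

    Alternates expansion (matrix squaring) and inflation (elementwise power
    followed by column renormalization), pruning entries below ``prune``,
    until the matrix is stable.  Clusters are read from attractor rows;
    overlapping clusters are merged.  Self-loops are added with the node's
    maximum incident weight (``self_loop="max"``), the conventional damping
    for weighted similarity graphs.
    """
    n = len(nodes)
    index = {g: i for i, g in enumerate(nodes)}
    m = np.zeros((n, n))
    for (u, v), w in weights.items():
        m[index[u], index[v]] = w
        m[index[v], index[u]] = w
    if self_loop == "max":
        loops = m.max(axis=0)
        loops[loops == 0] = 1.0
        np.fill_diagonal(m, loops)
    else:
        np.fill_diagonal(m, 1.0)

    def normalize(mat: np.ndarray) -> np.ndarray:
        sums = mat.sum(axis=0)
        sums[sums == 0] = 1.0
        return mat / sums

    m = normalize(m)
    for _ in range(max_iter):
        expanded = m @ m
        inflated = normalize(np.power(expanded, inflation))
        inflated[inflated < prune] = 0.0
        inflated = normalize(inflated)
        if np.allclose(inflated, m, atol=1e-8):
            m = inflated
            break
        m = inflated

    clusters: list[set[int]] = []
    attractors = [i for i in range(n) if m[i, i] > 0]
    for i in attractors:
        members = {j for j in range(n) if m[i, j] > 0}
        merged = False
        for cl in clusters:
            if cl & members:
                cl |= members
                merged = True
                break
        if not merged:
            clusters.append(members)
    covered = set().union(*clusters) if clusters else set()
    for j in range(n):  # nodes starved of flow become singletons
        if j not in covered:
            clusters.append({j})
    return [{nodes[j] for j in cl} for cl in clusters]


def mcl_refine(
    family: Family,
    subgraph_weights: dict[tuple[str, str], float],
    genome_of: dict[str, str],
    n_genomes: int,
    inflation: float = 1.4,
) -> list[Family]:
    """Split an ambiguous family by Markov clustering of its sigma-weighted subgraph.

    Non-ambiguous input is returned unchanged with a warning.  The union of
    the refined families always covers exactly the input genes.
    """
    if family.family_class != AMBIGUOUS:
        warnings.warn("mcl_refine called on a non-ambiguous family", stacklevel=2)
        return [family]
    nodes = sorted(family.genes)
    weights = {
        (u, v): w
        for (u, v), w in subgraph_weights.items()
        if u in family.genes and v in family.genes
    }
    clusters = markov_cluster(nodes, weights, inflation=inflation)
    out: list[Family] = []
    for cl in sorted(clusters, key=lambda c: sorted(c)[0]):
        genomes = [genome_of[g] for g in cl]
        if len(genomes) != len(set(genomes)):
            cls = AMBIGUOUS
        elif len(set(genomes)) == n_genomes:
            cls = RESOLVED_COMPLETE
        else:
            cls = RESOLVED_INCOMPLETE
        out.append(Family(frozenset(cl), cls))
    assert set().union(*(f.genes for f in out)) == family.genes
    return out


# ---------------------------------------------------------------------------
# 2-subset precision / recall
# ---------------------------------------------------------------------------

@dataclass
class HomologyMetrics:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    empty_prediction: bool = False

    def to_dict(self) -> dict:
        return {
            "TP": self.tp,
            "FP": self.fp,
            "FN": self.fn,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "empty_prediction": self.empty_prediction,
        }


def _two_subsets(families: FamilySet) -> set[frozenset[str]]:
    out: set[frozenset[str]] = set()
    for fam in families:
        for a, b in itertools.combinations(sorted(fam), 2):
            out.add(frozenset((a, b)))
    return out


def homology_pair_metrics(predicted: FamilySet, reference: FamilySet) -> HomologyMetrics:
    """2-subset precision/recall/F1 of a family set against a reference.

    Genes absent from the reference are first dropped from the predicted
    families (inferred sets routinely contain genes a curated reference
    never classified); the reference itself stays intact, so its pairs
    count as false negatives when missed.  An empty prediction pair set
    yields precision 0 with an explicit flag instead of 0/0.
    """
    h_pred = _two_subsets(predicted.restricted_to(reference.gene_universe))
    h_ref = _two_subsets(reference)
    tp = len(h_pred & h_ref)
    fp = len(h_pred - h_ref)
    fn = len(h_ref - h_pred)
    empty = len(h_pred) == 0
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    return HomologyMetrics(tp, fp, fn, precision, recall, f1, empty_prediction=empty)


def families_to_familyset(families: list[Family], label: str = "") -> FamilySet:
    return FamilySet([f.genes for f in families], label=label)
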