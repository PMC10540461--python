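"""Filtered gene similarity graph between two genomes.

Each cross-genome gene pair (x, y) is scored by its relative reciprocal
score

    sigma(x, y) = (bitscr(x->y) + bitscr(y->x)) / (bitscr(x->x) + bitscr(y->y)),

clipped to at most 1 so that edge scores and vertex weights stay in (0, 1].
Two filters discard negligible similarities:

* absolute filter ``f_eps``: sigma(x, y) >= f_eps;
* relative reciprocal filter ``f_t``: bitscr(x->y) must reach an f_t
  fraction of the best bitscore of x against any gene of the other genome,
  and symmetrically for bitscr(y->x).  The maxima are taken over raw
  bitscores, before the absolute filter.

Genes whose every similarity is filtered away remain in the graph as
isolated vertices with weight 0 -- they still occur in the gene orders and
are insertion/deletion candidates downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .genomes import BitscoreTable, Genome


@dataclass(frozen=True)
class SimilarityFilterConfig:
    """Thresholds of the similarity filter (defaults 0.1 and 0.8)."""

    f_eps: float = 0.1
    f_t: float = 0.8

    def __post_init__(self) -> None:
        for name in ("f_eps", "f_t"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must lie in (0, 1], got {v}")


def relative_reciprocal_score(
    b_xy: float, b_yx: float, b_xx: float, b_yy: float
) -> float:
    """Relative reciprocal score of a gene pair, clipped to at most 1."""
    if not (b_xx > 0 and b_yy > 0):
        raise ValueError("self bitscores must be positive")
    if not (b_xy > 0 and b_yx > 0):
        raise ValueError("reciprocal bitscores must be positive")
    return min(1.0, (b_xy + b_yx) / (b_xx + b_yy))


class GeneSimilarityGraph:
    """Weighted bipartite graph over the genes of two genomes.

    Edges carry scores sigma in (0, 1]; every vertex u carries the weight
    w(u) = max sigma over incident edges (0 if isolated).
    """

    def __init__(self, genome_a: Genome, genome_b: Genome):
        self.genome_a = genome_a
        self.genome_b = genome_b
        self.edges: dict[tuple[str, str], float] = {}
        self._adj_a: dict[str, dict[str, float]] = {g: {} for g in genome_a.gene_ids}
        self._adj_b: dict[str, dict[str, float]] = {g: {} for g in genome_b.gene_ids}

    def add_edge(self, a: str, b: str, sigma: float) -> None:
        if a not in self._adj_a or b not in self._adj_b:
            raise KeyError(f"edge ({a!r},{b!r}) references unknown genes")
        if not (0 < sigma <= 1):
            raise ValueError(f"sigma must lie in (0, 1], got {sigma}")
        self.edges[(a, b)] = sigma
        self._adj_a[a][b] = sigma
        self._adj_b[b][a] = sigma

    def sigma(self, a: str, b: str) -> float:
        return self.edges[(a, b)]

    def neighbors_a(self, a: str) -> dict[str, float]:
        return self._adj_a[a]

    def neighbors_b(self, b: str) -> dict[str, float]:
        return self._adj_b[b]

    def weight(self, gene: str) -> float:
        adj = self._adj_a.get(gene)
        if adj is None:
            adj = self._adj_b.get(gene)
        if adj is None:
            raise KeyError(gene)
        return max(adj.values(), default=0.0)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def sorted_edges(self) -> list[tuple[str, str, float]]:
        return [(a, b, s) for (a, b), s in sorted(self.edges.items())]

    def dump_edge_list(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for a, b, s in self.sorted_edges():
                fh.write(f"{a}\t{b}\t{s:.6g}\n")


def build_similarity_graph(
    genome_a: Genome,
    genome_b: Genome,
    hits: BitscoreTable,
    cfg: SimilarityFilterConfig | None = None,
) -> GeneSimilarityGraph:
    """Build the filtered gene similarity graph from a bitscore table.

    Hits referencing genes absent from both genomes are skipped with a
    warning; a gene appearing in a surviving cross-genome hit without a
    self-hit is a hard error (the score is undefined without it).
    """
    cfg = cfg or SimilarityFilterConfig()
    ids_a, ids_b = genome_a.gene_ids, genome_b.gene_ids
    graph = GeneSimilarityGraph(genome_a, genome_b)

    # raw directed bitscores restricted to the two genomes, and per-gene
    # best raw bitscore against the opposite genome (the f_t reference)
    fwd: dict[tuple[str, str], float] = {}
    rev: dict[tuple[str, str], float] = {}
    best_a: dict[str, float] = {}
    best_b: dict[str, float] = {}
    unknown: set[str] = set()
    for q, s, b in hits:
        if q == s:
            continue
        if q in ids_a and s in ids_b:
            fwd[(q, s)] = b
            if b > best_a.get(q, 0.0):
                best_a[q] = b
        elif q in ids_b and s in ids_a:
            rev[(s, q)] = b
            if b > best_b.get(q, 0.0):
                best_b[q] = b
        elif q in ids_a or q in ids_b or s in ids_a or s in ids_b:
            continue  # within-genome or mixed rows are irrelevant here
        else:
            unknown.add((q, s)[0])
    if unknown:
        warnings.warn(
            f"skipped hits referencing {len(unknown)} gene(s) absent from both genomes",
            stacklevel=2,
        )

    for (a, b), b_ab in sorted(fwd.items()):
        b_ba = rev.get((a, b))
        if b_ba is None:
            continue
        if b_ab < cfg.f_t * best_a[a] or b_ba < cfg.f_t * best_b[b]:
            continue
        b_aa = hits.self_score(a)
        b_bb = hits.self_score(b)
        if b_aa is None or b_bb is None:
            missing = a if b_aa is None else b
            raise ValueError(
                f"gene {missing!r} occurs in a cross-genome hit but has no self-hit"
            )
        sigma = relative_reciprocal_score(b_ab, b_ba, b_aa, b_bb)
        if sigma < cfg.f_eps:
            continue
        graph.add_edge(a, b, sigma)
    return graph
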