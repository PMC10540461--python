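"""Family-free relational graph, consistent decompositions and distances.

The family-free relational graph (FFR) of two genomes A and B under a gene
similarity graph S has one vertex per gene extremity (tail ``t`` and head
``h``).  Adjacency edges join consecutive extremities within a segment,
every similarity edge ab contributes the sibling pair of extremity edges
(a^t b^t, a^h b^h), and every gene contributes one indel edge between its
two extremities, weighted by the gene's similarity weight w.

A sibling-set L (pairs of siblings, no two incident) induces the consistent
decomposition D[L] = L ∪ L~ ∪ E_adj, a vertex-disjoint collection of cycles
and paths; paths end at telomeres, so every decomposition has
kappa(A) + kappa(B) paths, of types AA, BB or AB.

The DCJ-indel distance of an ortholog-set O and the weighted distance

    wd = d + |O| - sigma(O) + w(O~)

are computed from the decomposition once its paths are closed into cycles
by a capping.  For a capped decomposition made of cycles only,

    d = (|O| + p) - c + sum over cycles of lambda(C),

where p is the number of cap pairs per genome, c the number of cycles, and
lambda(C) the indel-potential of cycle C: with Lambda(C) maximal blocks of
same-genome indel edges read cyclically around C, lambda = 0 when the cycle
carries no indel edge and ceil((Lambda+1)/2) otherwise.  An optimal capping
preserves the uncapped weighted cost; both facts are exercised against an
exhaustive breadth-first operation-count oracle in the test suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Iterable, Iterator

from .genomes import FORWARD, Genome
from .similarity import GeneSimilarityGraph

Vertex = tuple[str, str, str]  # (side "A"/"B", gene_id, "t"/"h")

SIDE_A = "A"
SIDE_B = "B"


def _extremities(gene_id: str, orientation: int) -> tuple[str, str]:
    """Left and right extremity letters of an oriented gene occurrence."""
    return ("t", "h") if orientation == FORWARD else ("h", "t")


class FFRGraph:
    """The family-free relational graph of two genomes under a similarity graph."""

    def __init__(self, genome_a: Genome, genome_b: Genome, sim: GeneSimilarityGraph):
        if sim.genome_a is not genome_a or sim.genome_b is not genome_b:
            # allow equal-by-content graphs built separately
            if (
                sim.genome_a.gene_ids != genome_a.gene_ids
                or sim.genome_b.gene_ids != genome_b.gene_ids
            ):
                raise ValueError("similarity graph does not match the genomes")
        self.genome_a = genome_a
        self.genome_b = genome_b
        self.sim = sim

        self.adj_edges: dict[str, list[tuple[Vertex, Vertex]]] = {SIDE_A: [], SIDE_B: []}
        #: per side, one (left, right) telomere-vertex pair per segment, in
        #: sorted segment order (the deterministic order capping relies on)
        self.telomeres: dict[str, list[tuple[Vertex, Vertex]]] = {SIDE_A: [], SIDE_B: []}
        self.segment_order: dict[str, list[str]] = {SIDE_A: [], SIDE_B: []}
        self.indel_weight: dict[Vertex, float] = {}  # keyed by (side, gene, "t")

        for side, genome in ((SIDE_A, genome_a), (SIDE_B, genome_b)):
            for seg in sorted(genome.segments, key=lambda s: s.segment_id):
                self.segment_order[side].append(seg.segment_id)
                prev_right: Vertex | None = None
                first_left: Vertex | None = None
                for gene in seg.genes:
                    lext, rext = _extremities(gene.gene_id, gene.orientation)
                    left: Vertex = (side, gene.gene_id, lext)
                    right: Vertex = (side, gene.gene_id, rext)
                    if prev_right is not None:
                        self.adj_edges[side].append((prev_right, left))
                    else:
                        first_left = left
                    prev_right = right
                    self.indel_weight[(side, gene.gene_id, "t")] = sim.weight(
                        gene.gene_id
                    )
                assert first_left is not None and prev_right is not None
                self.telomeres[side].append((first_left, prev_right))

    # -- structural counts ------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return 2 * (self.genome_a.n_genes + self.genome_b.n_genes)

    def n_adjacency_edges(self, side: str) -> int:
        return len(self.adj_edges[side])

    @property
    def n_indel_edges(self) -> tuple[int, int]:
        return self.genome_a.n_genes, self.genome_b.n_genes

    @property
    def sibling_pairs(self) -> list[tuple[str, str, float]]:
        """One entry per similarity edge; each stands for two extremity edges."""
        return self.sim.sorted_edges()

    def all_telomere_vertices(self, side: str) -> list[Vertex]:
        out: list[Vertex] = []
        for left, right in self.telomeres[side]:
            out.extend((left, right))
        return out


class InconsistentSiblingSetError(ValueError):
    """The proposed edge set is not a valid sibling-set / matching."""


def check_matching(
    ortholog_set: Iterable[tuple[str, str]],
    genome_a: Genome,
    genome_b: Genome,
) -> list[tuple[str, str]]:
    """Validate that an ortholog-set is a matching between the two gene sets."""
    pairs = sorted(set(ortholog_set))
    seen_a: set[str] = set()
    seen_b: set[str] = set()
    for a, b in pairs:
        if a not in genome_a.gene_ids or b not in genome_b.gene_ids:
            raise InconsistentSiblingSetError(f"pair ({a!r},{b!r}) not across genomes")
        if a in seen_a or b in seen_b:
            raise InconsistentSiblingSetError(f"gene matched twice in ({a!r},{b!r})")
        seen_a.add(a)
        seen_b.add(b)
    return pairs


class SiblingSet:
    """A consistent sibling-set: for every ortholog pair, both sibling edges."""

    def __init__(self, ffr: FFRGraph, ortholog_set: Iterable[tuple[str, str]]):
        self.ffr = ffr
        self.ortholog_set = check_matching(
            ortholog_set, ffr.genome_a, ffr.genome_b
        )
        self.edges: list[tuple[Vertex, Vertex]] = []
        for a, b in self.ortholog_set:
            self.edges.append(((SIDE_A, a, "t"), (SIDE_B, b, "t")))
            self.edges.append(((SIDE_A, a, "h"), (SIDE_B, b, "h")))

    @classmethod
    def from_extremity_edges(
        cls, ffr: FFRGraph, edges: Iterable[tuple[Vertex, Vertex]]
    ) -> "SiblingSet":
        """Build from explicit extremity edges, demanding full sibling pairs."""
        pairs: dict[tuple[str, str], set[str]] = {}
        for u, v in edges:
            (sa, a, ea), (sb, b, eb) = sorted((u, v))
            if sa != SIDE_A or sb != SIDE_B or ea != eb:
                raise InconsistentSiblingSetError(f"edge {u}-{v} is not an extremity edge")
            pairs.setdefault((a, b), set()).add(ea)
        for (a, b), exts in pairs.items():
            if exts != {"t", "h"}:
                raise InconsistentSiblingSetError(
                    f"lone non-sibling edge for pair ({a!r},{b!r})"
                )
        return cls(ffr, pairs.keys())

    @property
    def size(self) -> int:
        return len(self.edges)

    def sigma(self) -> float:
        return sum(self.ffr.sim.sigma(a, b) for a, b in self.ortholog_set)

    def unmatched_genes(self) -> tuple[list[str], list[str]]:
        ma = {a for a, _ in self.ortholog_set}
        mb = {b for _, b in self.ortholog_set}
        ua = sorted(self.ffr.genome_a.gene_ids - ma)
        ub = sorted(self.ffr.genome_b.gene_ids - mb)
        return ua, ub


@dataclass
class Component:
    """One cycle or path of a decomposition."""

    kind: str  # "cycle" | "path"
    vertices: list[Vertex]
    labels: list[str]  # genome side of each indel edge, in walk order
    path_type: str | None = None  # "AA" | "BB" | "AB" for paths

    @property
    def endpoints(self) -> tuple[Vertex, Vertex]:
        if self.kind != "path":
            raise ValueError("cycles have no endpoints")
        return self.vertices[0], self.vertices[-1]


def cycle_indel_potential(labels: list[str]) -> int:
    """lambda of a cycle from its cyclic sequence of indel-edge genome labels."""
    n = len(labels)
    if n == 0:
        return 0
    transitions = sum(labels[i] != labels[i - 1] for i in range(n))
    big_lambda = transitions if transitions > 0 else 1
    return (big_lambda + 2) // 2  # ceil((Lambda + 1) / 2)


class Decomposition:
    """A consistent decomposition D[L] with its component census."""

    def __init__(self, ffr: FFRGraph, sibling_set: SiblingSet):
        self.ffr = ffr
        self.sibling_set = sibling_set
        self.components: list[Component] = []
        self._build()

    def _build(self) -> None:
        ffr = self.ffr
        adj: dict[Vertex, list[tuple[Vertex, str]]] = {}

        def add(u: Vertex, v: Vertex, kind: str) -> None:
            adj.setdefault(u, []).append((v, kind))
            adj.setdefault(v, []).append((u, kind))

        for side in (SIDE_A, SIDE_B):
            for u, v in ffr.adj_edges[side]:
                add(u, v, "adj")
        for u, v in self.sibling_set.edges:
            add(u, v, "sib")
        ua, ub = self.sibling_set.unmatched_genes()
        for side, genes in ((SIDE_A, ua), (SIDE_B, ub)):
            for g in genes:
                add((side, g, "t"), (side, g, "h"), f"id{side}")

        # ensure isolated vertices (none expected) and all extremities present
        all_vertices: list[Vertex] = []
        for side, genome in ((SIDE_A, ffr.genome_a), (SIDE_B, ffr.genome_b)):
            for g in sorted(genome.gene_ids):
                all_vertices.append((side, g, "t"))
                all_vertices.append((side, g, "h"))

        visited: set[Vertex] = set()

        def walk(start: Vertex, first: tuple[Vertex, str] | None) -> Component:
            vertices = [start]
            labels: list[str] = []
            visited.add(start)
            prev = start
            cur, kind = first if first is not None else (start, "")
            if first is None:
                return Component("path", vertices, labels)
            while True:
                if kind.startswith("id"):
                    labels.append(kind[2:])
                if cur == start:
                    return Component("cycle", vertices, labels)
                vertices.append(cur)
                visited.add(cur)
                nxt = [(v, k) for v, k in adj.get(cur, []) if v != prev]
                if not nxt:
                    return Component("path", vertices, labels)
                # degree <= 2 everywhere; a lone neighbor continues the walk
                prev = cur
                cur, kind = nxt[0]

        # paths start at degree-1 vertices (telomeres)
        for v in all_vertices:
            if v in visited:
                continue
            neigh = adj.get(v, [])
            if len(neigh) == 1:
                comp = walk(v, neigh[0])
                comp.path_type = "".join(sorted((comp.vertices[0][0], comp.vertices[-1][0])))
                self.components.append(comp)
        for v in all_vertices:
            if v not in visited:
                neigh = adj.get(v, [])
                if len(neigh) != 2:  # isolated vertex: single-vertex path
                    comp = walk(v, None)
                    comp.path_type = v[0] * 2
                    self.components.append(comp)
                    continue
                self.components.append(walk(v, neigh[0]))

    # -- census -----------------------------------------------------------
    @property
    def cycles(self) -> list[Component]:
        return [c for c in self.components if c.kind == "cycle"]

    @property
    def paths(self) -> list[Component]:
        return [c for c in self.components if c.kind == "path"]

    def census(self) -> dict[str, int]:
        out = {"cycles": len(self.cycles), "AA": 0, "BB": 0, "AB": 0}
        for p in self.paths:
            out[p.path_type] += 1
        return out

    def census_rows(self) -> list[tuple[str, int]]:
        """(component type, length) rows for a TSV export."""
        rows = []
        for c in self.components:
            label = "cycle" if c.kind == "cycle" else f"{c.path_type}-path"
            rows.append((label, len(c.vertices)))
        return rows

    def closed_cycle_cost(self) -> tuple[int, int]:
        """(number of cycles, summed indel-potential) of the pre-closed cycles."""
        lam = sum(cycle_indel_potential(c.labels) for c in self.cycles)
        return len(self.cycles), lam


def induce_decomposition(
    ffr: FFRGraph, sibling_set: SiblingSet | Iterable[tuple[str, str]]
) -> Decomposition:
    """Induce the consistent decomposition D[L] of a sibling-set.

    Accepts either a :class:`SiblingSet` or a bare ortholog-set of
    ``(gene_a, gene_b)`` pairs, which is validated and lifted to its
    sibling pairs.
    """
    if not isinstance(sibling_set, SiblingSet):
        sibling_set = SiblingSet(ffr, sibling_set)
    if sibling_set.ffr is not ffr:
        raise InconsistentSiblingSetError("sibling-set built for a different graph")
    return Decomposition(ffr, sibling_set)


def build_ffr(genome_a: Genome, genome_b: Genome, sim: GeneSimilarityGraph) -> FFRGraph:
    return FFRGraph(genome_a, genome_b, sim)


@dataclass
class DistanceReport:
    """The four terms of the weighted DCJ-indel distance."""

    d: int
    o_size: int
    sigma_o: float
    w_comp: float

    @property
    def wd(self) -> float:
        return self.d + self.o_size - self.sigma_o + self.w_comp

    def to_json(self) -> str:
        payload = asdict(self)
        payload["wd"] = self.wd
        return json.dumps(payload, sort_keys=True)


def trivial_similarity_for(
    genome_a: Genome, genome_b: Genome, ortholog_set: Iterable[tuple[str, str]]
) -> GeneSimilarityGraph:
    """A similarity graph holding exactly an ortholog-set's edges at sigma=1."""
    sim = GeneSimilarityGraph(genome_a, genome_b)
    for a, b in ortholog_set:
        sim.add_edge(a, b, 1.0)
    return sim


def dcj_indel_distance(
    genome_a: Genome,
    genome_b: Genome,
    ortholog_set: Iterable[tuple[str, str]],
) -> int:
    """Minimum number of DCJ + indel operations transforming A into B.

    Matched genes are identified; only complement genes may be inserted or
    deleted, and no gene is both deleted and (re)inserted.  Computed as the
    minimum capped-decomposition cost over all capping-sets of the optimal
    capping: enumerated exhaustively when the cap count is small, otherwise
    delegated to the MILP with the matching fixed.
    """
    pairs = check_matching(ortholog_set, genome_a, genome_b)
    sim = trivial_similarity_for(genome_a, genome_b, pairs)
    ffr = build_ffr(genome_a, genome_b, sim)
    decomp = induce_decomposition(ffr, pairs)

    from .capping import optimal_capping  # local import avoids a cycle

    capped = optimal_capping(ffr)
    if capped.p <= 3:
        from .capping import iter_capping_sets, evaluate_capping

        best = None
        for pset in iter_capping_sets(capped):
            res = evaluate_capping(capped, decomp, pset)
            if best is None or res.d < best:
                best = res.d
        assert best is not None
        return best
    from .solver import solve_capped_ffr, SolverConfig

    result = solve_capped_ffr(capped, SolverConfig(), fixed_orthologs=pairs)
    return result.report.d


def weighted_distance(
    genome_a: Genome,
    genome_b: Genome,
    sim: GeneSimilarityGraph,
    ortholog_set: Iterable[tuple[str, str]],
) -> DistanceReport:
    """Weighted rearrangement distance wd = d + |O| - sigma(O) + w(O~)."""
    pairs = check_matching(ortholog_set, genome_a, genome_b)
    for a, b in pairs:
        if (a, b) not in sim.edges:
            raise InconsistentSiblingSetError(
                f"ortholog pair ({a!r},{b!r}) is not an edge of the similarity graph"
            )
    d = dcj_indel_distance(genome_a, genome_b, pairs)
    sigma_o = sum(sim.sigma(a, b) for a, b in pairs)
    ma = {a for a, _ in pairs}
    mb = {b for _, b in pairs}
    w_comp = sum(sim.weight(g) for g in genome_a.gene_ids - ma)
    w_comp += sum(sim.weight(g) for g in genome_b.gene_ids - mb)
    return DistanceReport(d=d, o_size=len(pairs), sigma_o=sigma_o, w_comp=w_comp)


def iter_matchings(
    edges: list[tuple[str, str, float]],
) -> Iterator[list[tuple[str, str]]]:
    """All matchings (including the empty one) of a bipartite edge list."""

    def rec(i: int, used_a: set[str], used_b: set[str]) -> Iterator[list[tuple[str, str]]]:
        if i == len(edges):
            yield []
            return
        a, b, _ = edges[i]
        for rest in rec(i + 1, used_a, used_b):
            yield rest
        if a not in used_a and b not in used_b:
            used_a.add(a)
            used_b.add(b)
            for rest in rec(i + 1, used_a, used_b):
                yield [(a, b)] + rest
            used_a.discard(a)
            used_b.discard(b)

    yield from rec(0, set(), set())
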