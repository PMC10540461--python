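"""Exhaustive breadth-first oracle for the DCJ-indel operation count.

Explores the space of genome states reachable from genome A by applying
every possible DCJ (all rewirings of two adjacencies/telomeres, including
fissions and circular intermediates), every deletion of a contiguous block
of deletable genes, and every insertion of a signed arrangement of pending
target-unique genes, until genome B is reached.  Matched genes are
identified through the ortholog-set; the no-reinsertion restriction is
enforced by construction: only A-unique genes can be deleted and only
B-unique genes can be inserted, each at most once.

This module is deliberately independent of the relational-graph machinery:
it counts operations on genome states directly and serves as ground truth
for tiny instances (guarded to <= 4 genes per genome).

The search is bidirectional (inverse operations swap the roles of
deletable and insertable genes), which keeps it tractable for operation
counts up to about six.
"""

from __future__ import annotations

import itertools
from typing import Iterable, Iterator

from .genomes import Genome
from .ffr import check_matching

SignedGene = tuple[str, int]
Chromosome = tuple[str, tuple[SignedGene, ...]]  # ("L"|"C", genes)
State = tuple[Chromosome, ...]

MAX_GENES_PER_GENOME = 9


def _canonical_chromosome(kind: str, genes: tuple[SignedGene, ...]) -> Chromosome:
    rev = tuple((g, -s) for g, s in reversed(genes))
    if kind == "L":
        return ("L", min(genes, rev))
    best = None
    for seq in (genes, rev):
        for r in range(len(seq)):
            rot = seq[r:] + seq[:r]
            if best is None or rot < best:
                best = rot
    return ("C", best)


def canonical_state(chromosomes: Iterable[tuple[str, tuple[SignedGene, ...]]]) -> State:
    return tuple(sorted(_canonical_chromosome(k, g) for k, g in chromosomes if g))


def _extremity(gene: SignedGene, which: str):
    gid, sign = gene
    if which == "left":
        return (gid, "t" if sign > 0 else "h")
    return (gid, "h" if sign > 0 else "t")


def _state_to_points(state: State):
    """Adjacency (frozenset pairs) and telomere sets of a genome state."""
    adjacencies: set[frozenset] = set()
    telomeres: set = set()
    for kind, genes in state:
        pts = []
        for g in genes:
            pts.append(_extremity(g, "left"))
            pts.append(_extremity(g, "right"))
        inner = [frozenset((pts[i], pts[i + 1])) for i in range(1, len(pts) - 1, 2)]
        adjacencies.update(inner)
        if kind == "L":
            telomeres.add(pts[0])
            telomeres.add(pts[-1])
        else:
            adjacencies.add(frozenset((pts[-1], pts[0])))
    return adjacencies, telomeres


def _points_to_state(adjacencies: set, telomeres: set, genes: set) -> State:
    """Rebuild chromosomes by walking adjacencies from telomeres, then cycles."""
    nbr: dict = {}
    for adj in adjacencies:
        pair = tuple(adj)
        if len(pair) == 1:  # degenerate self-adjacency of a single-gene circle
            a = pair[0]
            nbr[a] = a
        else:
            a, b = pair
            nbr[a] = b
            nbr[b] = a

    def other_end(pt):
        gid, ext = pt
        return (gid, "h" if ext == "t" else "t")

    def gene_from_entry(pt) -> SignedGene:
        gid, ext = pt
        return (gid, 1 if ext == "t" else -1)

    used: set = set()
    chromosomes = []
    for tel in sorted(telomeres):
        if tel in used:
            continue
        seq = []
        pt = tel
        while True:
            used.add(pt)
            seq.append(gene_from_entry(pt))
            out = other_end(pt)
            used.add(out)
            nxt = nbr.get(out)
            if nxt is None:
                break
            pt = nxt
        chromosomes.append(("L", tuple(seq)))
    remaining = {(g, e) for g in genes for e in ("t", "h")} - used
    while remaining:
        pt = min(remaining)
        seq = []
        start = pt
        while True:
            used.add(pt)
            remaining.discard(pt)
            seq.append(gene_from_entry(pt))
            out = other_end(pt)
            used.add(out)
            remaining.discard(out)
            pt = nbr[out]
            if pt == start:
                break
        chromosomes.append(("C", tuple(seq)))
    return canonical_state(chromosomes)


def _genes_of(state: State) -> set[str]:
    return {g for _, genes in state for g, _ in genes}


def _dcj_successors(state: State) -> Iterator[State]:
    adjacencies, telomeres = _state_to_points(state)
    genes = _genes_of(state)
    adj_list = sorted(adjacencies, key=lambda fs: sorted(fs))
    tel_list = sorted(telomeres)

    def rebuild(new_adj, new_tel):
        return _points_to_state(set(new_adj), set(new_tel), genes)

    # two adjacencies -> two rewirings
    for p, q in itertools.combinations(adj_list, 2):
        pp, qq = sorted(p), sorted(q)
        if len(pp) < 2 or len(qq) < 2:
            continue
        (a, b), (c, d) = pp, qq
        base_adj = adjacencies - {p, q}
        for pair1, pair2 in (((a, c), (b, d)), ((a, d), (b, c))):
            yield rebuild(
                base_adj | {frozenset(pair1), frozenset(pair2)}, telomeres
            )
    # adjacency + telomere
    for p in adj_list:
        pp = sorted(p)
        if len(pp) < 2:
            continue
        a, b = pp
        for c in tel_list:
            base_adj = adjacencies - {p}
            yield rebuild(base_adj | {frozenset((a, c))}, (telomeres - {c}) | {b})
            yield rebuild(base_adj | {frozenset((b, c))}, (telomeres - {c}) | {a})
    # two telomeres -> join
    for c, d in itertools.combinations(tel_list, 2):
        yield rebuild(adjacencies | {frozenset((c, d))}, telomeres - {c, d})
    # one adjacency -> two telomeres (fission of an adjacency)
    for p in adj_list:
        pp = sorted(p)
        if len(pp) < 2:
            continue
        a, b = pp
        yield rebuild(adjacencies - {p}, telomeres | {a, b})


def _deletion_successors(state: State, deletable: set[str]) -> Iterator[State]:
    for idx, (kind, genes) in enumerate(state):
        rest = state[:idx] + state[idx + 1 :]
        n = len(genes)
        if kind == "L":
            for i in range(n):
                for j in range(i, n):
                    block = genes[i : j + 1]
                    if all(g in deletable for g, _ in block):
                        remainder = genes[:i] + genes[j + 1 :]
                        chroms = list(rest)
                        if remainder:
                            chroms.append(("L", remainder))
                        yield canonical_state(chroms)
        else:
            if all(g in deletable for g, _ in genes):
                yield canonical_state(rest)  # whole circular chromosome
            for i in range(n):
                for length in range(1, n):
                    block_idx = [(i + k) % n for k in range(length)]
                    if all(genes[k][0] in deletable for k in block_idx):
                        keep = [genes[k] for k in range(n) if k not in set(block_idx)]
                        # deleting an arc linearizes nothing: circle stays circular
                        yield canonical_state(list(rest) + [("C", tuple(keep))])


def _insertion_successors(state: State, pending: set[str]) -> Iterator[State]:
    for size in range(1, len(pending) + 1):
        for subset in itertools.combinations(sorted(pending), size):
            for perm in itertools.permutations(subset):
                for signs in itertools.product((1, -1), repeat=size):
                    block = tuple(zip(perm, signs))
                    # as a new linear chromosome
                    yield canonical_state(list(state) + [("L", block)])
                    # inside existing chromosomes
                    for idx, (kind, genes) in enumerate(state):
                        rest = state[:idx] + state[idx + 1 :]
                        positions = range(len(genes) + 1) if kind == "L" else range(len(genes))
                        for pos in positions:
                            newg = genes[:pos] + block + genes[pos:]
                            yield canonical_state(list(rest) + [(kind, newg)])


def genome_to_state(genome: Genome, relabel: dict[str, str]) -> State:
    chroms = []
    for seg in genome.segments:
        chroms.append(
            ("L", tuple((relabel[g.gene_id], g.orientation) for g in seg.genes))
        )
    return canonical_state(chroms)


def bfs_dcj_indel_distance(
    genome_a: Genome,
    genome_b: Genome,
    ortholog_set: Iterable[tuple[str, str]],
    max_ops: int = 10,
) -> int:
    """Minimum DCJ+indel operation count by bidirectional state-space search."""
    if (
        genome_a.n_genes > MAX_GENES_PER_GENOME
        or genome_b.n_genes > MAX_GENES_PER_GENOME
    ):
        raise ValueError(
            f"state-space oracle guarded to <= {MAX_GENES_PER_GENOME} genes per genome"
        )
    pairs = check_matching(ortholog_set, genome_a, genome_b)
    label_a: dict[str, str] = {}
    label_b: dict[str, str] = {}
    for k, (a, b) in enumerate(pairs):
        label_a[a] = label_b[b] = f"m{k}"
    unique_a = sorted(genome_a.gene_ids - set(label_a))
    unique_b = sorted(genome_b.gene_ids - set(label_b))
    for g in unique_a:
        label_a[g] = f"da:{g}"
    for g in unique_b:
        label_b[g] = f"ib:{g}"
    start = genome_to_state(genome_a, label_a)
    goal = genome_to_state(genome_b, label_b)
    if start == goal:
        return 0

    del_labels = {f"da:{g}" for g in unique_a}
    ins_labels = {f"ib:{g}" for g in unique_b}

    def successors(state: State, forward: bool) -> Iterator[State]:
        present = _genes_of(state)
        if forward:
            deletable = del_labels & present
            pending = ins_labels - present
        else:  # inverse operations seen from the goal side
            deletable = ins_labels & present
            pending = del_labels - present
        yield from _dcj_successors(state)
        yield from _deletion_successors(state, deletable)
        yield from _insertion_successors(state, pending)

    dist_f: dict[State, int] = {start: 0}
    dist_b: dict[State, int] = {goal: 0}
    frontier_f = [start]
    frontier_b = [goal]
    best = None
    depth_f = depth_b = 0
    while frontier_f and frontier_b:
        if best is not None and depth_f + depth_b + 1 >= best:
            break
        if depth_f + depth_b >= max_ops:
            break
        # expand the smaller frontier
        if len(frontier_f) <= len(frontier_b):
            frontier, dist, other, fwd = frontier_f, dist_f, dist_b, True
            depth_f += 1
            new_depth = depth_f
        else:
            frontier, dist, other, fwd = frontier_b, dist_b, dist_f, False
            depth_b += 1
            new_depth = depth_b
        nxt: list[State] = []
        for state in frontier:
            for succ in successors(state, fwd):
                if succ in dist:
                    continue
                dist[succ] = new_depth
                if succ in other:
                    total = new_depth + other[succ]
                    if best is None or total < best:
                        best = total
                nxt.append(succ)
        if fwd:
            frontier_f = nxt
        else:
            frontier_b = nxt
        if best is not None and best <= depth_f + depth_b:
            return best
    if best is None:
        raise RuntimeError(f"no scenario within {max_ops} operations")
    return best
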