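"""Capping of the family-free relational graph: optimal and heuristic.

Capping closes the paths of every consistent decomposition into cycles by
attaching a cap vertex to each telomere and joining caps across genomes by
cap edges; a capping-set is a perfect matching on the cap vertices.  The
*optimal* capping equalizes the two genomes with ``p = max(kappa_A,
kappa_B)`` cap pairs per side, dummy adjacencies on the smaller side, and a
complete bipartite set of ``(2p)^2`` cap edges, multiplying the search
space by ``(2p)!``.

The *heuristic* capping restricts cap edges to the ends of linear segments
that share gene content.  The shared-content graph scores segment pairs by
``Omega(A,B)`` (summed similarity between their genes), lets every vertex
keep only its tau best edges and then drops edges weaker than an epsilon
fraction of their endpoints' best surviving score, is completed into a perfect shared-content
graph by adding dummy segments along Hall violators until a perfect
matching exists, and is finally stripped of edges that lie in no perfect
matching.  Each surviving segment pair contributes the two crosswise cap
pairings (four cap edges), so a capping-set always exists (validity) while
the number of capping-sets — bounded via the Bregman–Minc permanent
inequality — collapses relative to ``(2p)!``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

from .ffr import Decomposition, FFRGraph, SIDE_A, SIDE_B, Vertex, cycle_indel_potential

Cap = tuple[str, int]  # (side, 1-based cap index)


# ---------------------------------------------------------------------------
# small bipartite-matching helpers (kept dependency-free and deterministic)
# ---------------------------------------------------------------------------

def maximum_bipartite_matching(
    left: Sequence, adj: dict
) -> dict:
    """Maximum matching via augmenting paths; returns a left->right map."""
    match_l: dict = {}
    match_r: dict = {}

    def try_augment(u, seen: set) -> bool:
        for v in adj.get(u, ()):  # adjacency lists are pre-sorted by caller
            if v in seen:
                continue
            seen.add(v)
            if v not in match_r or try_augment(match_r[v], seen):
                match_l[u] = v
                match_r[v] = u
                return True
        return False

    for u in left:
        if u not in match_l:
            try_augment(u, set())
    return match_l


def has_perfect_matching(left: Sequence, right: Sequence, adj: dict) -> bool:
    if len(left) != len(right):
        return False
    return len(maximum_bipartite_matching(left, adj)) == len(left)


def iter_perfect_matchings(
    left: Sequence, adj: dict
) -> Iterator[list[tuple]]:
    """All perfect matchings of a bipartite graph, by backtracking."""
    n = len(left)
    order = sorted(left, key=lambda u: len(adj.get(u, ())))

    def rec(i: int, used: set) -> Iterator[list[tuple]]:
        if i == n:
            yield []
            return
        u = order[i]
        for v in adj.get(u, ()):
            if v in used:
                continue
            used.add(v)
            for rest in rec(i + 1, used):
                yield [(u, v)] + rest
            used.discard(v)

    yield from rec(0, set())


# ---------------------------------------------------------------------------
# shared-content graph
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CappingConfig:
    """Heuristic-capping thresholds (defaults tau=2, eps=0.1) and mode."""

    tau: int = 2
    eps: float = 0.1
    mode: str = "heuristic"  # "optimal" | "heuristic"

    def __post_init__(self) -> None:
        if self.tau < 1:
            raise ValueError(f"tau must be >= 1, got {self.tau}")
        if not (0 < self.eps <= 1):
            raise ValueError(f"eps must lie in (0, 1], got {self.eps}")
        if self.mode not in ("optimal", "heuristic"):
            raise ValueError(f"unknown capping mode {self.mode!r}")


class SharedContentGraph:
    """Bipartite graph on linear segments scored by shared genomic content."""

    def __init__(
        self,
        segments_a: Sequence[str],
        segments_b: Sequence[str],
        edges: dict[tuple[str, str], float],
    ):
        self.segments_a = list(segments_a)
        self.segments_b = list(segments_b)
        self.edges = {k: v for k, v in edges.items() if v > 0}

    def omega(self, a: str, b: str) -> float:
        return self.edges.get((a, b), 0.0)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def incident(self, side: str, seg: str) -> list[tuple[tuple[str, str], float]]:
        pos = 0 if side == SIDE_A else 1
        return sorted(
            ((e, w) for e, w in self.edges.items() if e[pos] == seg),
            key=lambda ew: (-ew[1], ew[0]),
        )

    def dump_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for (a, b), w in sorted(self.edges.items()):
                fh.write(f"{a}\t{b}\t{w:.6g}\n")


def build_shared_content_graph(
    genome_a, genome_b, sim, cfg: CappingConfig | None = None
) -> SharedContentGraph:
    """Score segment pairs by Omega and apply the tau- and eps-filters.

    The tau-filter keeps an edge iff it ranks among the tau highest-scored
    edges of at least one endpoint, with all ties at rank tau kept; the
    eps-filter then removes, on the surviving graph, every edge weaker than
    eps times the best surviving score of either endpoint.  Both passes are
    order-independent.
    """
    cfg = cfg or CappingConfig()
    segs_a = sorted(s.segment_id for s in genome_a.segments)
    segs_b = sorted(s.segment_id for s in genome_b.segments)
    omega: dict[tuple[str, str], float] = {}
    for (a, b), s in sim.edges.items():
        key = (genome_a.segment_of(a), genome_b.segment_of(b))
        omega[key] = omega.get(key, 0.0) + s
    graph = SharedContentGraph(segs_a, segs_b, omega)

    # tau-filter: every vertex keeps only its tau best edges, so an edge
    # survives iff it ranks within tau (ties at rank tau kept) for BOTH
    # endpoints; ranks are taken on the initial graph, making the pass
    # order-independent
    keep: set[tuple[str, str]] = set(graph.edges)
    for side, segs in ((SIDE_A, segs_a), (SIDE_B, segs_b)):
        for seg in segs:
            inc = graph.incident(side, seg)
            if len(inc) > cfg.tau:
                threshold = inc[cfg.tau - 1][1]
                keep -= {e for e, w in inc if w < threshold}
    surviving = {e: w for e, w in graph.edges.items() if e in keep}

    # eps-filter on the surviving graph
    best: dict[tuple[str, str], float] = {}
    for (a, b), w in surviving.items():
        best[(SIDE_A, a)] = max(best.get((SIDE_A, a), 0.0), w)
        best[(SIDE_B, b)] = max(best.get((SIDE_B, b), 0.0), w)
    final = {
        (a, b): w
        for (a, b), w in surviving.items()
        if w >= cfg.eps * best[(SIDE_A, a)] and w >= cfg.eps * best[(SIDE_B, b)]
    }
    return SharedContentGraph(segs_a, segs_b, final)


# ---------------------------------------------------------------------------
# completion to a perfect shared-content graph
# ---------------------------------------------------------------------------

class PerfectSharedContentGraph:
    """A completed shared-content graph admitting a perfect matching.

    Dummy segments (named ``phi:<side>:<k>``) equalize deficiencies found
    along Hall violators; every remaining edge is matchable.  Dummy edges
    carry no content score and are exempt from the tau/eps filters.
    """

    def __init__(
        self,
        segments_a: Sequence[str],
        segments_b: Sequence[str],
        dummies_a: Sequence[str],
        dummies_b: Sequence[str],
        edges: set[tuple[str, str]],
    ):
        self.order_a = list(segments_a) + list(dummies_a)
        self.order_b = list(segments_b) + list(dummies_b)
        self.dummies_a = set(dummies_a)
        self.dummies_b = set(dummies_b)
        if len(self.order_a) != len(self.order_b):
            raise ValueError("partite sets must have equal cardinality")
        self.edges = set(edges)

    @property
    def p(self) -> int:
        return len(self.order_a)

    def is_dummy(self, side: str, seg: str) -> bool:
        return seg in (self.dummies_a if side == SIDE_A else self.dummies_b)

    def degree(self, side: str, seg: str) -> int:
        pos = 0 if side == SIDE_A else 1
        return sum(1 for e in self.edges if e[pos] == seg)

    def _adj(self) -> dict:
        adj: dict = {a: [] for a in self.order_a}
        for a, b in sorted(self.edges):
            adj[a].append(b)
        return adj

    def perfect_matchings(self) -> Iterator[list[tuple[str, str]]]:
        yield from iter_perfect_matchings(self.order_a, self._adj())

    def has_perfect_matching(self) -> bool:
        return has_perfect_matching(self.order_a, self.order_b, self._adj())

    def components(self) -> list[tuple[set[str], set[str]]]:
        """Connected components as (A-side segments, B-side segments)."""
        parent: dict = {}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        nodes = [(SIDE_A, a) for a in self.order_a] + [(SIDE_B, b) for b in self.order_b]
        for n in nodes:
            parent[n] = n
        for a, b in self.edges:
            ra, rb = find((SIDE_A, a)), find((SIDE_B, b))
            if ra != rb:
                parent[ra] = rb
        comps: dict = {}
        for n in nodes:
            comps.setdefault(find(n), ([], []))[0 if n[0] == SIDE_A else 1].append(n[1])
        return [(set(a), set(b)) for a, b in comps.values()]


def find_hall_violator(
    segments_side: Sequence[str],
    adj: dict[str, Sequence[str]],
    matching: dict[str, str],
    v: str,
) -> set[str]:
    """Hall violator containing the M-unsaturated vertex ``v``.

    ``adj`` maps vertices of v's side to their neighborhoods and
    ``matching`` maps the *opposite* side back to v's side.  The violator
    is v plus every same-side vertex reachable by an M-alternating path;
    when M is maximum it satisfies ``|N(S)| < |S|``.
    """
    if v in matching.values():
        raise ValueError(f"vertex {v!r} is saturated")
    s = {v}
    reached_other: set[str] = set()
    frontier = [v]
    while frontier:
        nxt: list[str] = []
        for u in frontier:
            for w in adj.get(u, ()):
                if w in reached_other:
                    continue
                reached_other.add(w)
                partner = matching.get(w)
                if partner is not None and partner not in s:
                    s.add(partner)
                    nxt.append(partner)
        frontier = nxt
    del segments_side
    return s


def neighborhood(adj: dict[str, Sequence[str]], s: Iterable[str]) -> set[str]:
    out: set[str] = set()
    for u in s:
        out.update(adj.get(u, ()))
    return out


def complete_to_perfect(graph: SharedContentGraph) -> PerfectSharedContentGraph:
    """Complete a shared-content graph into a perfect one (dummies + pruning).

    Iteratively: compute a maximum matching; while it is not perfect, take
    an unsaturated vertex, extract its Hall violator S and create
    ``|S| - |N(S)|`` dummy segments on the opposite side, each connected to
    every segment of S.  Finally remove all non-matchable edges.
    """
    segs_a = list(graph.segments_a)
    segs_b = list(graph.segments_b)
    dummies_a: list[str] = []
    dummies_b: list[str] = []
    edges: set[tuple[str, str]] = set(graph.edges)

    def adj_of(side: str) -> dict[str, list[str]]:
        pos = 0 if side == SIDE_A else 1
        order = (segs_a + dummies_a) if side == SIDE_A else (segs_b + dummies_b)
        adj: dict[str, list[str]] = {s: [] for s in order}
        for e in sorted(edges):
            adj[e[pos]].append(e[1 - pos])
        return adj

    while True:
        left = segs_a + dummies_a
        right = segs_b + dummies_b
        adj_a = adj_of(SIDE_A)
        match_ab = maximum_bipartite_matching(left, adj_a)
        saturated_b = set(match_ab.values())
        if len(match_ab) == len(left) and len(saturated_b) == len(right):
            break
        # pick a deterministic unsaturated vertex, preferring side A
        unsat_a = [s for s in left if s not in match_ab]
        if unsat_a:
            side, v = SIDE_A, unsat_a[0]
            adj = adj_a
            matching_back = {b: a for a, b in match_ab.items()}
        else:
            side, v = SIDE_B, next(s for s in right if s not in saturated_b)
            adj = adj_of(SIDE_B)
            matching_back = dict(match_ab)  # maps A-side back from B-side view
        violator = find_hall_violator([], adj, matching_back, v)
        deficiency = len(violator) - len(neighborhood(adj, violator))
        assert deficiency >= 1, "maximum matching left no Hall violator"
        for _ in range(deficiency):
            if side == SIDE_A:
                name = f"phi:B:{len(dummies_b) + 1}"
                dummies_b.append(name)
                edges.update((s, name) for s in violator)
            else:
                name = f"phi:A:{len(dummies_a) + 1}"
                dummies_a.append(name)
                edges.update((name, s) for s in violator)

    completed = PerfectSharedContentGraph(segs_a, segs_b, dummies_a, dummies_b, edges)
    return prune_non_matchable(completed)


def prune_non_matchable(graph: PerfectSharedContentGraph) -> PerfectSharedContentGraph:
    """Keep exactly the edges that belong to some perfect matching.

    Standard construction: fix one perfect matching M, orient matched edges
    A->B and unmatched edges B->A; an edge is matchable iff it is in M or
    its endpoints lie on a common directed cycle (same strongly connected
    component).
    """
    adj = graph._adj()
    match_ab = maximum_bipartite_matching(graph.order_a, adj)
    if len(match_ab) != graph.p:
        raise ValueError("graph admits no perfect matching")
    # Tarjan-free iterative Kosaraju on the oriented graph
    succ: dict = {}
    for a, b in graph.edges:
        na, nb = (SIDE_A, a), (SIDE_B, b)
        if match_ab.get(a) == b:
            succ.setdefault(na, []).append(nb)
        else:
            succ.setdefault(nb, []).append(na)
    nodes = [(SIDE_A, a) for a in graph.order_a] + [(SIDE_B, b) for b in graph.order_b]
    comp = _scc(nodes, succ)
    kept = {
        (a, b)
        for a, b in graph.edges
        if match_ab.get(a) == b or comp[(SIDE_A, a)] == comp[(SIDE_B, b)]
    }
    return PerfectSharedContentGraph(
        [s for s in graph.order_a if s not in graph.dummies_a],
        [s for s in graph.order_b if s not in graph.dummies_b],
        [s for s in graph.order_a if s in graph.dummies_a],
        [s for s in graph.order_b if s in graph.dummies_b],
        kept,
    )


def _scc(nodes: list, succ: dict) -> dict:
    """Strongly connected components (iterative Tarjan); node -> comp id."""
    index: dict = {}
    low: dict = {}
    on_stack: set = set()
    stack: list = []
    comp: dict = {}
    counter = itertools.count()
    comp_counter = itertools.count()

    for root in nodes:
        if root in index:
            continue
        work = [(root, iter(succ.get(root, ())))]
        index[root] = low[root] = next(counter)
        stack.append(root)
        on_stack.add(root)
        while work:
            node, it = work[-1]
            advanced = False
            for child in it:
                if child not in index:
                    index[child] = low[child] = next(counter)
                    stack.append(child)
                    on_stack.add(child)
                    work.append((child, iter(succ.get(child, ()))))
                    advanced = True
                    break
                elif child in on_stack:
                    low[node] = min(low[node], index[child])
            if advanced:
                continue
            work.pop()
            if low[node] == index[node]:
                cid = next(comp_counter)
                while True:
                    w = stack.pop()
                    on_stack.discard(w)
                    comp[w] = cid
                    if w == node:
                        break
            if work:
                parent = work[-1][0]
                low[parent] = min(low[parent], low[node])
    return comp


# ---------------------------------------------------------------------------
# capped family-free relational graph
# ---------------------------------------------------------------------------

@dataclass
class CappedFFRGraph:
    """An FFR graph extended with cap vertices, dummy adjacencies, cap edges."""

    ffr: FFRGraph
    mode: str
    p: int
    telomere_to_cap: dict[Vertex, Cap]
    cap_to_telomere: dict[Cap, Vertex | None]
    dummy_adjacencies: dict[str, list[tuple[Cap, Cap]]]
    #: None means the complete bipartite set (optimal capping)
    cap_edge_set: set[tuple[int, int]] | None
    shared_content: PerfectSharedContentGraph | None = None
    _cap_components: list[tuple[set[int], set[int]]] | None = field(
        default=None, repr=False
    )

    @property
    def n_cap_vertices_per_side(self) -> int:
        return 2 * self.p

    @property
    def n_cap_edges(self) -> int:
        if self.cap_edge_set is None:
            return (2 * self.p) ** 2
        return len(self.cap_edge_set)

    def has_cap_edge(self, i: int, j: int) -> bool:
        if self.cap_edge_set is None:
            return 1 <= i <= 2 * self.p and 1 <= j <= 2 * self.p
        return (i, j) in self.cap_edge_set

    def cap_edges(self) -> list[tuple[int, int]]:
        if self.cap_edge_set is None:
            rng = range(1, 2 * self.p + 1)
            return [(i, j) for i in rng for j in rng]
        return sorted(self.cap_edge_set)

    def cap_adjacency(self) -> dict[int, list[int]]:
        adj: dict[int, list[int]] = {i: [] for i in range(1, 2 * self.p + 1)}
        for i, j in self.cap_edges():
            adj[i].append(j)
        return adj

    def is_valid(self) -> bool:
        """Lemma-1 validity: a capping-set (perfect matching on caps) exists."""
        rng = list(range(1, 2 * self.p + 1))
        return has_perfect_matching(rng, rng, self.cap_adjacency())

    def search_space_report(self) -> dict:
        report = {
            "mode": self.mode,
            "p": self.p,
            "n_cap_edges": self.n_cap_edges,
        }
        if self.cap_edge_set is None:
            report["capping_sets"] = f"({2 * self.p})!"
            report["capping_sets_log10"] = math.lgamma(2 * self.p + 1) / math.log(10)
        else:
            bound = capping_search_space_bound(self)
            report.update(bound)
        if self.shared_content is not None:
            report["n_components"] = len(self.shared_content.components())
        return report


def _assign_caps(
    ffr: FFRGraph, side: str, order: list[str], n_dummies: int, p: int
) -> tuple[dict[Vertex, Cap], dict[Cap, Vertex | None], list[tuple[Cap, Cap]]]:
    """Wire telomeres to caps 2i-1/2i per segment; pair leftover caps as dummies."""
    seg_pos = {seg: i + 1 for i, seg in enumerate(ffr.segment_order[side])}
    tel_to_cap: dict[Vertex, Cap] = {}
    cap_to_tel: dict[Cap, Vertex | None] = {}
    for seg_idx, (left, right) in enumerate(ffr.telomeres[side]):
        seg_id = ffr.segment_order[side][seg_idx]
        i = seg_pos[seg_id]
        for cap_i, tel in (((side, 2 * i - 1), left), ((side, 2 * i), right)):
            tel_to_cap[tel] = cap_i
            cap_to_tel[cap_i] = tel
    kappa = len(ffr.telomeres[side])
    dummies: list[tuple[Cap, Cap]] = []
    for k in range(n_dummies):
        i = kappa + 1 + k
        c1, c2 = (side, 2 * i - 1), (side, 2 * i)
        cap_to_tel[c1] = None
        cap_to_tel[c2] = None
        dummies.append((c1, c2))
    assert kappa + n_dummies == p
    del order
    return tel_to_cap, cap_to_tel, dummies


def optimal_capping(ffr: FFRGraph, *_ignored) -> CappedFFRGraph:
    """Steps of the optimal capping: complete bipartite cap edges.

    ``p = max(kappa_A, kappa_B)`` cap pairs per side; the smaller genome
    receives ``p - kappa`` dummy adjacencies, paired deterministically by
    index; all ``2p x 2p`` cap edges are present, hence ``(2p)!``
    capping-sets.
    """
    ka, kb = ffr.genome_a.kappa, ffr.genome_b.kappa
    p = max(ka, kb)
    t2c_a, c2t_a, dum_a = _assign_caps(ffr, SIDE_A, ffr.segment_order[SIDE_A], p - ka, p)
    t2c_b, c2t_b, dum_b = _assign_caps(ffr, SIDE_B, ffr.segment_order[SIDE_B], p - kb, p)
    return CappedFFRGraph(
        ffr=ffr,
        mode="optimal",
        p=p,
        telomere_to_cap={**t2c_a, **t2c_b},
        cap_to_telomere={**c2t_a, **c2t_b},
        dummy_adjacencies={SIDE_A: dum_a, SIDE_B: dum_b},
        cap_edge_set=None,
    )


def heuristic_capping(
    ffr: FFRGraph, c_hat: PerfectSharedContentGraph
) -> CappedFFRGraph:
    """Capping induced by a perfect shared-content graph.

    Real segments keep their two caps; each dummy segment becomes a dummy
    adjacency between its two caps.  Every edge AB of the perfect
    shared-content graph contributes the two crosswise cap pairings (four
    cap edges), except an edge forming a complete two-vertex component with
    a dummy endpoint, whose two pairings are equivalent — only one is kept.
    """
    if not c_hat.has_perfect_matching():
        raise ValueError("shared-content graph admits no perfect matching")
    real_a = [s for s in c_hat.order_a if s not in c_hat.dummies_a]
    real_b = [s for s in c_hat.order_b if s not in c_hat.dummies_b]
    if real_a != ffr.segment_order[SIDE_A] or real_b != ffr.segment_order[SIDE_B]:
        raise ValueError("segment order of the shared-content graph mismatches the FFR")
    p = c_hat.p
    t2c_a, c2t_a, dum_a = _assign_caps(
        ffr, SIDE_A, real_a, p - len(real_a), p
    )
    t2c_b, c2t_b, dum_b = _assign_caps(
        ffr, SIDE_B, real_b, p - len(real_b), p
    )
    pos_a = {seg: i + 1 for i, seg in enumerate(c_hat.order_a)}
    pos_b = {seg: i + 1 for i, seg in enumerate(c_hat.order_b)}
    cap_edges: set[tuple[int, int]] = set()
    for a, b in sorted(c_hat.edges):
        i, j = pos_a[a], pos_b[b]
        straight = [(2 * i - 1, 2 * j - 1), (2 * i, 2 * j)]
        crosswise = [(2 * i - 1, 2 * j), (2 * i, 2 * j - 1)]
        lone_component = c_hat.degree(SIDE_A, a) == 1 and c_hat.degree(SIDE_B, b) == 1
        involves_dummy = c_hat.is_dummy(SIDE_A, a) or c_hat.is_dummy(SIDE_B, b)
        if lone_component and involves_dummy:
            cap_edges.update(straight)  # the two pairings are equivalent
        else:
            cap_edges.update(straight)
            cap_edges.update(crosswise)
    return CappedFFRGraph(
        ffr=ffr,
        mode="heuristic",
        p=p,
        telomere_to_cap={**t2c_a, **t2c_b},
        cap_to_telomere={**c2t_a, **c2t_b},
        dummy_adjacencies={SIDE_A: dum_a, SIDE_B: dum_b},
        cap_edge_set=cap_edges,
        shared_content=c_hat,
    )


def induced_capping(
    ffr: FFRGraph, segment_edges: Iterable[tuple[str, str]]
) -> CappedFFRGraph:
    """Capping induced by a bare, possibly deficient segment graph.

    Used to study validity: no dummy segments are added and no perfect
    matching is demanded, so the result may be invalid.
    """
    ka, kb = ffr.genome_a.kappa, ffr.genome_b.kappa
    if ka != kb:
        raise ValueError("induced capping needs equal segment counts")
    p = ka
    t2c_a, c2t_a, dum_a = _assign_caps(ffr, SIDE_A, ffr.segment_order[SIDE_A], 0, p)
    t2c_b, c2t_b, dum_b = _assign_caps(ffr, SIDE_B, ffr.segment_order[SIDE_B], 0, p)
    pos_a = {seg: i + 1 for i, seg in enumerate(ffr.segment_order[SIDE_A])}
    pos_b = {seg: i + 1 for i, seg in enumerate(ffr.segment_order[SIDE_B])}
    cap_edges: set[tuple[int, int]] = set()
    for a, b in segment_edges:
        i, j = pos_a[a], pos_b[b]
        cap_edges.update(
            [(2 * i - 1, 2 * j - 1), (2 * i, 2 * j), (2 * i - 1, 2 * j), (2 * i, 2 * j - 1)]
        )
    return CappedFFRGraph(
        ffr=ffr,
        mode="heuristic",
        p=p,
        telomere_to_cap={**t2c_a, **t2c_b},
        cap_to_telomere={**c2t_a, **c2t_b},
        dummy_adjacencies={SIDE_A: dum_a, SIDE_B: dum_b},
        cap_edge_set=cap_edges,
    )


# ---------------------------------------------------------------------------
# evaluation of a capping-set on a decomposition
# ---------------------------------------------------------------------------

@dataclass
class CapEvaluation:
    """Cost terms of one capped decomposition."""

    d: int
    n_cycles: int
    lam_total: int
    paths_per_cap_cycle: list[int]

    @property
    def max_paths_linked(self) -> int:
        return max(self.paths_per_cap_cycle, default=0)


def evaluate_capping(
    capped: CappedFFRGraph,
    decomp: Decomposition,
    capping_set: Iterable[tuple[int, int]],
) -> CapEvaluation:
    """Cost of the capped decomposition D^[L, P] for a given capping-set P.

    Walks the cap-level cycle structure: caps are linked pairwise either
    through a path of the decomposition, through a dummy adjacency, or
    through a cap edge of P; indel-run labels are concatenated in walk
    order to evaluate each cycle's indel-potential.
    """
    p = capped.p
    pairs = list(capping_set)
    if len(pairs) != 2 * p:
        raise ValueError("capping-set must match all cap vertices")
    pa = [i for i, _ in pairs]
    pb = [j for _, j in pairs]
    if sorted(pa) != list(range(1, 2 * p + 1)) or sorted(pb) != list(range(1, 2 * p + 1)):
        raise ValueError("capping-set is not a perfect matching on cap vertices")
    for i, j in pairs:
        if not capped.has_cap_edge(i, j):
            raise ValueError(f"capping-set uses absent cap edge ({i},{j})")

    partner: dict[Cap, Cap] = {}
    for i, j in pairs:
        partner[(SIDE_A, i)] = (SIDE_B, j)
        partner[(SIDE_B, j)] = (SIDE_A, i)

    # structural link of each cap: through a decomposition path or a dummy
    link: dict[Cap, tuple[Cap, tuple[str, ...], bool]] = {}
    for comp in decomp.paths:
        v1, v2 = comp.endpoints
        c1 = capped.telomere_to_cap[v1]
        c2 = capped.telomere_to_cap[v2]
        link[c1] = (c2, tuple(comp.labels), True)
        link[c2] = (c1, tuple(reversed(comp.labels)), True)
    for side in (SIDE_A, SIDE_B):
        for c1, c2 in capped.dummy_adjacencies[side]:
            link[c1] = (c2, (), False)
            link[c2] = (c1, (), False)

    n_closed, lam_closed = decomp.closed_cycle_cost()
    visited: set[Cap] = set()
    n_cap_cycles = 0
    lam_cap = 0
    paths_per_cycle: list[int] = []
    for start in sorted(link):
        if start in visited:
            continue
        labels: list[str] = []
        n_paths = 0
        cap = start
        while True:
            visited.add(cap)
            other, lab, is_path = link[cap]
            labels.extend(lab)
            n_paths += is_path
            visited.add(other)
            cap = partner[other]
            if cap == start:
                break
        n_cap_cycles += 1
        lam_cap += cycle_indel_potential(labels)
        paths_per_cycle.append(n_paths)

    n_star = len(decomp.sibling_set.ortholog_set) + p
    c = n_closed + n_cap_cycles
    lam_total = lam_closed + lam_cap
    return CapEvaluation(
        d=n_star - c + lam_total,
        n_cycles=c,
        lam_total=lam_total,
        paths_per_cap_cycle=paths_per_cycle,
    )


def iter_capping_sets(capped: CappedFFRGraph) -> Iterator[list[tuple[int, int]]]:
    """All capping-sets (perfect matchings on cap vertices within E_theta)."""
    n = 2 * capped.p
    if capped.cap_edge_set is None:
        for perm in itertools.permutations(range(1, n + 1)):
            yield [(i + 1, perm[i]) for i in range(n)]
    else:
        adj = capped.cap_adjacency()
        yield from iter_perfect_matchings(list(range(1, n + 1)), adj)


def min_capping_cost(
    capped: CappedFFRGraph, decomp: Decomposition
) -> tuple[CapEvaluation, list[tuple[int, int]]]:
    """Exhaustive minimum over capping-sets (tiny instances only)."""
    best: tuple[CapEvaluation, list[tuple[int, int]]] | None = None
    for pset in iter_capping_sets(capped):
        res = evaluate_capping(capped, decomp, pset)
        if best is None or res.d < best[0].d:
            best = (res, pset)
    if best is None:
        raise ValueError("capping admits no capping-set (invalid capping)")
    return best


# ---------------------------------------------------------------------------
# search-space accounting
# ---------------------------------------------------------------------------

def bregman_minc_bound(row_degrees: Sequence[int]) -> float:
    """Bregman–Minc upper bound on the permanent: prod (r_i!)^(1/r_i)."""
    bound = 1.0
    for r in row_degrees:
        if r == 0:
            return 0.0
        bound *= math.factorial(r) ** (1.0 / r)
    return bound


def permanent(matrix: Sequence[Sequence[int]]) -> int:
    """Exact 0/1 permanent by expansion with memoized column masks (n <= 12)."""
    n = len(matrix)
    if n > 12:
        raise ValueError("exact permanent guarded to n <= 12")
    rows = [sum(1 << j for j, v in enumerate(row) if v) for row in matrix]
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def rec(i: int, used: int) -> int:
        if i == n:
            return 1
        total = 0
        avail = rows[i] & ~used
        while avail:
            bit = avail & -avail
            avail ^= bit
            total += rec(i + 1, used | bit)
        return total

    return rec(0, 0)


def factorial_display(value: float) -> str:
    """Largest k with k! <= value, formatted like the field reports it."""
    if value < 1:
        return "0!"
    k = 1
    while math.factorial(k + 1) <= value:
        k += 1
    return f"~{k}!"


def capping_search_space_bound(
    source: CappedFFRGraph | PerfectSharedContentGraph,
) -> dict:
    """Bregman–Minc bound (and small-case exact count) on capping-sets.

    The count of capping-sets equals the permanent of the cap-edge
    biadjacency matrix; its Bregman–Minc bound uses the cap row degrees.
    """
    if isinstance(source, CappedFFRGraph):
        n = 2 * source.p
        adj = source.cap_adjacency()
        matrix = [
            [1 if j in adj[i] else 0 for j in range(1, n + 1)] for i in range(1, n + 1)
        ]
    else:
        if len(source.order_a) != len(source.order_b):
            raise ValueError("graph must be square")
        n = source.p
        pos_b = {seg: j for j, seg in enumerate(source.order_b)}
        matrix = [[0] * n for _ in range(n)]
        for i, a in enumerate(source.order_a):
            for aa, bb in source.edges:
                if aa == a:
                    matrix[i][pos_b[bb]] = 1
    degrees = [sum(row) for row in matrix]
    bound = bregman_minc_bound(degrees)
    out = {"bound": bound, "bound_display": factorial_display(bound)}
    if n <= 12:
        out["exact"] = permanent(matrix)
    return out
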