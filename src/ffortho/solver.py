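"""MILP and exhaustive solvers for the capped family-free relational graph.

The optimization jointly chooses a sibling-set L (equivalently an
ortholog-set O, a matching in the similarity graph) and a capping-set P
(a perfect matching on cap vertices within the cap edges) minimizing the
weighted distance

    wd = d + |O| - sigma(O) + w(O~),
    d  = (|O| + p) - c + sum_C lambda(C).

The MILP linearizes the cycle terms in the standard way: every vertex
carries a potential y_v <= index(v) forced equal around each selected
cycle and forced to 0 on cycles traversing an indel edge, so a binary
z_v with index(v) * z_v <= y_v can score exactly one unit per indel-free
cycle; indel runs are charged through binary genome labels r_v fixed at
indel-edge endpoints, paying one transition t_e wherever the label flips
along a selected edge.  With those pieces,

    d = (|O| + p) - (# indel-free cycles) + (1/2) sum_e t_e,

which equals the lambda form above.  The backend is the HiGHS solver
behind :func:`scipy.optimize.milp`; ties between equally optimal
ortholog-sets are broken toward the lexicographically smallest edge list
by an epsilon-weighted secondary objective.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import LinearConstraint, milp

from .capping import (
    CappedFFRGraph,
    CappingConfig,
    build_shared_content_graph,
    complete_to_perfect,
    evaluate_capping,
    heuristic_capping,
    min_capping_cost,
    optimal_capping,
)
from .ffr import (
    Decomposition,
    DistanceReport,
    SIDE_A,
    SIDE_B,
    SiblingSet,
    build_ffr,
    induce_decomposition,
    iter_matchings,
)
from .genomes import Genome
from .similarity import SimilarityFilterConfig, build_similarity_graph

TIE_BREAK_MASS = 1e-7


@dataclass(frozen=True)
class SolverConfig:
    """MILP backend settings; defaults follow the tool's operating points."""

    backend: str = "highs"
    time_limit_min: float = 60.0
    threads: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.time_limit_min <= 0:
            raise ValueError("time_limit must be positive")


@dataclass
class SolveResult:
    ortholog_set: list[tuple[str, str]]
    capping_set: list[tuple[int, int]]
    report: DistanceReport
    status: str  # "optimal" | "feasible-at-timeout" | "infeasible"
    objective: float = float("nan")
    extra: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "status": self.status,
            "orthologs": [list(p) for p in self.ortholog_set],
            "capping_set": [list(p) for p in self.capping_set],
            "d": self.report.d,
            "o_size": self.report.o_size,
            "sigma_o": self.report.sigma_o,
            "w_comp": self.report.w_comp,
            "wd": self.report.wd,
        }


class _Model:
    """Sparse MILP assembly for one capped FFR graph."""

    def __init__(self, capped: CappedFFRGraph):
        self.capped = capped
        ffr = capped.ffr
        self.sim_edges = ffr.sim.sorted_edges()
        self.genes = [(SIDE_A, g) for g in sorted(ffr.genome_a.gene_ids)] + [
            (SIDE_B, g) for g in sorted(ffr.genome_b.gene_ids)
        ]
        self.cap_edge_list = capped.cap_edges()

        vertices = []
        for side, genome in ((SIDE_A, ffr.genome_a), (SIDE_B, ffr.genome_b)):
            for g in sorted(genome.gene_ids):
                vertices.append((side, g, "t"))
                vertices.append((side, g, "h"))
        for side in (SIDE_A, SIDE_B):
            for i in range(1, 2 * capped.p + 1):
                vertices.append((side, "@cap", str(i)))
        self.vertices = vertices
        self.vidx = {v: i + 1 for i, v in enumerate(vertices)}  # 1-based

        # graph edges: (u, v, kind, ref) with kind in fixed/sib/indel/cap
        edges = []
        for side in (SIDE_A, SIDE_B):
            for u, v in ffr.adj_edges[side]:
                edges.append((u, v, "fixed", None))
            for (c1s, c1i), (c2s, c2i) in capped.dummy_adjacencies[side]:
                edges.append(
                    ((c1s, "@cap", str(c1i)), (c2s, "@cap", str(c2i)), "fixed", None)
                )
        for tel, (side, i) in sorted(capped.telomere_to_cap.items()):
            edges.append((tel, (side, "@cap", str(i)), "fixed", None))
        for k, (a, b, _s) in enumerate(self.sim_edges):
            edges.append(((SIDE_A, a, "t"), (SIDE_B, b, "t"), "sib", k))
            edges.append(((SIDE_A, a, "h"), (SIDE_B, b, "h"), "sib", k))
        for gi, (side, g) in enumerate(self.genes):
            edges.append(((side, g, "t"), (side, g, "h"), "indel", gi))
        for ei, (i, j) in enumerate(self.cap_edge_list):
            edges.append(
                ((SIDE_A, "@cap", str(i)), (SIDE_B, "@cap", str(j)), "cap", ei)
            )
        self.edges = edges

        # variable layout
        self.nx = len(self.sim_edges)
        self.nu = len(self.genes)
        self.nq = len(self.cap_edge_list)
        self.nv = len(vertices)
        self.ne = len(edges)
        self.off_x = 0
        self.off_u = self.nx
        self.off_q = self.off_u + self.nu
        self.off_z = self.off_q + self.nq
        self.off_r = self.off_z + self.nv
        self.off_t = self.off_r + self.nv
        self.off_y = self.off_t + self.ne
        self.n_vars = self.off_y + self.nv

    def build(self, fixed_orthologs: set[tuple[str, str]] | None):
        capped, ffr = self.capped, self.capped.ffr
        big = float(self.nv)
        rows: list[int] = []
        cols: list[int] = []
        vals: list[float] = []
        lo: list[float] = []
        hi: list[float] = []
        row = 0

        def add(entries: Sequence[tuple[int, float]], lb: float, ub: float) -> None:
            nonlocal row
            for c, v in entries:
                rows.append(row)
                cols.append(c)
                vals.append(v)
            lo.append(lb)
            hi.append(ub)
            row += 1

        # (1) per-gene degree: sum of incident similarity edges + indel = 1
        incident: dict[tuple[str, str], list[int]] = {g: [] for g in self.genes}
        for k, (a, b, _s) in enumerate(self.sim_edges):
            incident[(SIDE_A, a)].append(k)
            incident[(SIDE_B, b)].append(k)
        for gi, g in enumerate(self.genes):
            entries = [(self.off_x + k, 1.0) for k in incident[g]]
            entries.append((self.off_u + gi, 1.0))
            add(entries, 1.0, 1.0)

        # (2) cap-vertex degree: exactly one incident cap edge
        inc_cap: dict[tuple[str, int], list[int]] = {}
        for ei, (i, j) in enumerate(self.cap_edge_list):
            inc_cap.setdefault((SIDE_A, i), []).append(ei)
            inc_cap.setdefault((SIDE_B, j), []).append(ei)
        for side in (SIDE_A, SIDE_B):
            for i in range(1, 2 * capped.p + 1):
                eids = inc_cap.get((side, i), [])
                if not eids:
                    raise ValueError(
                        f"invalid capping: cap vertex ({side},{i}) has no cap edge"
                    )
                add([(self.off_q + e, 1.0) for e in eids], 1.0, 1.0)

        # (3)+(5) per graph edge: potential propagation and label transitions
        for ei, (u, v, kind, ref) in enumerate(self.edges):
            yu, yv = self.off_y + self.vidx[u] - 1, self.off_y + self.vidx[v] - 1
            ru, rv = self.off_r + self.vidx[u] - 1, self.off_r + self.vidx[v] - 1
            te = self.off_t + ei
            if kind == "fixed":
                add([(yu, 1.0), (yv, -1.0)], 0.0, 0.0)
                add([(ru, 1.0), (rv, -1.0), (te, -1.0)], -np.inf, 0.0)
                add([(rv, 1.0), (ru, -1.0), (te, -1.0)], -np.inf, 0.0)
            elif kind in ("sib", "cap"):
                sel = (self.off_x + ref) if kind == "sib" else (self.off_q + ref)
                add([(yu, 1.0), (yv, -1.0), (sel, big)], -np.inf, big)
                add([(yv, 1.0), (yu, -1.0), (sel, big)], -np.inf, big)
                add([(ru, 1.0), (rv, -1.0), (te, -1.0), (sel, 1.0)], -np.inf, 1.0)
                add([(rv, 1.0), (ru, -1.0), (te, -1.0), (sel, 1.0)], -np.inf, 1.0)
            else:  # indel edge: kill the cycle potential, pin the labels
                ug = self.off_u + ref
                side = self.genes[ref][0]
                add([(yu, 1.0), (ug, big)], -np.inf, big)
                add([(yv, 1.0), (ug, big)], -np.inf, big)
                if side == SIDE_A:  # label 0
                    add([(ru, 1.0), (ug, 1.0)], -np.inf, 1.0)
                    add([(rv, 1.0), (ug, 1.0)], -np.inf, 1.0)
                else:  # label 1
                    add([(ru, -1.0), (ug, 1.0)], -np.inf, 0.0)
                    add([(rv, -1.0), (ug, 1.0)], -np.inf, 0.0)

        # (6) cycle counters: index(v) * z_v <= y_v
        for v in self.vertices:
            i = self.vidx[v]
            add(
                [(self.off_z + i - 1, float(i)), (self.off_y + i - 1, -1.0)],
                -np.inf,
                0.0,
            )

        a_mat = sparse.csr_matrix(
            (vals, (rows, cols)), shape=(row, self.n_vars)
        )
        constraints = LinearConstraint(a_mat, np.array(lo), np.array(hi))

        # objective
        c = np.zeros(self.n_vars)
        for k, (_a, _b, s) in enumerate(self.sim_edges):
            c[self.off_x + k] = 2.0 - s + TIE_BREAK_MASS * (k + 1) / (self.nx + 1)
        for gi, (side, g) in enumerate(self.genes):
            c[self.off_u + gi] = ffr.sim.weight(g)
        c[self.off_z : self.off_z + self.nv] = -1.0
        c[self.off_t : self.off_t + self.ne] = 0.5

        integrality = np.zeros(self.n_vars)
        integrality[: self.off_z + self.nv] = 1  # x, u, q, z binary
        integrality[self.off_r : self.off_r + self.nv] = 1  # r binary

        lb = np.zeros(self.n_vars)
        ub = np.ones(self.n_vars)
        ub[self.off_t : self.off_t + self.ne] = 2.0
        for v in self.vertices:
            i = self.vidx[v]
            ub[self.off_y + i - 1] = float(i)
        if fixed_orthologs is not None:
            for k, (a, b, _s) in enumerate(self.sim_edges):
                val = 1.0 if (a, b) in fixed_orthologs else 0.0
                lb[self.off_x + k] = ub[self.off_x + k] = val
        return constraints, c, integrality, lb, ub


def solve_capped_ffr(
    capped: CappedFFRGraph,
    cfg: SolverConfig | None = None,
    fixed_orthologs: Iterable[tuple[str, str]] | None = None,
) -> SolveResult:
    """Solve the joint ortholog/capping optimization on a capped FFR graph.

    With ``fixed_orthologs`` the matching is pinned and only the capping is
    optimized, which evaluates the DCJ-indel distance of a given
    ortholog-set.
    """
    cfg = cfg or SolverConfig()
    if not capped.is_valid():
        raise ValueError("capping admits no capping-set (invalid capping)")
    model = _Model(capped)
    fixed = set(fixed_orthologs) if fixed_orthologs is not None else None
    constraints, c, integrality, lb, ub = model.build(fixed)
    from scipy.optimize import Bounds

    res = milp(
        c=c,
        constraints=constraints,
        integrality=integrality,
        bounds=Bounds(lb, ub),
        options={"time_limit": cfg.time_limit_min * 60.0, "disp": False},
    )
    if res.x is None:
        if res.status == 2:
            return SolveResult([], [], DistanceReport(0, 0, 0.0, 0.0), "infeasible")
        raise RuntimeError(f"MILP terminated without incumbent: {res.message}")
    status = "optimal" if res.status == 0 else "feasible-at-timeout"
    x = res.x
    orthologs = [
        (a, b)
        for k, (a, b, _s) in enumerate(model.sim_edges)
        if x[model.off_x + k] > 0.5
    ]
    capping_set = [
        model.cap_edge_list[ei]
        for ei in range(model.nq)
        if x[model.off_q + ei] > 0.5
    ]
    # recompute the exact integer cost from the selected decomposition
    decomp = induce_decomposition(capped.ffr, orthologs)
    ev = evaluate_capping(capped, decomp, capping_set)
    sim = capped.ffr.sim
    sigma_o = sum(sim.sigma(a, b) for a, b in orthologs)
    ma = {a for a, _ in orthologs}
    mb = {b for _, b in orthologs}
    w_comp = sum(sim.weight(g) for g in capped.ffr.genome_a.gene_ids - ma)
    w_comp += sum(sim.weight(g) for g in capped.ffr.genome_b.gene_ids - mb)
    report = DistanceReport(d=ev.d, o_size=len(orthologs), sigma_o=sigma_o, w_comp=w_comp)
    return SolveResult(
        ortholog_set=sorted(orthologs),
        capping_set=sorted(capping_set),
        report=report,
        status=status,
        objective=float(res.fun) + capped.p,
        extra={"milp_status": int(res.status)},
    )


MAX_EXHAUSTIVE_SIM_EDGES = 8
MAX_EXHAUSTIVE_P = 3


def exhaustive_solve(capped: CappedFFRGraph) -> SolveResult:
    """Enumerate every sibling-set and capping-set; return the global optimum.

    A test oracle for the MILP, guarded to tiny instances.  Ties are broken
    toward the lexicographically smallest ortholog-set.
    """
    ffr = capped.ffr
    if ffr.sim.n_edges > MAX_EXHAUSTIVE_SIM_EDGES:
        raise ValueError(
            f"exhaustive solver guarded to <= {MAX_EXHAUSTIVE_SIM_EDGES} similarity edges"
        )
    if capped.p > MAX_EXHAUSTIVE_P:
        raise ValueError(f"exhaustive solver guarded to p <= {MAX_EXHAUSTIVE_P}")
    best: tuple[float, list, SolveResult] | None = None
    sim = ffr.sim
    for matching in iter_matchings(sim.sorted_edges()):
        pairs = sorted(matching)
        decomp = induce_decomposition(ffr, pairs)
        ev, pset = min_capping_cost(capped, decomp)
        sigma_o = sum(sim.sigma(a, b) for a, b in pairs)
        ma = {a for a, _ in pairs}
        mb = {b for _, b in pairs}
        w_comp = sum(sim.weight(g) for g in ffr.genome_a.gene_ids - ma)
        w_comp += sum(sim.weight(g) for g in ffr.genome_b.gene_ids - mb)
        report = DistanceReport(
            d=ev.d, o_size=len(pairs), sigma_o=sigma_o, w_comp=w_comp
        )
        key = (report.wd, pairs)
        if best is None or key < (best[0], best[1]):
            result = SolveResult(
                ortholog_set=pairs,
                capping_set=sorted(pset),
                report=report,
                status="optimal",
            )
            best = (report.wd, pairs, result)
    assert best is not None  # the empty matching always exists
    return best[2]


def gendiff_pair(
    genome_a: Genome,
    genome_b: Genome,
    hits,
    sim_cfg: SimilarityFilterConfig | None = None,
    cap_cfg: CappingConfig | None = None,
    solver_cfg: SolverConfig | None = None,
) -> SolveResult:
    """One pairwise comparison: similarity graph, FFR, capping, MILP solve."""
    cap_cfg = cap_cfg or CappingConfig()
    sim = build_similarity_graph(genome_a, genome_b, hits, sim_cfg)
    ffr = build_ffr(genome_a, genome_b, sim)
    if cap_cfg.mode == "optimal":
        capped = optimal_capping(ffr)
    else:
        scg = build_shared_content_graph(genome_a, genome_b, sim, cap_cfg)
        c_hat = complete_to_perfect(scg)
        capped = heuristic_capping(ffr, c_hat)
    result = solve_capped_ffr(capped, solver_cfg)
    result.extra["search_space"] = capped.search_space_report()
    result.extra["sim_edges"] = sim.n_edges
    return result


__all__ = [
    "SolverConfig",
    "SolveResult",
    "solve_capped_ffr",
    "exhaustive_solve",
    "gendiff_pair",
    "SiblingSet",
    "Decomposition",
]
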