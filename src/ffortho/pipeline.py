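"""End-to-end orchestration: all pairwise comparisons, then family building.

For each of the n(n-1)/2 genome pairs the pipeline builds the filtered
similarity graph, the relational graph and its capping (optimal or
heuristic), solves the MILP for an optimal ortholog-set, integrates every
pairwise ortholog-set into the n-partite family graph, classifies the
connected components and optionally refines ambiguous families with
Markov clustering.  Pairwise comparisons are independent: results never
depend on execution order.  A failing pair is recorded and skipped;
families are then built from the successful pairs and the run is flagged.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

from .capping import (
    CappingConfig,
    build_shared_content_graph,
    complete_to_perfect,
    heuristic_capping,
    optimal_capping,
)
from .families import (
    AMBIGUOUS,
    Family,
    FamilyGraph,
    classify_families,
    families_to_familyset,
    homology_pair_metrics,
    integrate_ortholog_sets,
    mcl_refine,
    unclassified_singletons,
)
from .ffr import build_ffr
from .genomes import BitscoreTable, FamilySet, Genome
from .similarity import SimilarityFilterConfig, build_similarity_graph
from .solver import SolveResult, SolverConfig, solve_capped_ffr

logger = logging.getLogger("ffortho")


@dataclass
class PipelineConfig:
    similarity: SimilarityFilterConfig = field(default_factory=SimilarityFilterConfig)
    capping: CappingConfig = field(default_factory=CappingConfig)
    solver: SolverConfig = field(default_factory=SolverConfig)
    mcl: bool = True
    mcl_inflation: float = 1.4


@dataclass
class PairOutcome:
    genome_a: str
    genome_b: str
    result: SolveResult | None
    sigma: dict[tuple[str, str], float] = field(default_factory=dict)
    error: str | None = None
    seconds: float = 0.0


@dataclass
class PipelineResult:
    pair_outcomes: list[PairOutcome]
    family_graph: FamilyGraph
    families: list[Family]
    refined_families: list[Family] | None
    singletons: set[str]
    ok: bool

    def final_families(self) -> list[Family]:
        return self.refined_families if self.refined_families is not None else self.families

    def family_set(self, include_singletons: bool = True) -> FamilySet:
        fams = [f.genes for f in self.final_families()]
        if include_singletons:
            fams.extend(frozenset((g,)) for g in sorted(self.singletons))
        return FamilySet(fams, label="ffortho")


def run_pair(
    genome_a: Genome,
    genome_b: Genome,
    hits: BitscoreTable,
    cfg: PipelineConfig,
) -> PairOutcome:
    t0 = time.perf_counter()
    sim = build_similarity_graph(genome_a, genome_b, hits, cfg.similarity)
    ffr = build_ffr(genome_a, genome_b, sim)
    if cfg.capping.mode == "optimal":
        capped = optimal_capping(ffr)
    else:
        scg = build_shared_content_graph(genome_a, genome_b, sim, cfg.capping)
        c_hat = complete_to_perfect(scg)
        capped = heuristic_capping(ffr, c_hat)
    logger.info(
        "pair %s/%s: %d similarity edges, capping %s",
        genome_a.genome_id,
        genome_b.genome_id,
        sim.n_edges,
        capped.search_space_report(),
    )
    result = solve_capped_ffr(capped, cfg.solver)
    sigma = {(a, b): sim.sigma(a, b) for a, b in result.ortholog_set}
    return PairOutcome(
        genome_a=genome_a.genome_id,
        genome_b=genome_b.genome_id,
        result=result,
        sigma=sigma,
        seconds=time.perf_counter() - t0,
    )


def run_pipeline(
    genomes: list[Genome],
    hits: BitscoreTable,
    cfg: PipelineConfig | None = None,
) -> PipelineResult:
    if len(genomes) < 2:
        raise ValueError("the pipeline needs at least two genomes")
    ids = [g.genome_id for g in genomes]
    if len(set(ids)) != len(ids):
        raise ValueError("genome ids must be unique")
    cfg = cfg or PipelineConfig()

    outcomes: list[PairOutcome] = []
    for i in range(len(genomes)):
        for j in range(i + 1, len(genomes)):
            ga, gb = genomes[i], genomes[j]
            try:
                outcomes.append(run_pair(ga, gb, hits, cfg))
            except Exception as exc:  # noqa: BLE001 - isolate per-pair failures
                logger.error("pair %s/%s failed: %s", ga.genome_id, gb.genome_id, exc)
                outcomes.append(
                    PairOutcome(ga.genome_id, gb.genome_id, None, error=str(exc))
                )

    genome_of = {g: gn.genome_id for gn in genomes for g in gn.gene_ids}
    pairwise = [
        (
            o.genome_a,
            o.genome_b,
            [(a, b, o.sigma[(a, b)]) for a, b in o.result.ortholog_set],
        )
        for o in outcomes
        if o.result is not None
    ]
    fg = integrate_ortholog_sets(pairwise, genome_of)
    families = classify_families(fg, n_genomes=len(genomes))
    singletons = unclassified_singletons(fg)

    refined: list[Family] | None = None
    if cfg.mcl:
        weights = {
            (u, v): d["sigma"] for u, v, d in fg.graph.edges(data=True)
        }
        refined = []
        for fam in families:
            if fam.family_class == AMBIGUOUS:
                refined.extend(
                    mcl_refine(
                        fam,
                        weights,
                        genome_of,
                        len(genomes),
                        inflation=cfg.mcl_inflation,
                    )
                )
            else:
                refined.append(fam)
        # refinement may strand single genes; keep them as singletons
        kept: list[Family] = []
        for fam in refined:
            if len(fam.genes) == 1:
                singletons |= fam.genes
            else:
                kept.append(fam)
        refined = kept

    ok = all(o.error is None for o in outcomes)
    return PipelineResult(
        pair_outcomes=outcomes,
        family_graph=fg,
        families=families,
        refined_families=refined,
        singletons=singletons,
        ok=ok,
    )


def evaluate_against_reference(
    result_or_set: PipelineResult | FamilySet, reference: FamilySet
) -> dict:
    """Score an inferred family set against a reference (2-subset metrics)."""
    if isinstance(result_or_set, PipelineResult):
        predicted = result_or_set.family_set()
    else:
        predicted = result_or_set
    return homology_pair_metrics(predicted, reference).to_dict()


__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "PairOutcome",
    "run_pair",
    "run_pipeline",
    "evaluate_against_reference",
    "families_to_familyset",
]
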