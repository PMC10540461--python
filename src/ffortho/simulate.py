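"""Synthetic genome evolution with planted orthologies.

An ancestral genome is evolved independently into each extant genome by
seeded DCJ operations (inversions and translocations), deletions,
insertions of genome-specific genes and tandem-ish duplications.  Bitscore
tables are emitted so that planted orthologs pass the default similarity
filters, duplicated copies create ambiguous similarity, and optional noise
adds spurious hits.  The planted gene families (genes descending from the
same ancestral gene) are returned as ground truth.

DCJ operations preserve gene content, so with zero duplication and zero
noise the pipeline must recover the planted families exactly, whatever the
number of rearrangements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genomes import BitscoreTable, FamilySet, Genome, genome_from_lists

SELF_BITSCORE = 200.0
ORTHOLOG_BITSCORE = 190.0
DUPLICATE_BITSCORE = 182.0


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions of one synthetic dataset."""

    n_genomes: int = 3
    n_genes: int = 10
    n_segments: int = 2
    n_dcj: int = 2           # rearrangements per branch
    n_deletions: int = 0     # single-gene losses per branch
    n_insertions: int = 0    # genome-specific gains per branch
    duplication_rate: float = 0.0  # per-gene duplication probability
    noise: float = 0.0       # spurious-hit intensity and bitscore jitter
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genomes < 1 or self.n_genes < 1 or self.n_segments < 1:
            raise ValueError("counts must be positive")
        if self.n_segments > self.n_genes:
            raise ValueError("more segments than genes would leave empty segments")
        if min(self.n_dcj, self.n_deletions, self.n_insertions) < 0:
            raise ValueError("operation counts must be nonnegative")
        if not (0 <= self.duplication_rate <= 1) or self.noise < 0:
            raise ValueError("rates out of range")
        if self.n_genes - self.n_deletions < self.n_segments:
            raise ValueError("deletions would empty a segment budget")


@dataclass
class SyntheticDataset:
    genomes: list[Genome]
    hits: BitscoreTable
    planted: FamilySet
    spec: SyntheticSpec = field(repr=False, default=None)


def _ancestor(spec: SyntheticSpec) -> list[list[str]]:
    genes = [f"g{i + 1:03d}" for i in range(spec.n_genes)]
    bounds = np.linspace(0, spec.n_genes, spec.n_segments + 1).astype(int)
    return [genes[bounds[i] : bounds[i + 1]] for i in range(spec.n_segments)]


def _apply_dcj(segments: list[list[str]], rng: np.random.Generator) -> None:
    """One random content-preserving DCJ: inversion or translocation."""
    multi = len(segments) > 1
    if multi and rng.random() < 0.5:
        i, j = rng.choice(len(segments), size=2, replace=False)
        ci = rng.integers(0, len(segments[i]) + 1)
        cj = rng.integers(0, len(segments[j]) + 1)
        head_i, tail_i = segments[i][:ci], segments[i][ci:]
        head_j, tail_j = segments[j][:cj], segments[j][cj:]
        new_i, new_j = head_i + tail_j, head_j + tail_i
        if new_i and new_j:
            segments[i], segments[j] = new_i, new_j
            return
    seg = segments[int(rng.integers(0, len(segments)))]
    if len(seg) == 1:
        seg[0] = _flip(seg[0])
        return
    i = int(rng.integers(0, len(seg)))
    j = int(rng.integers(i, len(seg)))
    seg[i : j + 1] = [_flip(t) for t in reversed(seg[i : j + 1])]


def _flip(token: str) -> str:
    return token[1:] if token.startswith("-") else "-" + token


def _root(token: str) -> str:
    return token[1:] if token.startswith("-") else token


def generate_synthetic_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    rng = np.random.default_rng(spec.seed)
    ancestor = _ancestor(spec)

    genome_tokens: dict[str, list[list[str]]] = {}
    ancestral_of: dict[str, str] = {}  # full gene id -> ancestral gene
    for k in range(spec.n_genomes):
        gid = f"G{k + 1}"
        segments = [list(seg) for seg in ancestor]
        for _ in range(spec.n_dcj):
            _apply_dcj(segments, rng)
        for _ in range(spec.n_deletions):
            candidates = [i for i, seg in enumerate(segments) if len(seg) > 1]
            if not candidates:
                break
            i = int(rng.choice(candidates))
            pos = int(rng.integers(0, len(segments[i])))
            del segments[i][pos]
        for j in range(spec.n_insertions):
            i = int(rng.integers(0, len(segments)))
            pos = int(rng.integers(0, len(segments[i]) + 1))
            segments[i].insert(pos, f"x{k + 1}_{j + 1}")
        # duplications: copy a gene elsewhere under a fresh occurrence name
        present = [t for seg in segments for t in seg]
        n_dup = rng.binomial(len(present), spec.duplication_rate)
        for j in range(n_dup):
            src = _root(str(rng.choice(present)))
            i = int(rng.integers(0, len(segments)))
            pos = int(rng.integers(0, len(segments[i]) + 1))
            segments[i].insert(pos, f"{src}~dup{j + 1}")
        # qualify tokens with the genome id
        qualified: list[list[str]] = []
        for seg in segments:
            row = []
            for tok in seg:
                sign = "-" if tok.startswith("-") else ""
                name = _root(tok)
                full = f"{gid}|{name}"
                ancestral_of[full] = name.split("~")[0]
                row.append(sign + full)
            qualified.append(row)
        genome_tokens[gid] = qualified

    genomes = [
        genome_from_lists(gid, {f"{gid}.s{i + 1}": seg for i, seg in enumerate(segs)})
        for gid, segs in genome_tokens.items()
    ]

    hits = BitscoreTable()
    all_genes: dict[str, list[str]] = {g.genome_id: sorted(g.gene_ids) for g in genomes}
    for gid, genes in all_genes.items():
        for g in genes:
            hits.add(g, g, SELF_BITSCORE)
    by_ancestor: dict[str, list[str]] = {}
    for full, anc in ancestral_of.items():
        if anc.startswith("x"):
            continue  # genome-specific insertions have no homologs
        by_ancestor.setdefault(anc, []).append(full)
    genome_of = {g: gid for gid, genes in all_genes.items() for g in genes}
    for anc, members in sorted(by_ancestor.items()):
        for a in members:
            for b in members:
                if genome_of[a] == genome_of[b]:
                    continue
                primary = "~" not in a.split("|")[1] and "~" not in b.split("|")[1]
                base = ORTHOLOG_BITSCORE if primary else DUPLICATE_BITSCORE
                jitter = rng.uniform(0, 8.0 * spec.noise) if spec.noise > 0 else 0.0
                hits.add(a, b, max(base - jitter, 1.0))
    # spurious similarities between unrelated genes
    if spec.noise > 0:
        flat = sorted(genome_of)
        n_noise = rng.poisson(spec.noise * len(flat))
        for _ in range(n_noise):
            a, b = rng.choice(flat, size=2, replace=False)
            if genome_of[a] == genome_of[b] or ancestral_of[a] == ancestral_of[b]:
                continue
            score = float(rng.uniform(30.0, 130.0))
            hits.add(a, b, score)
            hits.add(b, a, score * float(rng.uniform(0.9, 1.0)))

    planted = FamilySet(
        [frozenset(m) for m in by_ancestor.values()], label="planted"
    )
    return SyntheticDataset(genomes=genomes, hits=hits, planted=planted, spec=spec)


def random_instance_pair(
    rng: np.random.Generator,
    max_genes: int = 4,
    max_segments: int = 3,
    max_edges: int = 4,
):
    """A random tiny two-genome instance with a random similarity graph.

    Used for enumerative studies of decompositions and cappings: genomes
    get up to ``max_genes`` genes spread over up to ``max_segments``
    segments with random orientations, and up to ``max_edges`` random
    cross-genome similarity edges with scores in (0, 1].
    """
    from .similarity import GeneSimilarityGraph

    def mk(prefix: str):
        n = int(rng.integers(1, max_genes + 1))
        genes = [f"{prefix}{i}" for i in range(n)]
        rng.shuffle(genes)
        n_segs = int(rng.integers(1, min(max_segments, n) + 1))
        bounds = sorted(rng.choice(range(1, n), size=n_segs - 1, replace=False)) if n_segs > 1 else []
        out, prev = [], 0
        for c in [*bounds, n]:
            out.append(
                [("-" if rng.random() < 0.5 else "") + g for g in genes[prev:c]]
            )
            prev = c
        return genome_from_lists(prefix.upper(), out)

    genome_a, genome_b = mk("a"), mk("b")
    sim = GeneSimilarityGraph(genome_a, genome_b)
    pairs = [(a, b) for a in sorted(genome_a.gene_ids) for b in sorted(genome_b.gene_ids)]
    idx = rng.permutation(len(pairs))
    for k in idx[: int(rng.integers(0, max_edges + 1))]:
        a, b = pairs[int(k)]
        sim.add_edge(a, b, float(np.round(rng.uniform(0.15, 1.0), 2)))
    return genome_a, genome_b, sim


def capping_linkage_study(
    seed: int,
    n_instances: int = 100,
    max_genes: int = 4,
    max_segments: int = 3,
) -> dict:
    """How many paths must an optimal capping link into a single cycle?

    Over ``n_instances`` seeded random genome pairs and every consistent
    decomposition of each, enumerate all capping-sets of the optimally
    capped graph; among those achieving the minimum weighted cost take one
    linking as few paths as possible into any single cycle (cost-neutral
    gratuitous merges between tied optima are not forced by the capping
    and are not counted).  Returns the maximum linkage observed, which the
    theory bounds by four (an A-A path, a B-B path and two A-B paths).
    """
    from .capping import evaluate_capping, iter_capping_sets, optimal_capping
    from .ffr import build_ffr, induce_decomposition, iter_matchings

    rng = np.random.default_rng(seed)
    overall = 0
    n_decompositions = 0
    for _ in range(n_instances):
        genome_a, genome_b, sim = random_instance_pair(
            rng, max_genes=max_genes, max_segments=max_segments
        )
        ffr = build_ffr(genome_a, genome_b, sim)
        capped = optimal_capping(ffr)
        capping_sets = list(iter_capping_sets(capped))
        for matching in iter_matchings(sim.sorted_edges()):
            decomp = induce_decomposition(ffr, matching)
            n_decompositions += 1
            best_d = None
            needed = 0
            for pset in capping_sets:
                ev = evaluate_capping(capped, decomp, pset)
                if best_d is None or ev.d < best_d:
                    best_d, needed = ev.d, ev.max_paths_linked
                elif ev.d == best_d and ev.max_paths_linked < needed:
                    needed = ev.max_paths_linked
            overall = max(overall, needed)
    return {
        "max_paths_linked": overall,
        "n_instances": n_instances,
        "n_decompositions": n_decompositions,
    }


def write_hits_tabular(hits: BitscoreTable, path) -> None:
    """Dump a BitscoreTable in the 12-column tabular dialect."""
    filler = ["100.0", "50", "0", "0", "1", "50", "1", "50", "1e-50"]
    with open(path, "w", encoding="utf-8") as fh:
        for q, s, b in sorted(hits):
            fh.write("\t".join([q, s, *filler, f"{b:.1f}"]) + "\n")
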