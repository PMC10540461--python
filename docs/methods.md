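# Methods

This note documents the model implemented by `ffortho`, the numerical and
design choices that were genuinely open, what the synthetic generator does
and does not emulate, and known limitations.

## Genomes, mutations and the weighted distance

A genome is a set of linear segments (chromosomes or contigs) of oriented
genes; a segment read backwards with all orientations flipped is the same
segment, and the data model treats it as such.  Two mutation classes are
modelled: DCJ operations (two cuts, one rejoining — covering inversions,
translocations, fusions and fissions, with circular intermediates allowed)
and indels of contiguous gene blocks, restricted so that no gene is both
deleted and (re)inserted — without this restriction the cheapest scenario
would simply delete one genome and insert the other.

Given genomes 𝔸, 𝔹, a similarity graph S and an ortholog-set 𝒪 (a matching
in S), the weighted distance is

    wd = d + |𝒪| − σ(𝒪) + w(𝒪̃),

trading one unit of rearrangement cost against one unit of unexplained
similarity: every matched pair costs 1 − σ(e) ≥ 0 and every unmatched gene
its weight w(u) on top of the operation count d.  Since σ ≤ 1 (scores are
clipped; reciprocal bitscores can arithmetically exceed self-scores) and
w ≥ 0, wd ≥ d ≥ 0 always.

## Gene similarities

σ(x, y) is the relative reciprocal score
(bitscr(x→y) + bitscr(y→x)) / (bitscr(x→x) + bitscr(y→y)), computed from
tabular DIAMOND/BLAST hits.  Duplicate HSP rows collapse to the maximum
bitscore (the conservative choice for a reciprocal score; the dialect does
not specify HSP handling).  Two filters apply: an absolute cutoff
Ϝ_ε = 0.1 on σ and a relative reciprocal cutoff Ϝ_t = 0.8 — each direction
must reach 0.8 of that gene's best raw bitscore against the other genome,
with the maxima taken over raw bitscores before any filtering.  An edge
requires hits in both directions.  Genes losing all edges stay in the
graph as isolated vertices with w = 0: they still occur in gene orders and
act as indel candidates.

## Distance computation

All costs are read off consistent decompositions of the family-free
relational graph (vertices = gene extremities; adjacency, sibling-paired
extremity and per-gene indel edges).  A decomposition has exactly
κ(𝔸) + κ(𝔹) paths, which a capping closes into cycles.  For a capped
decomposition made of cycles only,

    d = (|𝒪| + p) − c + Σ_C λ(C),

with p cap pairs per genome, c cycles, and λ(C) the indel-potential of
cycle C: reading the genome labels of the indel edges cyclically around C,
Λ(C) is the number of maximal same-genome blocks (1 if all labels agree,
otherwise an even count) and λ = ⌈(Λ + 1)/2⌉ when the cycle carries indel
edges, 0 otherwise.  This run accounting reflects that a deletion removes
one contiguous block, that sorting DCJs can merge runs, and that a
same-genome pair of runs costs one extra operation to reconcile across
genomes.  The formula is exercised in two independent ways in the test
suite: against a bidirectional breadth-first search over genome states
(applying every DCJ, every permissible block deletion and insertion) on
all tiny instances, and through the cost-preservation identity — the
minimum capped cost over all capping-sets of the optimal capping equals
the uncapped distance.

The MILP linearizes the two cycle terms with standard devices: per-vertex
potentials y_v ≤ index(v), forced equal along selected edges and to zero
across indel edges, let a binary z_v score one unit per indel-free cycle
at its minimum-index vertex; binary genome labels r_v, pinned at indel-edge
endpoints, pay a transition t_e wherever they flip along a selected edge.
Then d = (|𝒪| + p) − Σz + ½Σt, which is algebraically identical to the λ
form.  The backend is HiGHS via `scipy.optimize.milp`; any MILP solver
would do.  Ties between equally optimal ortholog-sets are broken toward
the lexicographically smallest edge list by an epsilon-weighted secondary
objective (total mass < 1e-6, far below any meaningful score difference at
the instance sizes where ties matter; exact reproducibility additionally
rests on the deterministic variable order and single-threaded solve).

## Capping

Optimal capping: p★ = max(κ(𝔸), κ(𝔹)) cap pairs per side, dummy
adjacencies on the smaller side (paired deterministically by index, since
any pairing is equivalent), complete bipartite cap edges, (2p★)!
capping-sets.

Heuristic capping: the shared-content graph scores segment pairs by
Ω(A, B) = Σ σ over cross-segment similarity edges.  Each vertex keeps only
its τ = 2 best edges — an edge survives iff it ranks within τ for **both**
endpoints, with all ties at rank τ kept and ranks taken on the unfiltered
graph, making the pass order-independent.  The surviving graph is filtered
again: edges below ε = 0.1 of an endpoint's best surviving score are
dropped.  Completion adds dummy segments along Hall violators (the
unsaturated vertex plus everything reachable by alternating paths;
deficiency |S| − |N(S)| dummies, each connected to all of S) until a
perfect matching exists, then removes all non-matchable edges (one perfect
matching + strongly-connected-components of the matched/unmatched
orientation).  Each surviving segment pair contributes the two crosswise
cap pairings; a two-vertex component with a dummy endpoint keeps a single
pairing, the two being equivalent.  Validity — the existence of a
capping-set — is equivalent to the existence of a perfect matching in the
segment graph, and is checked exhaustively in the tests.  Capping-set
counts are reported via the Bregman–Minc permanent bound Π (r_i!)^(1/r_i),
with the exact permanent for small graphs.

A minimum-cost capping never needs to link more than four paths into one
cycle (an 𝔸𝔸-path, a 𝔹𝔹-path and two 𝔸𝔹-paths).  The linkage study in
`scripts/acceptance.py` measures the linkage *required*: among tied
minimum-cost capping-sets it selects one linking as few paths as possible,
because tied optima may merge cycles gratuitously (a merge that saves one
indel exactly compensates the lost cycle), which says nothing about the
capping the optimum needs.

## Families, MCL, metrics

Families are connected components of the integrated n-partite ortholog
graph.  Markov clustering of ambiguous families runs on their σ-weighted
subgraphs (σ is the only weight the pipeline carries; the alternative —
unweighted edges — discards exactly the signal that distinguishes a
paralog bridge from an ortholog clique).  Parameters: inflation 1.4,
pruning threshold 1e-5, at most 100 iterations, self-loops at the node's
maximum incident weight.  Clusters are read from attractor rows,
overlapping attractor sets merged, flow-starved nodes kept as singletons;
refinement conserves genes and can only remove gene pairs, never add them.

2-subset metrics drop predicted genes absent from the reference (curated
references never classify everything an inference sees) but keep the
reference intact, so missed reference pairs count as false negatives.  A
prediction with no pairs at all reports precision 0 with an explicit flag
rather than dividing by zero.

## Synthetic data

The generator evolves one ancestor independently into each genome with
seeded content-preserving DCJs (inversions, translocations), single-gene
deletions, genome-specific insertions and duplications, then emits
bitscores: self-hits at 200, orthologous pairs at 190 (duplicate copies at
182, creating ambiguous similarity), spurious reciprocal pairs and score
jitter controlled by a single noise intensity.  Defaults (3 genomes, 10
genes, 2 segments, 2 DCJs per branch, no indels/duplications/noise) are
small enough for exhaustive cross-checks while exercising every pipeline
stage.  What it does *not* emulate: realistic bitscore distributions,
domain-level partial homology, gene length variation, assembly
fragmentation correlated with gene content, or lineage-correlated
evolution (branches are independent).  Passing recovery tests therefore
demonstrate correctness of the inference machinery under the stated model,
not calibrated performance on real proteomes.

## Problem sizes and numerical choices

Enumeration guards: the exhaustive solver accepts ≤ 8 similarity edges and
p ≤ 3 (720 capping-sets); the state-space oracle ≤ 9 genes per genome; the
exact permanent n ≤ 12.  The acceptance study uses 100 instances with ≤ 4
genes and ≤ 3 segments per genome — the scale at which full enumeration of
decompositions × capping-sets stays exact.  MILP incumbents at timeout are
returned and flagged `feasible-at-timeout` rather than discarded.
Floating-point cost comparisons in tests use exact integers for d (the
solver's cost is re-derived by walking the selected decomposition, not
read from the objective) and tolerances of 1e-9 elsewhere.

## Limitations

Circular chromosomes are rejected at parse time (capping concerns linear
segment ends).  Operation scenarios are not reconstructed — only counts
and costs.  The pipeline's pairwise stage is an exact solver for an
NP-hard problem: on real genome pairs the heuristic capping is what makes
it practical, and on adversarial inputs the MILP may still time out.
Transcript selection (e.g. keeping one isoform per gene) is upstream of
this tool.
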