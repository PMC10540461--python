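"""Genome data model and plain-text readers/writers.

A genome is a set of linear segments (chromosomes, scaffolds or contigs),
each an ordered list of oriented genes.  Three text formats are handled:

* gene orders -- one segment per line: ``segment_id<TAB>g1 g2 -g3 ...``
  where a leading ``-`` marks reverse orientation;
* all-vs-all tabular bitscore hits in the BLAST/DIAMOND ``outfmt 6``
  dialect (query id, subject id, ..., bitscore in the last column);
* family lists -- one family per line, whitespace-separated gene ids.

Circular chromosomes are not supported: the rearrangement model capped
here concerns linear segments only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

FORWARD = 1
REVERSE = -1


class GenomeFormatError(ValueError):
    """Raised on malformed gene-order, hits or family input."""


@dataclass(frozen=True)
class Gene:
    """An oriented gene occurrence within a linear segment."""

    gene_id: str
    genome_id: str
    segment_id: str
    index: int
    orientation: int  # FORWARD or REVERSE

    def __post_init__(self) -> None:
        if self.orientation not in (FORWARD, REVERSE):
            raise ValueError(f"orientation must be +1/-1, got {self.orientation}")


class LinearSegment:
    """A non-empty ordered list of oriented genes with two telomeres.

    A segment can be read in either of the two directions, so equality is
    invariant under full reversal with orientation flip.
    """

    def __init__(self, segment_id: str, genes: list[Gene]):
        if not genes:
            raise GenomeFormatError(f"segment {segment_id!r} is empty")
        self.segment_id = segment_id
        self.genes = list(genes)
        for i, g in enumerate(self.genes):
            if g.index != i:
                raise GenomeFormatError(
                    f"segment {segment_id!r}: gene {g.gene_id!r} has index "
                    f"{g.index}, expected {i}"
                )

    def __len__(self) -> int:
        return len(self.genes)

    def signed_tuple(self) -> tuple[tuple[str, int], ...]:
        return tuple((g.gene_id, g.orientation) for g in self.genes)

    def canonical_tuple(self) -> tuple[tuple[str, int], ...]:
        fwd = self.signed_tuple()
        rev = tuple((gid, -o) for gid, o in reversed(fwd))
        return min(fwd, rev)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LinearSegment):
            return NotImplemented
        return self.canonical_tuple() == other.canonical_tuple()

    def __hash__(self) -> int:
        return hash(self.canonical_tuple())

    @property
    def telomeres(self) -> tuple[tuple[str, str], tuple[str, str]]:
        """The two outermost gene extremities as ``(gene_id, 't'|'h')``.

        For a forward gene the left extremity is the tail and the right the
        head; a reverse-oriented gene exposes them the other way round.
        """
        first, last = self.genes[0], self.genes[-1]
        left = (first.gene_id, "t" if first.orientation == FORWARD else "h")
        right = (last.gene_id, "h" if last.orientation == FORWARD else "t")
        return left, right

    def __repr__(self) -> str:
        body = " ".join(
            ("" if g.orientation == FORWARD else "-") + g.gene_id for g in self.genes
        )
        return f"[{body}]"


class Genome:
    """A set of linear segments; ``kappa`` is the segment count."""

    def __init__(self, genome_id: str, segments: Iterable[LinearSegment]):
        self.genome_id = genome_id
        self.segments = list(segments)
        seen: set[str] = set()
        for seg in self.segments:
            for g in seg.genes:
                if g.gene_id in seen:
                    raise GenomeFormatError(
                        f"genome {genome_id!r}: duplicate gene id {g.gene_id!r}"
                    )
                seen.add(g.gene_id)
        self._gene_ids = seen

    @property
    def kappa(self) -> int:
        return len(self.segments)

    def genes(self) -> Iterator[Gene]:
        for seg in self.segments:
            yield from seg.genes

    @property
    def gene_ids(self) -> set[str]:
        return set(self._gene_ids)

    @property
    def n_genes(self) -> int:
        return len(self._gene_ids)

    def segment_of(self, gene_id: str) -> str:
        try:
            return self._segment_index()[gene_id]
        except KeyError:
            raise KeyError(f"gene {gene_id!r} not in genome {self.genome_id!r}") from None

    def _segment_index(self) -> dict[str, str]:
        idx = getattr(self, "_seg_idx", None)
        if idx is None:
            idx = {g.gene_id: g.segment_id for g in self.genes()}
            self._seg_idx = idx
        return idx

    def __repr__(self) -> str:
        return f"Genome({self.genome_id!r}, {self.segments})"


def _parse_token(token: str, genome_id: str, segment_id: str, index: int, lineno: int) -> Gene:
    orientation = FORWARD
    if token.startswith("-"):
        orientation = REVERSE
        token = token[1:]
    if not token:
        raise GenomeFormatError(f"line {lineno}: malformed gene token")
    return Gene(token, genome_id, segment_id, index, orientation)


def parse_gene_orders(path: str | Path, genome_id: str | None = None) -> Genome:
    """Read a genome from the one-segment-per-line gene-order format.

    ``genome_id`` defaults to the file stem.  Lines starting with ``#`` and
    blank lines are ignored.  Duplicate gene ids, empty segments and
    malformed tokens are hard errors reported with their line number.
    """
    path = Path(path)
    gid = genome_id if genome_id is not None else path.stem
    segments: list[LinearSegment] = []
    seg_ids: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "\t" in line:
                seg_id, _, rest = line.partition("\t")
            else:
                seg_id, _, rest = line.partition(" ")
            seg_id = seg_id.strip()
            tokens = rest.split()
            if not seg_id:
                raise GenomeFormatError(f"line {lineno}: missing segment id")
            if seg_id in seg_ids:
                raise GenomeFormatError(f"line {lineno}: duplicate segment id {seg_id!r}")
            if not tokens:
                raise GenomeFormatError(f"line {lineno}: empty segment {seg_id!r}")
            seg_ids.add(seg_id)
            genes = [
                _parse_token(tok, gid, seg_id, i, lineno) for i, tok in enumerate(tokens)
            ]
            segments.append(LinearSegment(seg_id, genes))
    if not segments:
        raise GenomeFormatError(f"{path}: no segments found")
    return Genome(gid, segments)


def write_gene_orders(genome: Genome, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for seg in genome.segments:
            body = " ".join(
                ("" if g.orientation == FORWARD else "-") + g.gene_id
                for g in seg.genes
            )
            fh.write(f"{seg.segment_id}\t{body}\n")


def genome_from_lists(
    genome_id: str, segments: dict[str, list[str]] | list[list[str]]
) -> Genome:
    """Build a Genome from signed gene-id strings, e.g. ``[["1","2","-3"]]``."""
    if isinstance(segments, dict):
        items = list(segments.items())
    else:
        items = [(f"seg{i+1}", seg) for i, seg in enumerate(segments)]
    out = []
    for seg_id, tokens in items:
        genes = [_parse_token(t, genome_id, seg_id, i, 0) for i, t in enumerate(tokens)]
        out.append(LinearSegment(seg_id, genes))
    return Genome(genome_id, out)


class BitscoreTable:
    """Directed bitscores ``bitscr(query -> subject)``; duplicates keep the max."""

    def __init__(self) -> None:
        self._scores: dict[tuple[str, str], float] = {}

    def add(self, query: str, subject: str, bitscore: float) -> None:
        if not (bitscore > 0) or math.isnan(bitscore):
            raise GenomeFormatError(
                f"bitscore for ({query!r},{subject!r}) must be positive, got {bitscore}"
            )
        key = (query, subject)
        prev = self._scores.get(key)
        if prev is None or bitscore > prev:
            self._scores[key] = bitscore

    def get(self, query: str, subject: str) -> float | None:
        return self._scores.get((query, subject))

    def self_score(self, gene: str) -> float | None:
        return self._scores.get((gene, gene))

    def __len__(self) -> int:
        return len(self._scores)

    def __iter__(self) -> Iterator[tuple[str, str, float]]:
        for (q, s), b in self._scores.items():
            yield q, s, b

    def queries(self) -> set[str]:
        return {q for q, _ in self._scores}


def parse_tabular_hits(path: str | Path) -> BitscoreTable:
    """Read BLAST/DIAMOND tabular hits (outfmt-6 dialect).

    Column 1 is the query id, column 2 the subject id and the *last* column
    the bitscore; intermediate columns are ignored.  Duplicate
    (query, subject) rows collapse to the maximum bitscore.  An empty file
    yields an empty table.
    """
    table = BitscoreTable()
    path = Path(path)
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#", dtype=str, engine="c"
        )
    except pd.errors.EmptyDataError:
        return table
    if df.shape[1] < 3:
        raise GenomeFormatError(
            f"{path}: expected tab-separated rows with >=3 columns, got {df.shape[1]}"
        )
    last = df.columns[-1]
    for row in df.itertuples(index=False):
        q, s, b = row[0], row[1], row[-1]
        try:
            score = float(b)
        except (TypeError, ValueError) as exc:
            raise GenomeFormatError(f"{path}: non-numeric bitscore {b!r}") from exc
        table.add(str(q), str(s), score)
    del last
    return table


@dataclass
class FamilySet:
    """A disjoint collection of gene-id sets with a provenance label."""

    families: list[frozenset[str]] = field(default_factory=list)
    label: str = ""

    def __post_init__(self) -> None:
        self.families = [frozenset(f) for f in self.families]
        seen: set[str] = set()
        for fam in self.families:
            for g in fam:
                if g in seen:
                    raise GenomeFormatError(
                        f"family set {self.label!r}: gene {g!r} occurs in two families"
                    )
                seen.add(g)

    def __len__(self) -> int:
        return len(self.families)

    def __iter__(self) -> Iterator[frozenset[str]]:
        return iter(self.families)

    @property
    def gene_universe(self) -> set[str]:
        out: set[str] = set()
        for fam in self.families:
            out |= fam
        return out

    def restricted_to(self, genes: set[str]) -> "FamilySet":
        fams = [fam & genes for fam in self.families]
        return FamilySet([f for f in fams if f], label=self.label)


def read_families(path: str | Path, label: str | None = None) -> FamilySet:
    path = Path(path)
    fams: list[frozenset[str]] = []
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fams.append(frozenset(line.split()))
    return FamilySet(fams, label=label if label is not None else path.stem)


def write_families(families: FamilySet, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for fam in families.families:
            fh.write(" ".join(sorted(fam)) + "\n")
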