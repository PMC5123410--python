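"""Core gene-order data model.

Genomes are represented as sets of *adjacencies* between gene *extremities*.
An oriented gene ``g`` has a tail ``g^t`` and a head ``g^h``; two genes that
are consecutive on a chromosome contribute the adjacency pairing the two
extremities that face each other.  Linear chromosome ends are recorded as
*telomeric* adjacencies pairing an extremity with the telomere marker.

Extremities are plain tuples ``(gene, end)`` with ``end in {"t", "h"}`` and
gene ids positive integers; the telomere is the distinguished tuple
``TELOMERE = (0, "o")``, which sorts before every real extremity so that
adjacency keys are canonical.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

Extremity = tuple[int, str]
Adjacency = tuple[Extremity, Extremity]

#: Telomere marker; gene id 0 is reserved.
TELOMERE: Extremity = (0, "o")


def tail(gene: int) -> Extremity:
    return (gene, "t")


def head(gene: int) -> Extremity:
    return (gene, "h")


def other_end(ext: Extremity) -> Extremity:
    """The opposite extremity of the same gene."""
    gene, end = ext
    if ext == TELOMERE:
        raise ValueError("telomere has no partner extremity")
    return (gene, "h" if end == "t" else "t")


def adjacency(x: Extremity, y: Extremity) -> Adjacency:
    """Canonical (sorted) adjacency between two extremities."""
    if x == y:
        raise ValueError(f"degenerate adjacency on extremity {x!r}")
    return (x, y) if x <= y else (y, x)


def is_telomeric(adj: Adjacency) -> bool:
    return adj[0] == TELOMERE


def fmt_extremity(ext: Extremity) -> str:
    if ext == TELOMERE:
        return "TEL"
    return f"{ext[0]}{ext[1]}"


def parse_extremity(text: str) -> Extremity:
    if text == "TEL":
        return TELOMERE
    m = re.fullmatch(r"(\d+)([th])", text)
    if m is None:
        raise ValueError(f"malformed extremity {text!r}")
    return (int(m.group(1)), m.group(2))


@dataclass(frozen=True)
class Chromosome:
    """An ordered sequence of signed genes, linear or circular."""

    genes: tuple[int, ...]
    circular: bool = False

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("empty chromosome")

    @property
    def gene_set(self) -> frozenset[int]:
        return frozenset(abs(g) for g in self.genes)

    def reversed_(self) -> "Chromosome":
        return Chromosome(tuple(-g for g in reversed(self.genes)), self.circular)

    def canonical(self) -> "Chromosome":
        """Rotation/orientation-invariant representative.

        Circular chromosomes are rotated so the smallest gene id comes first,
        with positive sign when either orientation allows it; linear
        chromosomes are oriented so the endpoint comparison is smallest.
        """
        def abskey(genes: tuple[int, ...]):
            return tuple((abs(g), g < 0) for g in genes)

        if not self.circular:
            rev = self.reversed_()
            return self if abskey(self.genes) <= abskey(rev.genes) else rev
        best: tuple[int, ...] | None = None
        for cand in (self.genes, self.reversed_().genes):
            k = len(cand)
            # rotate the smallest |gene| to the front
            pivot = min(range(k), key=lambda i: (abs(cand[i]), cand[i] < 0))
            rot = cand[pivot:] + cand[:pivot]
            if best is None or abskey(rot) < abskey(best):
                best = rot
        assert best is not None
        return Chromosome(best, True)

    def adjacencies(self) -> set[Adjacency]:
        """Adjacency set of this chromosome, telomeric ones included."""

        def left(g: int) -> Extremity:
            return tail(g) if g > 0 else head(-g)

        def right(g: int) -> Extremity:
            return head(g) if g > 0 else tail(-g)

        adjs: set[Adjacency] = set()
        for a, b in zip(self.genes, self.genes[1:]):
            adjs.add(adjacency(right(a), left(b)))
        if self.circular:
            if len(self.genes) == 1:
                g = self.genes[0]
                adjs.add(adjacency(tail(abs(g)), head(abs(g))))
            else:
                adjs.add(adjacency(right(self.genes[-1]), left(self.genes[0])))
        else:
            adjs.add(adjacency(TELOMERE, left(self.genes[0])))
            adjs.add(adjacency(TELOMERE, right(self.genes[-1])))
        return adjs


class GenomeError(ValueError):
    """Structural problem in a genome or genome file."""


@dataclass(frozen=True)
class Genome:
    """A multichromosomal genome as a set of adjacencies.

    Telomeric adjacencies are stored explicitly; each non-telomeric extremity
    appears in at most one adjacency, so the set decomposes uniquely into
    linear and circular chromosomes.
    """

    name: str
    adjacencies: frozenset[Adjacency]
    genes: frozenset[int] = field(default=frozenset())

    @staticmethod
    def from_chromosomes(name: str, chromosomes: Iterable[Chromosome]) -> "Genome":
        adjs: set[Adjacency] = set()
        genes: set[int] = set()
        for chrom in chromosomes:
            for g in (abs(x) for x in chrom.genes):
                if g in genes:
                    raise GenomeError(f"duplicate gene {g} in genome {name!r}")
                genes.add(g)
            adjs |= chrom.adjacencies()
        return Genome(name, frozenset(adjs), frozenset(genes))

    @staticmethod
    def from_gene_orders(
        name: str, orders: Iterable[tuple[Sequence[int], bool]]
    ) -> "Genome":
        return Genome.from_chromosomes(
            name, [Chromosome(tuple(genes), circ) for genes, circ in orders]
        )

    def non_telomeric(self) -> frozenset[Adjacency]:
        return frozenset(a for a in self.adjacencies if not is_telomeric(a))

    def chromosomes(self) -> list[Chromosome]:
        return adjacencies_to_chromosomes(self)

    def renamed(self, name: str) -> "Genome":
        return Genome(name, self.adjacencies, self.genes)

    def same_content(self, other: "Genome") -> bool:
        return self.genes == other.genes

    def equal_as_genome(self, other: "Genome") -> bool:
        """Equality of gene content and adjacency sets (names ignored)."""
        return self.genes == other.genes and self.adjacencies == other.adjacencies


def genome_from_adjacencies(
    name: str, adjs: Iterable[Adjacency], genes: Iterable[int]
) -> Genome:
    """Build a genome from non-telomeric adjacencies over an explicit gene set.

    Telomeric adjacencies for uncovered extremities are filled in
    automatically, so callers may pass only the internal adjacencies.
    """
    gene_set = frozenset(genes)
    full: set[Adjacency] = set()
    seen: dict[Extremity, Adjacency] = {}
    for adj in adjs:
        for ext in adj:
            if ext == TELOMERE:
                continue
            if abs(ext[0]) not in gene_set:
                raise GenomeError(f"adjacency {adj} uses unknown gene {ext[0]}")
            if ext in seen and seen[ext] != adj:
                raise GenomeError(f"extremity {fmt_extremity(ext)} in two adjacencies")
            seen[ext] = adj
        full.add(adj)
    for g in gene_set:
        for ext in (tail(g), head(g)):
            if ext not in seen:
                full.add(adjacency(TELOMERE, ext))
    genome = Genome(name, frozenset(full), gene_set)
    genome.chromosomes()  # validates decomposability
    return genome


def adjacencies_to_chromosomes(genome: Genome) -> list[Chromosome]:
    """Decompose an adjacency set into linear and circular chromosomes."""
    partner: dict[Extremity, Extremity] = {}
    telomeric: set[Extremity] = set()
    for adj in genome.adjacencies:
        x, y = adj
        if x == TELOMERE:
            telomeric.add(y)
            continue
        for a, b in ((x, y), (y, x)):
            if a in partner:
                raise GenomeError(
                    f"extremity {fmt_extremity(a)} appears in two adjacencies"
                )
            partner[a] = b

    visited: set[int] = set()
    chromosomes: list[Chromosome] = []

    def walk(start: Extremity) -> tuple[list[int], bool]:
        """Follow gene/adjacency alternation from a starting extremity."""
        genes: list[int] = []
        ext = start
        while True:
            gene, end = ext
            genes.append(gene if end == "t" else -gene)
            visited.add(gene)
            nxt = other_end(ext)
            if nxt in telomeric or nxt not in partner:
                return genes, False
            ext = partner[nxt]
            if abs(genes[0]) == ext[0] and (
                (genes[0] > 0 and ext[1] == "t") or (genes[0] < 0 and ext[1] == "h")
            ):
                return genes, True

    for ext in sorted(telomeric):
        if ext[0] in visited:
            continue
        genes, circular = walk(ext)
        if circular:
            raise GenomeError(f"telomeric extremity {fmt_extremity(ext)} inside a cycle")
        chromosomes.append(Chromosome(tuple(genes), False).canonical())
    for gene in sorted(genome.genes):
        if gene in visited:
            continue
        genes, circular = walk(tail(gene))
        if not circular:
            raise GenomeError(f"gene {gene} lies on an unterminated path")
        chromosomes.append(Chromosome(tuple(genes), True).canonical())
    return sorted(chromosomes, key=lambda c: (abs(c.genes[0]), c.circular))


# ---------------------------------------------------------------------------
# GRIMM-style reading and writing
# ---------------------------------------------------------------------------

def parse_genomes(text: str) -> list[Genome]:
    """Parse a GRIMM-style multi-genome document.

    Format: ``>name`` headers followed by chromosome lines of signed
    integers terminated by ``$`` (linear) or ``@`` (circular).  Lines
    starting with ``#`` are comments.
    """
    genomes: list[Genome] = []
    name: str | None = None
    chroms: list[Chromosome] = []

    def flush() -> None:
        nonlocal chroms
        if name is not None:
            genomes.append(Genome.from_chromosomes(name, chroms))
        chroms = []

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith(">"):
            flush()
            name = line[1:].strip()
            if not name:
                raise GenomeError(f"line {lineno}: empty genome name")
            continue
        if name is None:
            raise GenomeError(f"line {lineno}: chromosome before any '>' header")
        if not line.endswith(("$", "@")):
            raise GenomeError(f"line {lineno}: chromosome must end in '$' or '@'")
        circular = line.endswith("@")
        body = line[:-1].strip()
        if not body:
            raise GenomeError(f"line {lineno}: empty chromosome")
        try:
            genes = tuple(int(tok) for tok in body.split())
        except ValueError as exc:
            raise GenomeError(f"line {lineno}: malformed gene list") from exc
        if any(g == 0 for g in genes):
            raise GenomeError(f"line {lineno}: gene id 0 is reserved")
        chroms.append(Chromosome(genes, circular))
    flush()
    if not genomes:
        raise GenomeError("document contains no '>' header")
    return genomes


def write_genomes(genomes: Iterable[Genome]) -> str:
    """Serialize genomes back to GRIMM text (canonical chromosome forms)."""
    out: list[str] = []
    for genome in genomes:
        out.append(f">{genome.name}")
        for chrom in genome.chromosomes():
            marker = "@" if chrom.circular else "$"
            out.append(" ".join(str(g) for g in chrom.genes) + f" {marker}")
    return "\n".join(out) + "\n"


def iter_gene_orders(genome: Genome) -> Iterator[tuple[tuple[int, ...], bool]]:
    for chrom in genome.chromosomes():
        yield chrom.genes, chrom.circular
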