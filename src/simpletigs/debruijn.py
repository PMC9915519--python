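"""k-spectra and arc-centric de Bruijn graphs.

The k-spectrum of a genome is the *set* of its length-k substrings
(multiplicity discarded); circular chromosomes contribute their wrap-around
k-mers.  The arc-centric de Bruijn graph of a spectrum ``S_k`` has node set
``S_{k-1}`` (every (k-1)-mer occurring as a prefix or suffix of a spectrum
k-mer) and exactly one arc per k-mer, from its (k-1)-prefix to its
(k-1)-suffix.  A walk spells a string by writing its first node and then
appending the last character of each subsequent node.

The graph here is single stranded: reverse complements are never added.
Double-stranded assembly graphs enter the library through
:func:`simpletigs.graph_model.double_graph` instead.

String coordinates in error messages are 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .graph_model import Graph, GraphError, Walk

ALPHABET = "ACGT"


class GenomeError(ValueError):
    """Malformed genome or infeasible k."""


@dataclass(frozen=True)
class Chromosome:
    name: str
    sequence: str
    circular: bool = False

    def __post_init__(self) -> None:
        if not self.sequence:
            raise GenomeError(f"chromosome {self.name!r} is empty")
        bad = set(self.sequence) - set(ALPHABET)
        if bad:
            raise GenomeError(
                f"chromosome {self.name!r} contains non-ACGT characters {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Genome:
    """A genome: named chromosomes, each linear or circular."""

    chromosomes: tuple[Chromosome, ...]

    def __post_init__(self) -> None:
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise GenomeError("duplicate chromosome names")

    @classmethod
    def from_sequences(cls, sequences, circular: bool = False) -> "Genome":
        """Build a genome from bare sequences, naming them ``chr1, chr2, ...``."""
        return cls(tuple(
            Chromosome(f"chr{i + 1}", s, circular=circular)
            for i, s in enumerate(sequences)
        ))

    def __iter__(self):
        return iter(self.chromosomes)


@dataclass(frozen=True)
class KSpectrum:
    k: int
    kmers: frozenset[str]

    def __post_init__(self) -> None:
        if self.k < 2:
            raise GenomeError(f"k must be >= 2, got {self.k}")
        for x in self.kmers:
            if len(x) != self.k:
                raise GenomeError(f"spectrum member {x!r} has length != k={self.k}")

    def __len__(self) -> int:
        return len(self.kmers)


@dataclass(frozen=True)
class BoundarySet:
    """The set L of first/last (k-1)-mers of the linear chromosomes."""

    members: frozenset[str]

    def __contains__(self, item: str) -> bool:
        return item in self.members

    def __len__(self) -> int:
        return len(self.members)


def _check_k(genome: Genome, k: int) -> None:
    if k < 2:
        raise GenomeError(f"k must be >= 2, got {k}")
    for chrom in genome:
        if len(chrom) < k:
            raise GenomeError(
                f"chromosome {chrom.name!r} (length {len(chrom)}) is shorter than k={k}"
            )


def k_spectrum(genome: Genome, k: int) -> KSpectrum:
    """Set of length-k substrings of the genome, wrap-around for circular."""
    _check_k(genome, k)
    kmers: set[str] = set()
    for chrom in genome:
        s = chrom.sequence
        if chrom.circular:
            t = s + s[:k - 1]
            kmers.update(t[i:i + k] for i in range(len(s)))
        else:
            kmers.update(s[i:i + k] for i in range(len(s) - k + 1))
    return KSpectrum(k, frozenset(kmers))


def boundary_set(genome: Genome, k: int) -> BoundarySet:
    """First and last (k-1)-mers of each linear chromosome.

    Circular chromosomes contribute nothing (they have no ends), so the set
    is empty for an all-circular genome.
    """
    _check_k(genome, k)
    members: set[str] = set()
    for chrom in genome:
        if chrom.circular:
            continue
        s = chrom.sequence
        members.add(s[:k - 1])
        members.add(s[len(s) - k + 1:])
    return BoundarySet(frozenset(members))


def build_dbg(spectrum: KSpectrum) -> Graph:
    """Arc-centric de Bruijn graph of a k-spectrum.

    Nodes carry their (k-1)-mer string as payload, arcs are created in
    sorted k-mer order (one per spectrum member), so construction is
    deterministic.
    """
    if not spectrum.kmers:
        raise GenomeError("cannot build a de Bruijn graph from an empty spectrum")
    g = Graph()
    node_of: dict[str, int] = {}
    kmers = sorted(spectrum.kmers)
    for x in kmers:
        for mer in (x[:-1], x[1:]):
            if mer not in node_of:
                node_of[mer] = g.add_node(mer)
    # second pass keeps node ids in first-occurrence order of sorted k-mers
    for x in kmers:
        g.add_arc(node_of[x[:-1]], node_of[x[1:]])
    return g


def spell(walk: Walk, g: Graph, cyclic: bool = False) -> str:
    """Spell the string of a walk in a de Bruijn graph.

    The result has length ``(k-1) + (l-1)``.  With ``cyclic=True`` (only
    valid for circular walks) the ``(l-1)``-length cyclic representative is
    returned instead: the linear spelling with the wrap-duplicated final
    ``k-1`` characters dropped.
    """
    walk.validate(g)
    first = g.node_payload(walk.nodes[0])
    if not isinstance(first, str):
        raise GraphError("spell requires (k-1)-mer string payloads")
    out = [first]
    for v in walk.nodes[1:]:
        payload = g.node_payload(v)
        if not isinstance(payload, str):
            raise GraphError("spell requires (k-1)-mer string payloads")
        out.append(payload[-1])
    s = "".join(out)
    if cyclic:
        if not walk.circular:
            raise GraphError("cyclic spelling requires a circular walk")
        return s[:len(walk) - 1]
    return s


def walk_of_chromosome(chrom: Chromosome, k: int, g: Graph) -> Walk:
    """Reconstruct the walk a chromosome traces through its de Bruijn graph.

    Used by invariants/tests: follows the chromosome's consecutive k-mers,
    picking for each the arc whose endpoints carry the right payloads.
    """
    s = chrom.sequence + (chrom.sequence[:k - 1] if chrom.circular else "")
    n_kmers = len(chrom) if chrom.circular else len(chrom) - k + 1
    start = g.find_node(s[:k - 1])
    if start is None:
        raise GraphError("chromosome start (k-1)-mer absent from graph")
    nodes = [start]
    arcs = []
    for i in range(n_kmers):
        suffix = s[i + 1:i + k]
        for aid in g.out_arcs(nodes[-1]):
            if g.node_payload(g.arc(aid).head) == suffix:
                arcs.append(aid)
                nodes.append(g.arc(aid).head)
                break
        else:
            raise GraphError(
                f"no arc spelling k-mer at position {i + 1} of {chrom.name!r}"
            )
    return Walk(tuple(nodes), tuple(arcs), circular=chrom.circular)
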