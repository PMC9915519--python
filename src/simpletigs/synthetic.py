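"""Seeded generators of test genomes and graphs.

The generators emulate the genome structures the tig algorithms are
designed around: tandem-free exact repeats with unique flanks (two copies
of a unit ``R`` in one chromosome, ``X R Y R Z``) and bubbles (a diploid
style pair ``A B C`` / ``A D C`` emitted as two chromosomes).  Feature
coordinates are recorded in a manifest.  Generation is a pure function of
the spec: the same spec always yields byte-identical output.

Uniqueness of the non-repeat portions is enforced, for a caller-supplied
``unique_k``, by rejection sampling: a draw is rejected when some
(k-1)-mer occurs twice outside the planted feature.  This guarantees the
repeat/bubble appears in the de Bruijn graph exactly as designed (branching
only at the planted structure).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Union

from .debruijn import ALPHABET, Chromosome, Genome
from .graph_model import BidirectedGraph, Graph


class GenerationError(ValueError):
    """Infeasible generator spec."""


@dataclass(frozen=True)
class RepeatFeature:
    """An exact repeat: ``copies`` copies of a random unit, separated and
    flanked by random unique sequence."""

    copies: int = 2
    unit_length: int = 30
    flank_length: int = 50


@dataclass(frozen=True)
class BubbleFeature:
    """Two chromosomes sharing flanks around divergent arms (B != D)."""

    arm_length: int = 20
    flank_length: int = 50


Feature = Union[RepeatFeature, BubbleFeature]

_MAX_ATTEMPTS = 1000


@dataclass(frozen=True)
class GenomeSpec:
    """Declarative description of a synthetic genome.

    ``n_chromosomes`` plain random chromosomes with lengths drawn from
    ``length_range`` are generated first; every planted feature then adds
    its own dedicated chromosome(s).  ``unique_k`` switches on rejection
    sampling so that no (k-1)-mer repeats outside planted features.
    """

    n_chromosomes: int = 1
    length_range: tuple[int, int] = (200, 200)
    circular: bool = False
    alphabet: str = ALPHABET
    features: tuple[Feature, ...] = ()
    seed: int = 0
    unique_k: int | None = None


def random_sequence(rng: random.Random, length: int, alphabet: str = ALPHABET) -> str:
    return "".join(rng.choice(alphabet) for _ in range(length))


def _kmer_positions(seqs: list[str], k1: int) -> dict[str, list[tuple[int, int]]]:
    occ: dict[str, list[tuple[int, int]]] = {}
    for ci, s in enumerate(seqs):
        for p in range(len(s) - k1 + 1):
            occ.setdefault(s[p:p + k1], []).append((ci, p))
    return occ


def _only_repeats_inside(seqs: list[str], allowed: list[list[tuple[int, int]]],
                         k1: int) -> bool:
    """True if every duplicated (k-1)-mer lies entirely inside an allowed
    span on each of its occurrences.  ``allowed[ci]`` lists (start, end)
    half-open spans for chromosome ``ci``."""
    for positions in _kmer_positions(seqs, k1).values():
        if len(positions) == 1:
            continue
        for ci, p in positions:
            if not any(a <= p and p + k1 <= b for a, b in allowed[ci]):
                return False
    return True


def _make_repeat_chromosome(rng: random.Random, feat: RepeatFeature,
                            unique_k: int | None) -> tuple[str, list[dict]]:
    if feat.copies < 2:
        raise GenerationError("a repeat needs at least two copies")
    for _ in range(_MAX_ATTEMPTS):
        unit = random_sequence(rng, feat.unit_length)
        parts = [random_sequence(rng, feat.flank_length)]
        spans = []
        pos = feat.flank_length
        for _c in range(feat.copies):
            parts.append(unit)
            spans.append((pos, pos + feat.unit_length))
            parts.append(random_sequence(rng, feat.flank_length))
            pos += feat.unit_length + feat.flank_length
        seq = "".join(parts)
        if unique_k is None:
            break
        k1 = unique_k - 1
        if _only_repeats_inside([seq], [[s for s in spans]], k1):
            break
    else:
        raise GenerationError(
            "could not generate a repeat chromosome with unique flanks "
            f"in {_MAX_ATTEMPTS} attempts"
        )
    features = [{"type": "repeat", "unit_length": feat.unit_length,
                 "copies": [{"start": a, "end": b} for a, b in spans]}]
    return seq, features


def _make_bubble_chromosomes(rng: random.Random, feat: BubbleFeature,
                             unique_k: int | None) -> tuple[list[str], list[dict]]:
    for _ in range(_MAX_ATTEMPTS):
        a = random_sequence(rng, feat.flank_length)
        c = random_sequence(rng, feat.flank_length)
        b = random_sequence(rng, feat.arm_length)
        d = random_sequence(rng, feat.arm_length)
        if b == d:
            continue
        s1 = a + b + c
        s2 = a + d + c
        if unique_k is None:
            break
        k1 = unique_k - 1
        # duplicates are only allowed inside the shared flanks A and C
        shared = [(0, feat.flank_length),
                  (feat.flank_length + feat.arm_length, len(s1))]
        if _only_repeats_inside([s1, s2], [shared, shared], k1):
            break
    else:
        raise GenerationError(
            "could not generate a bubble with unique arms "
            f"in {_MAX_ATTEMPTS} attempts"
        )
    features = [{"type": "bubble", "arm_length": feat.arm_length,
                 "shared_prefix": {"start": 0, "end": feat.flank_length},
                 "arm": {"start": feat.flank_length,
                         "end": feat.flank_length + feat.arm_length},
                 "shared_suffix": {"start": feat.flank_length + feat.arm_length,
                                   "end": len(s1)}}]
    return [s1, s2], features


def generate_genome(spec: GenomeSpec) -> tuple[Genome, dict]:
    """Generate a genome and its manifest from a spec (deterministic)."""
    lo, hi = spec.length_range
    if lo < 1 or hi < lo:
        raise GenerationError(f"invalid length range {spec.length_range}")
    rng = random.Random(spec.seed)
    chroms: list[Chromosome] = []
    manifest_chroms: list[dict] = []

    def _add(seq: str, circular: bool, features: list[dict]) -> None:
        name = f"chr{len(chroms) + 1}"
        chroms.append(Chromosome(name, seq, circular=circular))
        manifest_chroms.append({
            "name": name, "length": len(seq), "circular": circular,
            "features": features,
        })

    for _ in range(spec.n_chromosomes):
        length = rng.randint(lo, hi)
        _add(random_sequence(rng, length, spec.alphabet), spec.circular, [])

    for feat in spec.features:
        if isinstance(feat, RepeatFeature):
            seq, features = _make_repeat_chromosome(rng, feat, spec.unique_k)
            _add(seq, spec.circular, features)
        elif isinstance(feat, BubbleFeature):
            seqs, features = _make_bubble_chromosomes(rng, feat, spec.unique_k)
            _add(seqs[0], spec.circular, features)
            _add(seqs[1], spec.circular, features)
        else:
            raise GenerationError(f"unknown feature {feat!r}")

    manifest = {"seed": spec.seed, "unique_k": spec.unique_k,
                "chromosomes": manifest_chroms}
    return Genome(tuple(chroms)), manifest


def generate_random_graph(n: int, m: int, seed: int) -> Graph:
    """Uniform random directed multigraph: ``m`` arcs sampled with
    replacement over ordered node pairs (self-loops and parallels allowed)."""
    if n < 1:
        raise GenerationError("need at least one node")
    if m < 0:
        raise GenerationError("negative arc count")
    rng = random.Random(seed)
    g = Graph()
    for i in range(n):
        g.add_node(f"v{i}")
    for _ in range(m):
        g.add_arc(rng.randrange(n), rng.randrange(n))
    return g


def generate_random_bidirected(n_segments: int, n_links: int, seed: int) -> BidirectedGraph:
    """Uniform random bidirected graph for doubled-graph testing."""
    if n_segments < 1:
        raise GenerationError("need at least one segment")
    rng = random.Random(seed)
    bg = BidirectedGraph()
    names = [f"s{i}" for i in range(n_segments)]
    for name in names:
        bg.add_segment(name)
    for _ in range(n_links):
        bg.add_link(rng.choice(names), rng.choice("+-"),
                    rng.choice(names), rng.choice("+-"), "0M")
    return bg


def fixtures() -> dict[str, Graph]:
    """The two worked repeat/bubble graphs used throughout the tests.

    ``G1`` is the two-copy-repeat graph (each genome-level block drawn as a
    length-two path): blocks ``a``, ``r``, ``b``, ``c`` with the repeat
    block ``r`` entered from ``a`` and from ``b`` and left toward ``b`` and
    ``c``.  ``G2`` is the bubble graph: shared flank ``a``, arms ``b`` and
    ``d``, shared flank ``c``.  Node payloads are the block names.
    """
    g1 = Graph()
    ids1 = {name: g1.add_node(name)
            for name in ("a1", "a2", "r1", "r2", "b1", "b2", "c1", "c2")}
    for t, h in (("a1", "a2"), ("a2", "r1"), ("r1", "r2"), ("r2", "b1"),
                 ("b1", "b2"), ("b2", "r1"), ("r2", "c1"), ("c1", "c2")):
        g1.add_arc(ids1[t], ids1[h])

    g2 = Graph()
    ids2 = {name: g2.add_node(name)
            for name in ("a1", "a2", "b1", "b2", "c1", "c2", "d1", "d2")}
    for t, h in (("a1", "a2"), ("a2", "b1"), ("a2", "d1"), ("b1", "b2"),
                 ("b2", "c1"), ("d1", "d2"), ("d2", "c1"), ("c1", "c2")):
        g2.add_arc(ids2[t], ids2[h])

    return {"G1": g1, "G2": g2}
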