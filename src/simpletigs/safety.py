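"""Safety verification for unitigs and simple omnitigs.

A walk of an error-free, perfect-coverage de Bruijn graph is *safe* if its
spelled string occurs in the genome the graph was built from.  For a genome
of linear chromosomes, a simple omnitig is guaranteed safe whenever none of
its inner nodes belongs to the boundary set ``L`` (the first/last
(k-1)-mers of the chromosomes); for a single circular chromosome every
simple omnitig is safe.  The converse does not hold: omnitigs touching
chromosome ends can still be safe under graph-topology conditions not
modelled here, so non-applicable walks are reported, never asserted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .debruijn import (Genome, boundary_set, build_dbg, k_spectrum, spell)
from .graph_model import Walk
from .tigs import maximal_simple_omnitigs, maximal_unitigs


@dataclass(frozen=True)
class WalkSafety:
    """Safety record for one walk."""

    walk_id: int
    walk: Walk
    spelled: str
    applicable: bool  # no inner node in the boundary set L
    safe: bool        # spelled string occurs in some chromosome
    witness_chr: str | None = None
    witness_offset: int | None = None


@dataclass(frozen=True)
class SafetyReport:
    records: tuple[WalkSafety, ...]
    #: when True every walk must be safe (unitigs); otherwise only
    #: applicable walks carry the guarantee (simple omnitigs)
    require_all_safe: bool = False

    @property
    def violations(self) -> tuple[WalkSafety, ...]:
        if self.require_all_safe:
            return tuple(r for r in self.records if not r.safe)
        return tuple(r for r in self.records if r.applicable and not r.safe)

    @property
    def ok(self) -> bool:
        return not self.violations


def is_substring(s: str, genome: Genome) -> tuple[bool, tuple[str, int] | None]:
    """Occurrence test against linear and circular chromosomes.

    Circular chromosomes are tested rotation-aware: the pattern is searched
    in a periodic extension of the chromosome and must start within the
    first period; the reported offset is modulo the chromosome length.
    """
    for chrom in genome:
        c = chrom.sequence
        if chrom.circular:
            if len(s) > 1:
                reps = 1 + (len(s) - 1 + len(c) - 1) // len(c)
            else:
                reps = 1
            idx = (c * reps).find(s)
            if 0 <= idx < len(c):
                return True, (chrom.name, idx % len(c))
        else:
            idx = c.find(s)
            if idx >= 0:
                return True, (chrom.name, idx)
    return False, None


def _report(genome: Genome, k: int, walks, require_all_safe: bool) -> SafetyReport:
    spectrum = k_spectrum(genome, k)
    g = build_dbg(spectrum)
    L = boundary_set(genome, k)
    records = []
    for wid, walk in enumerate(walks(g)):
        spelled = spell(walk, g)
        inner = walk.nodes[1:-1]
        applicable = all(g.node_payload(v) not in L for v in inner)
        safe, witness = is_substring(spelled, genome)
        records.append(WalkSafety(
            walk_id=wid, walk=walk, spelled=spelled,
            applicable=applicable, safe=safe,
            witness_chr=witness[0] if witness else None,
            witness_offset=witness[1] if witness else None,
        ))
    return SafetyReport(tuple(records), require_all_safe=require_all_safe)


def check_boundary_safety(genome: Genome, k: int) -> SafetyReport:
    """Verify the boundary-set safety guarantee for simple omnitigs.

    Builds the de Bruijn graph of the genome's k-spectrum, enumerates the
    maximal simple omnitigs and records, per walk, whether its inner nodes
    avoid ``L`` (``applicable``) and whether its spelled string occurs in
    the genome (``safe``).  ``report.violations`` lists applicable-but-
    unsafe walks, which the safety guarantee forbids.
    """
    if not genome.chromosomes:
        return SafetyReport(())
    return _report(
        genome, k,
        lambda g: (so.walk for so in maximal_simple_omnitigs(g)),
        require_all_safe=False,
    )


def unitig_safety_check(genome: Genome, k: int) -> SafetyReport:
    """Baseline comparator: every maximal unitig of an error-free
    perfect-coverage de Bruijn graph must be safe."""
    if not genome.chromosomes:
        return SafetyReport((), require_all_safe=True)
    return _report(
        genome, k,
        lambda g: (u.walk for u in maximal_unitigs(g)),
        require_all_safe=True,
    )
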