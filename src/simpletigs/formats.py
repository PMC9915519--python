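"""Readers and writers for the plain-text formats the CLI consumes.

FASTA goes through Biopython; GFA1 (S/L subset) and PAF are simple
line-oriented TSV formats parsed directly.  Coordinates are 0-based
half-open everywhere, the PAF/BED convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .contiguity import AlignmentRecord
from .debruijn import Chromosome, Genome
from .graph_model import BidirectedGraph, Graph, GraphError

log = logging.getLogger("simpletigs")


class FormatError(ValueError):
    """Malformed input file."""


# ----------------------------------------------------------------------
# FASTA


@dataclass(frozen=True)
class FastaRecord:
    name: str
    sequence: str
    tags: dict[str, str] = field(default_factory=dict)


def _parse_tags(description: str) -> dict[str, str]:
    tags = {}
    for token in description.split()[1:]:
        if "=" in token:
            key, _, value = token.partition("=")
            tags[key] = value
    return tags


def read_fasta(path: str | Path) -> list[FastaRecord]:
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise FormatError(
                        f"{path}:{lineno}: expected a FASTA header, got {line.strip()!r}"
                    )
                break
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(FastaRecord(rec.id, str(rec.seq).upper(),
                                   _parse_tags(rec.description)))
    return records


def write_fasta(records, path: str | Path, width: int = 80) -> None:
    seq_records = []
    for rec in records:
        description = " ".join(f"{k}={v}" for k, v in rec.tags.items())
        seq_records.append(SeqRecord(Seq(rec.sequence), id=rec.name,
                                     description=description))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


def genome_from_fasta(path: str | Path, default_circular: bool = False) -> Genome:
    """Read a genome; per-record ``circular=true`` header tags override the
    default topology."""
    chroms = []
    for rec in read_fasta(path):
        tag = rec.tags.get("circular")
        circular = default_circular if tag is None else tag.lower() == "true"
        chroms.append(Chromosome(rec.name, rec.sequence, circular=circular))
    return Genome(tuple(chroms))


def genome_to_fasta(genome: Genome, path: str | Path) -> None:
    write_fasta(
        [FastaRecord(c.name, c.sequence,
                     {"circular": "true"} if c.circular else {})
         for c in genome],
        path,
    )


# ----------------------------------------------------------------------
# GFA1 (S/L subset)


def read_gfa(path: str | Path) -> BidirectedGraph:
    path = Path(path)
    bg = BidirectedGraph()
    pending_links = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("H"):
                continue
            fields = line.split("\t")
            if fields[0] == "S":
                if len(fields) < 3:
                    raise FormatError(f"{path}:{lineno}: S line needs name and sequence")
                name, seq = fields[1], fields[2]
                bg.add_segment(name, None if seq == "*" else seq.upper())
            elif fields[0] == "L":
                if len(fields) < 6:
                    raise FormatError(f"{path}:{lineno}: L line needs 6 fields")
                pending_links.append((lineno, fields[1], fields[2], fields[3],
                                      fields[4], fields[5]))
            else:
                log.warning("%s:%d: skipping unsupported record type %r",
                            path, lineno, fields[0])
    for lineno, a, oa, b, ob, overlap in pending_links:
        for seg in (a, b):
            if seg not in bg.segments:
                raise FormatError(
                    f"{path}:{lineno}: link references unknown segment {seg!r}"
                )
        bg.add_link(a, oa, b, ob, overlap)
    return bg


def write_gfa(bg: BidirectedGraph, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("H\tVN:Z:1.0\n")
        for name, seq in bg.segments.items():
            fh.write(f"S\t{name}\t{seq if seq is not None else '*'}\n")
        for a, oa, b, ob, overlap in bg.links:
            fh.write(f"L\t{a}\t{oa}\t{b}\t{ob}\t{overlap}\n")


def graph_to_gfa(g: Graph, path: str | Path, overlap: str = "*") -> None:
    """Export a plain directed graph as GFA.

    Node payloads become segment names/sequences: a ``(segment, orient)``
    payload (doubled graph) is written as ``<segment><orient>`` with no
    sequence, a string payload as a segment carrying that string as its
    sequence, and anything else by node id.  Arcs become ``+/+`` links.
    """
    def seg_name(v: int) -> str:
        payload = g.node_payload(v)
        if isinstance(payload, tuple) and len(payload) == 2:
            return f"{payload[0]}{payload[1]}"
        if isinstance(payload, str):
            return payload
        return f"n{v}"

    with open(path, "w") as fh:
        fh.write("H\tVN:Z:1.0\n")
        for v in g.nodes:
            payload = g.node_payload(v)
            seq = payload if isinstance(payload, str) and set(payload) <= set("ACGT") \
                else None
            fh.write(f"S\t{seg_name(v)}\t{seq if seq is not None else '*'}\n")
        for a in g.arcs:
            fh.write(f"L\t{seg_name(a.tail)}\t+\t{seg_name(a.head)}\t+\t{overlap}\n")


def dbg_to_gfa(g: Graph, path: str | Path) -> None:
    """Export a de Bruijn graph: (k-1)-mer segments, (k-2)M overlaps."""
    payload = g.node_payload(0)
    if not isinstance(payload, str):
        raise GraphError("not a de Bruijn graph (payloads are not k-mer strings)")
    graph_to_gfa(g, path, overlap=f"{len(payload) - 1}M")


# ----------------------------------------------------------------------
# PAF


def read_paf(path: str | Path) -> list[AlignmentRecord]:
    """Parse >=12-column PAF; keeps query name and the target block
    (columns 6-9: name, length, start, end)."""
    path = Path(path)
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise FormatError(
                    f"{path}:{lineno}: PAF needs >= 12 columns, got {len(fields)}"
                )
            query = fields[0]
            target, tlen, tstart, tend = fields[5], int(fields[6]), \
                int(fields[7]), int(fields[8])
            if tend > tlen:
                raise FormatError(
                    f"{path}:{lineno}: target end {tend} exceeds target length {tlen}"
                )
            records.append(AlignmentRecord(query, target, tstart, tend))
    return records


def read_paf_target_lengths(path: str | Path) -> dict[str, int]:
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) >= 12:
                lengths[fields[5]] = int(fields[6])
    return lengths


# ----------------------------------------------------------------------
# misassembly positions (2-column TSV: reference, position)


def read_positions_tsv(path: str | Path) -> dict[str, list[int]]:
    path = Path(path)
    by_ref: dict[str, list[int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(
                    f"{path}:{lineno}: expected 'reference<TAB>position'"
                )
            by_ref.setdefault(fields[0], []).append(int(fields[1]))
    for positions in by_ref.values():
        positions.sort()
    return by_ref
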