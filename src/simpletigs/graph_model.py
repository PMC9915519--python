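"""Directed-multigraph model for assembly-graph algorithms.

The model is arc-centric: nodes are dense opaque integers ``0..n-1`` with an
optional payload (a ``(k-1)``-mer string for de Bruijn graphs, a
``(segment, orientation)`` pair for doubled graphs), and arcs are dense
integers ``0..m-1``.  Parallel arcs and self-loops are first class, and a
self-loop counts once toward the in-degree and once toward the out-degree of
its node, matching the multiset semantics of the arc set ``E``.

Walks store both their node sequence and their arc sequence, so that walks
through parallel arcs are unambiguous.

Bidirected graphs (GFA segments + links) are converted to plain directed
"doubled" graphs: each segment ``s`` becomes two nodes ``s+`` and ``s-``,
and each link ``(a, oa, b, ob)`` becomes the arc ``a^oa -> b^ob`` together
with its mirror ``b^flip(ob) -> a^flip(oa)``.  The conversion records the
node/arc mirror maps on the resulting :class:`Graph` so that downstream
algorithms can pair each walk with its reverse complement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterator


class GraphError(ValueError):
    """Invalid graph query or malformed walk."""


@dataclass(frozen=True)
class Arc:
    """A directed arc with a dense integer identity."""

    id: int
    tail: int
    head: int


class Graph:
    """A directed multigraph with payload-carrying nodes.

    Node and arc identifiers are opaque integers assigned densely in
    insertion order; payloads are attached but never used for graph
    semantics.
    """

    __slots__ = ("_payloads", "_arcs", "_out", "_in", "mirror_node", "mirror_arc")

    def __init__(self) -> None:
        self._payloads: list[Any] = []
        self._arcs: list[Arc] = []
        self._out: list[list[int]] = []
        self._in: list[list[int]] = []
        #: populated by :func:`double_graph`; ``None`` for plain graphs
        self.mirror_node: dict[int, int] | None = None
        self.mirror_arc: dict[int, int] | None = None

    # ------------------------------------------------------------------
    # construction

    def add_node(self, payload: Any = None) -> int:
        self._payloads.append(payload)
        self._out.append([])
        self._in.append([])
        return len(self._payloads) - 1

    def add_arc(self, tail: int, head: int) -> int:
        self._check_node(tail)
        self._check_node(head)
        aid = len(self._arcs)
        self._arcs.append(Arc(aid, tail, head))
        self._out[tail].append(aid)
        self._in[head].append(aid)
        return aid

    # ------------------------------------------------------------------
    # queries

    @property
    def n(self) -> int:
        return len(self._payloads)

    @property
    def m(self) -> int:
        return len(self._arcs)

    @property
    def nodes(self) -> range:
        return range(self.n)

    @property
    def arcs(self) -> tuple[Arc, ...]:
        return tuple(self._arcs)

    def arc(self, aid: int) -> Arc:
        if not 0 <= aid < len(self._arcs):
            raise GraphError(f"unknown arc id {aid!r}")
        return self._arcs[aid]

    def node_payload(self, v: int) -> Any:
        self._check_node(v)
        return self._payloads[v]

    def find_node(self, payload: Any) -> int | None:
        """First node carrying ``payload``, or ``None``."""
        try:
            return self._payloads.index(payload)
        except ValueError:
            return None

    def out_arcs(self, v: int) -> tuple[int, ...]:
        self._check_node(v)
        return tuple(self._out[v])

    def in_arcs(self, v: int) -> tuple[int, ...]:
        self._check_node(v)
        return tuple(self._in[v])

    def out_degree(self, v: int) -> int:
        self._check_node(v)
        return len(self._out[v])

    def in_degree(self, v: int) -> int:
        self._check_node(v)
        return len(self._in[v])

    def is_split(self, v: int) -> bool:
        """A split has at least two outgoing arcs."""
        return self.out_degree(v) >= 2

    def is_join(self, v: int) -> bool:
        """A join has at least two incoming arcs."""
        return self.in_degree(v) >= 2

    def _check_node(self, v: int) -> None:
        if not isinstance(v, int) or not 0 <= v < len(self._payloads):
            raise GraphError(f"unknown node {v!r}")

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Graph(n={self.n}, m={self.m})"


# ----------------------------------------------------------------------
# walks


@dataclass(frozen=True)
class Walk:
    """A walk ``(w_1, ..., w_l)`` with its arc sequence.

    ``tail`` is ``w_1`` and ``head`` is ``w_l``.  A circular walk has
    ``w_1 == w_l`` and ``l >= 2``; it represents a closed traversal broken
    at ``w_1`` for storage.
    """

    nodes: tuple[int, ...]
    arcs: tuple[int, ...] = ()
    circular: bool = False

    def __post_init__(self) -> None:
        if len(self.nodes) < 1:
            raise GraphError("a walk has at least one node")
        if len(self.arcs) != len(self.nodes) - 1:
            raise GraphError(
                f"walk with {len(self.nodes)} nodes needs "
                f"{len(self.nodes) - 1} arcs, got {len(self.arcs)}"
            )
        if self.circular and (len(self.nodes) < 2 or self.nodes[0] != self.nodes[-1]):
            raise GraphError("a circular walk has w_1 == w_l and l >= 2")

    @property
    def tail(self) -> int:
        return self.nodes[0]

    @property
    def head(self) -> int:
        return self.nodes[-1]

    def __len__(self) -> int:
        return len(self.nodes)

    def validate(self, g: Graph) -> None:
        """Check every stored arc connects its consecutive node pair."""
        for u, v, aid in zip(self.nodes, self.nodes[1:], self.arcs):
            a = g.arc(aid)
            if a.tail != u or a.head != v:
                raise GraphError(
                    f"arc {aid} is {a.tail}->{a.head}, walk expects {u}->{v}"
                )

    @classmethod
    def from_arcs(cls, g: Graph, arc_ids: Iterator[int] | list[int],
                  circular: bool = False) -> "Walk":
        arc_ids = tuple(arc_ids)
        if not arc_ids:
            raise GraphError("from_arcs needs at least one arc")
        nodes = [g.arc(arc_ids[0]).tail]
        for aid in arc_ids:
            a = g.arc(aid)
            if a.tail != nodes[-1]:
                raise GraphError(f"arc {aid} does not continue the walk")
            nodes.append(a.head)
        return cls(tuple(nodes), arc_ids, circular=circular)


def concat(w1: Walk, w2: Walk) -> Walk:
    """Concatenate two walks sharing ``HEAD(w1) == TAIL(w2)``."""
    if w1.head != w2.tail:
        raise GraphError(
            f"cannot concatenate: head {w1.head} != tail {w2.tail}"
        )
    return Walk(w1.nodes + w2.nodes[1:], w1.arcs + w2.arcs)


def is_subwalk(small: Walk, big: Walk) -> bool:
    """True if ``small`` occurs as a contiguous subwalk of ``big``."""
    if len(small.nodes) == 1:
        return small.nodes[0] in big.nodes
    ls, lb = len(small.arcs), len(big.arcs)
    if ls > lb:
        return False
    return any(big.arcs[o:o + ls] == small.arcs for o in range(lb - ls + 1))


# ----------------------------------------------------------------------
# bidirected graphs and doubling

ORIENTATIONS = ("+", "-")


def flip_orientation(o: str) -> str:
    if o == "+":
        return "-"
    if o == "-":
        return "+"
    raise GraphError(f"invalid orientation {o!r}")


@dataclass
class BidirectedGraph:
    """GFA-style bidirected graph: named segments plus oriented links.

    Overlap strings (CIGAR) are stored verbatim and never interpreted;
    omnitig enumeration is topology-only.
    """

    segments: dict[str, str | None] = field(default_factory=dict)
    links: list[tuple[str, str, str, str, str]] = field(default_factory=list)

    def add_segment(self, name: str, sequence: str | None = None) -> None:
        self.segments[name] = sequence

    def add_link(self, a: str, oa: str, b: str, ob: str, overlap: str = "*") -> None:
        if oa not in ORIENTATIONS or ob not in ORIENTATIONS:
            raise GraphError(f"invalid link orientation {oa!r}/{ob!r}")
        self.links.append((a, oa, b, ob, overlap))


def double_graph(bg: BidirectedGraph) -> Graph:
    """Convert a bidirected graph to its doubled directed graph.

    Each segment ``s`` yields nodes with payloads ``(s, '+')`` and
    ``(s, '-')``.  Each link yields its forward arc and the mirror arc; the
    two coincide for palindromic links and are then emitted once.  Links
    that are reverse-complement duplicates of an earlier link are skipped,
    so the output is closed under the mirror symmetry without double
    arcs.
    """
    g = Graph()
    node_of: dict[tuple[str, str], int] = {}
    for name in bg.segments:
        node_of[(name, "+")] = g.add_node((name, "+"))
        node_of[(name, "-")] = g.add_node((name, "-"))
    mirror_node = {}
    for name in bg.segments:
        mirror_node[node_of[(name, "+")]] = node_of[(name, "-")]
        mirror_node[node_of[(name, "-")]] = node_of[(name, "+")]

    mirror_arc: dict[int, int] = {}
    seen: set[tuple[str, str, str, str]] = set()
    for a, oa, b, ob, _overlap in bg.links:
        if a not in bg.segments:
            raise GraphError(f"link references unknown segment {a!r}")
        if b not in bg.segments:
            raise GraphError(f"link references unknown segment {b!r}")
        fwd = (a, oa, b, ob)
        rev = (b, flip_orientation(ob), a, flip_orientation(oa))
        if min(fwd, rev) in seen:
            continue
        seen.add(min(fwd, rev))
        e1 = g.add_arc(node_of[(a, oa)], node_of[(b, ob)])
        if fwd == rev:  # palindromic link mirrors onto itself
            mirror_arc[e1] = e1
        else:
            e2 = g.add_arc(node_of[(rev[0], rev[1])], node_of[(rev[2], rev[3])])
            mirror_arc[e1] = e2
            mirror_arc[e2] = e1
    g.mirror_node = mirror_node
    g.mirror_arc = mirror_arc
    return g


def mirror_walk(g: Graph, w: Walk) -> Walk:
    """Reverse-complement image of a walk on a doubled graph."""
    if g.mirror_node is None or g.mirror_arc is None:
        raise GraphError("graph carries no mirror information (not doubled)")
    nodes = tuple(g.mirror_node[v] for v in reversed(w.nodes))
    arcs = tuple(g.mirror_arc[a] for a in reversed(w.arcs))
    return Walk(nodes, arcs, circular=w.circular)
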