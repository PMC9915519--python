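"""Maximal unitigs, cores, univocal extensions and maximal simple omnitigs.

A *unitig* is a walk whose inner nodes have in- and out-degree one; the
maximal unitigs partition the arc set.  For a walk ``W = (w_1..w_l)`` with
``l >= 2``, let ``w_i`` be its first inner join (or ``w_l`` if none) and
``w_j`` its last inner split (or ``w_1`` if none); the *core* of ``W`` is
the subwalk ``w_j..w_i`` when ``j < i``, and a *simple omnitig* is a walk
that has a core.  Equivalently, a simple omnitig is the univocal extension
of its core: every inner node left of the core has in-degree one and every
inner node right of it has out-degree one, so any walk through the core's
first arc that does not start or end strictly inside the omnitig must
contain the whole omnitig.

The enumeration algorithm runs in ``O(m + out)`` time: it iterates the
maximal unitigs and keeps exactly those whose endpoints satisfy the
core-of-maximal characterization —

(a) the core of the unitig is the unitig itself,
(b) if ``w_1`` has exactly one outgoing arc then it has no incoming arcs,
(c) if ``w_l`` has exactly one incoming arc then it has no outgoing arcs —

and outputs their univocal extensions.  A brute-force enumerator over all
bounded-length walks serves as an independent oracle for testing.

Cyclic degree-(1,1) regions admit no maximal simple omnitig in the strict
sense (walks can wind forever); the univocal extension therefore stops on
the first repeated arc per direction, and isolated cycles are reported once
as circular unitigs broken at their smallest node.  The brute-force oracle
applies the same once-per-region convention so the two routes are
comparable on arbitrary graphs.
"""

from __future__ import annotations

from dataclasses import dataclass

from .graph_model import Graph, GraphError, Walk, is_subwalk, mirror_walk


@dataclass(frozen=True)
class Unitig:
    walk: Walk
    maximal: bool = True
    circular: bool = False


@dataclass(frozen=True)
class CoreDecomposition:
    """Result of locating the core of a walk.

    ``j`` is the 1-based index of the last inner split (or 1), ``i`` the
    index of the first inner join (or ``l``); the core ``w_j..w_i`` exists
    iff ``j < i``.
    """

    walk: Walk
    j: int
    i: int
    has_core: bool
    core: Walk | None


@dataclass(frozen=True)
class SimpleOmnitig:
    walk: Walk
    core: Walk
    maximal: bool = True
    circular: bool = False


# ----------------------------------------------------------------------
# maximal unitigs


def _is_through(g: Graph, v: int) -> bool:
    return g.in_degree(v) == 1 and g.out_degree(v) == 1


def maximal_unitigs(g: Graph) -> list[Unitig]:
    """Partition the arcs of ``g`` into maximal unitigs.

    Non-circular unitigs start and end at branching nodes (split, join,
    source or sink).  Components that are pure degree-(1,1) cycles are
    returned once each as a circular unitig broken at the smallest node id.
    Output order is deterministic: sorted by first node id, then length,
    then arc ids.
    """
    used = [False] * g.m
    tigs: list[Unitig] = []

    for aid in range(g.m):
        a = g.arc(aid)
        if _is_through(g, a.tail):
            continue  # not a unitig start; reached by extension or a cycle
        nodes = [a.tail, a.head]
        arcs = [aid]
        used[aid] = True
        cur = a.head
        while _is_through(g, cur):
            nxt = g.out_arcs(cur)[0]
            if used[nxt]:  # safety net; cannot trigger on a valid partition
                break
            used[nxt] = True
            arcs.append(nxt)
            cur = g.arc(nxt).head
            nodes.append(cur)
        tigs.append(Unitig(Walk(tuple(nodes), tuple(arcs))))

    # leftover arcs lie on isolated degree-(1,1) cycles
    for aid in range(g.m):
        if used[aid]:
            continue
        cycle_arcs = [aid]
        used[aid] = True
        cur = g.arc(aid).head
        while cur != g.arc(aid).tail:
            nxt = g.out_arcs(cur)[0]
            used[nxt] = True
            cycle_arcs.append(nxt)
            cur = g.arc(nxt).head
        walk = _canonical_cycle(g, cycle_arcs)
        tigs.append(Unitig(walk, circular=True))

    tigs.sort(key=lambda u: (u.walk.nodes[0], len(u.walk), u.walk.arcs))
    return tigs


def _canonical_cycle(g: Graph, cycle_arcs: list[int]) -> Walk:
    """Rotate a closed arc sequence to start at its smallest node id."""
    tails = [g.arc(a).tail for a in cycle_arcs]
    start = tails.index(min(tails))
    rotated = cycle_arcs[start:] + cycle_arcs[:start]
    return Walk.from_arcs(g, rotated, circular=True)


# ----------------------------------------------------------------------
# cores


def core_decomposition(w: Walk, g: Graph) -> CoreDecomposition:
    """Locate the core of a walk (last inner split .. first inner join)."""
    if w.circular:
        raise GraphError("core decomposition is defined for non-circular walks")
    ell = len(w)
    if ell < 2:
        return CoreDecomposition(w, j=1, i=1, has_core=False, core=None)
    first_join = None
    last_split = None
    for idx in range(1, ell - 1):  # 0-based inner positions
        v = w.nodes[idx]
        if first_join is None and g.is_join(v):
            first_join = idx + 1
        if g.is_split(v):
            last_split = idx + 1
    i = first_join if first_join is not None else ell
    j = last_split if last_split is not None else 1
    has_core = j < i
    core = None
    if has_core:
        core = Walk(w.nodes[j - 1:i], w.arcs[j - 1:i - 1])
    return CoreDecomposition(w, j=j, i=i, has_core=has_core, core=core)


def is_simple_omnitig(w: Walk, g: Graph) -> bool:
    """A simple omnitig is a walk that has a core."""
    if w.circular or len(w) < 2:
        return False
    return core_decomposition(w, g).has_core


def _check_unitig(w: Walk, g: Graph) -> None:
    w.validate(g)
    for v in w.nodes[1:-1]:
        if not _is_through(g, v):
            raise GraphError(f"inner node {v} breaks the unitig property")


def is_core_of_maximal(u: Walk, g: Graph) -> bool:
    """Endpoint characterization: is this maximal unitig the core of a maximal
    simple omnitig?

    Conditions: (a) the core of the unitig is the unitig itself (automatic
    for unitigs of length >= 2), (b) if the first node has exactly one
    outgoing arc it has no incoming arcs, and (c) if the last node has
    exactly one incoming arc it has no outgoing arcs.

    A single-node unitig is accepted only if (b) and (c) hold and its
    univocal extension has length >= 2 and itself possesses a core; the
    defining core subwalk ``w_j..w_i`` with ``j < i`` always spans at least
    two nodes, so this case never produces new omnitigs from the arc
    partition.
    """
    if u.circular:
        raise GraphError("circular unitigs are excluded from core testing")
    _check_unitig(u, g)
    w1, wl = u.nodes[0], u.nodes[-1]
    cond_b = not (g.out_degree(w1) == 1 and g.in_degree(w1) > 0)
    cond_c = not (g.in_degree(wl) == 1 and g.out_degree(wl) > 0)
    if len(u) == 1:
        if not (cond_b and cond_c):
            return False
        ext = univocal_extension(u, g)
        return len(ext) >= 2 and core_decomposition(ext, g).has_core
    return cond_b and cond_c


# ----------------------------------------------------------------------
# univocal extension


def univocal_extension(w: Walk, g: Graph) -> Walk:
    """Extend a walk through unique out-arcs of its head and unique in-arcs
    of its tail.

    Each direction stops when the head (resp. tail) branches or when the
    arc to add was already added in that direction (cycle guard, which
    bounds the extension by O(m) per direction and cannot trigger on
    error-free graphs with branching flanks).
    """
    w.validate(g)
    nodes = list(w.nodes)
    arcs = list(w.arcs)
    used_fwd: set[int] = set()
    while g.out_degree(nodes[-1]) == 1:
        e = g.out_arcs(nodes[-1])[0]
        if e in used_fwd:
            break
        used_fwd.add(e)
        arcs.append(e)
        nodes.append(g.arc(e).head)
    used_bwd: set[int] = set()
    while g.in_degree(nodes[0]) == 1:
        e = g.in_arcs(nodes[0])[0]
        if e in used_bwd:
            break
        used_bwd.add(e)
        arcs.insert(0, e)
        nodes.insert(0, g.arc(e).tail)
    return Walk(tuple(nodes), tuple(arcs))


# ----------------------------------------------------------------------
# maximal simple omnitigs (linear output-sensitive algorithm)


def maximal_simple_omnitigs(g: Graph, dedup_rc: bool | None = None) -> list[SimpleOmnitig]:
    """All maximal simple omnitigs of ``g``.

    Iterates the maximal unitigs, keeps those passing
    :func:`is_core_of_maximal`, and emits their univocal extensions;
    isolated circular unitigs are passed through flagged circular.  On
    doubled graphs each walk and its reverse-complement mirror would both
    appear; by default (``dedup_rc=None``) the lexicographically smaller of
    each mirror pair is kept when the graph carries mirror maps.  Pass
    ``dedup_rc=False`` to keep both, ``True`` to force deduplication.
    """
    if dedup_rc is None:
        dedup_rc = g.mirror_node is not None
    results: list[SimpleOmnitig] = []
    seen: set[tuple[tuple[int, ...], tuple[int, ...]]] = set()
    for u in maximal_unitigs(g):
        if u.circular:
            so = SimpleOmnitig(u.walk, core=u.walk, circular=True)
        elif is_core_of_maximal(u.walk, g):
            so = SimpleOmnitig(univocal_extension(u.walk, g), core=u.walk)
        else:
            continue
        key = (so.walk.nodes, so.walk.arcs)
        if key not in seen:
            seen.add(key)
            results.append(so)

    if dedup_rc and g.mirror_node is not None:
        results = _dedup_mirror_pairs(g, results)

    results.sort(key=lambda s: (s.walk.nodes[0], len(s.walk), s.walk.arcs))
    return results


def _dedup_mirror_pairs(g: Graph, tigs: list[SimpleOmnitig]) -> list[SimpleOmnitig]:
    kept: list[SimpleOmnitig] = []
    dropped: set[tuple[tuple[int, ...], tuple[int, ...]]] = set()
    for so in tigs:
        key = (so.walk.nodes, so.walk.arcs)
        if key in dropped:
            continue
        mw = mirror_walk(g, so.walk)
        if mw.circular:
            mw = _canonical_cycle(g, list(mw.arcs))
        mkey = (mw.nodes, mw.arcs)
        if mkey != key and mkey < key:
            # mirror is smaller; keep the mirror when it comes by, drop this
            continue
        kept.append(so)
        dropped.add(mkey)
    return kept


# ----------------------------------------------------------------------
# brute-force oracle


def _core_bounds(g: Graph, nodes) -> tuple[int, int]:
    """(j, i) of the core definition, 1-based, on a node sequence."""
    ell = len(nodes)
    first_join = None
    last_split = None
    for idx in range(1, ell - 1):
        v = nodes[idx]
        if first_join is None and g.in_degree(v) >= 2:
            first_join = idx + 1
        if g.out_degree(v) >= 2:
            last_split = idx + 1
    i = first_join if first_join is not None else ell
    j = last_split if last_split is not None else 1
    return j, i


def _has_core(g: Graph, nodes) -> bool:
    j, i = _core_bounds(g, nodes)
    return j < i


def brute_force_simple_omnitigs(g: Graph, max_len: int | None = None,
                                max_steps: int = 5_000_000) -> list[Walk]:
    """Exhaustive enumeration of maximal simple omnitigs on small graphs.

    Enumerates every walk of up to ``max_len`` nodes by depth-first search
    and keeps a walk iff

    * it possesses a core,
    * its arcs are duplicate-free within each of the three regions (left
      of the core, the core, right of the core) — the same once-per-
      direction convention as the univocal extension's cycle guard, which
      makes the result finite on cyclic graphs where walks with a core
      can wind forever, and
    * it is unextendable: no one-arc extension at the head (resp. tail)
      with an arc not already used right (resp. left) of the core produces
      a walk that still has a core.

    Isolated degree-(1,1) cycles, which admit no unextendable walk, are
    detected separately and reported once each as a circular walk broken
    at the smallest node, mirroring the unitig convention.

    The search is pruned with a monotone rule — once an inner split occurs
    strictly after the first inner join, no right-extension can ever have
    a core again — and raises :class:`GraphError` after ``max_steps`` DFS
    steps.
    """
    if max_len is None:
        max_len = 2 * g.m + 2
    kept: list[Walk] = []
    steps = 0

    def consider(nodes: list[int], arcs: list[int]) -> None:
        j, i = _core_bounds(g, nodes)
        if j >= i:
            return
        left = arcs[:j - 1]
        core = arcs[j - 1:i - 1]
        right = arcs[i - 1:]
        for region in (left, core, right):
            if len(set(region)) != len(region):
                return
        # unextendable at the head?
        right_set = set(right)
        for e in g.out_arcs(nodes[-1]):
            if e not in right_set and _has_core(g, nodes + [g.arc(e).head]):
                return
        # unextendable at the tail?
        left_set = set(left)
        for e in g.in_arcs(nodes[0]):
            if e not in left_set and _has_core(g, [g.arc(e).tail] + nodes):
                return
        kept.append(Walk(tuple(nodes), tuple(arcs)))

    from collections import defaultdict

    def dfs(nodes: list[int], arcs: list[int], counts, first_join: int | None) -> None:
        nonlocal steps
        if len(nodes) >= 2:
            consider(nodes, arcs)
        if len(nodes) >= max_len:
            return
        h = nodes[-1]
        for e in g.out_arcs(h):
            steps += 1
            if steps > max_steps:
                raise GraphError(
                    "brute-force enumeration budget exceeded; use a smaller instance"
                )
            if counts[e] >= 3:  # an arc fits in at most three regions
                continue
            new_first_join = first_join
            if len(nodes) >= 2:
                # appending makes the current head an inner node
                pos = len(nodes)
                if new_first_join is None and g.in_degree(h) >= 2:
                    new_first_join = pos
                if g.out_degree(h) >= 2 and new_first_join is not None \
                        and pos > new_first_join:
                    continue  # dead: inner split strictly after first join
            counts[e] += 1
            nodes.append(g.arc(e).head)
            arcs.append(e)
            dfs(nodes, arcs, counts, new_first_join)
            nodes.pop()
            arcs.pop()
            counts[e] -= 1

    for start in g.nodes:
        dfs([start], [], defaultdict(int), None)

    # isolated degree-(1,1) cycles, reported as circular walks
    visited: set[int] = set()
    for v in g.nodes:
        if v in visited or not _is_through(g, v):
            continue
        chain = [v]
        arcs_chain = []
        cur = v
        is_cycle = False
        while True:
            e = g.out_arcs(cur)[0]
            cur = g.arc(e).head
            arcs_chain.append(e)
            if cur == v:
                is_cycle = True
                break
            if not _is_through(g, cur) or cur in chain:
                break
            chain.append(cur)
        visited.update(chain)
        if is_cycle:
            kept.append(_canonical_cycle(g, arcs_chain))

    out: list[Walk] = []
    seen: set[tuple[tuple[int, ...], tuple[int, ...]]] = set()
    for w in kept:
        key = (w.nodes, w.arcs)
        if key not in seen:
            seen.add(key)
            out.append(w)
    out.sort(key=lambda w: (w.nodes[0], len(w), w.arcs))
    return out
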