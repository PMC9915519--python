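# Methods

## Model and definitions

The package works on directed multigraphs `G = (V, E)` with `n = |V|`
nodes and `m = |E|` arcs; parallel arcs and self-loops are allowed, and a
self-loop counts once toward the in-degree and once toward the out-degree
of its node. A *split* is a node with ≥ 2 outgoing arcs, a *join* a node
with ≥ 2 incoming arcs. Walks store their arc sequence alongside their
node sequence so that parallel arcs are unambiguous; a circular walk is a
closed traversal stored broken at its first node.

For a walk `W = (w_1, …, w_ℓ)` with `ℓ ≥ 2`, let `w_i` be its first inner
join (or `w_ℓ` if none) and `w_j` its last inner split (or `w_1` if none).
The *core* of `W` is the subwalk `w_j..w_i` when `j < i`; a *simple
omnitig* is a walk that has a core. Because a core spans from `w_j` to
`w_i` with `j < i`, every core has at least two nodes. The *univocal
extension* of a walk appends the unique out-arc of the head while the head
has out-degree exactly one, and symmetrically prepends the unique in-arc
of the tail.

The de Bruijn layer is single stranded and arc-centric: nodes are the
(k−1)-mers of a genome's k-spectrum (a *set* — multiplicity is discarded),
with one arc per k-mer from its prefix to its suffix. Circular chromosomes
contribute their wrap-around k-mers. Double-stranded assembly graphs enter
through the bidirected→doubled conversion instead: each GFA segment `s`
becomes nodes `s+` and `s−`, each link becomes an arc and its mirror, with
palindromic links emitted once and reverse-complement duplicate links
collapsed, so the doubled graph is closed under the mirror symmetry.
GFA overlap fields are stored but never interpreted; the enumeration is
topology-only.

## Enumerating maximal simple omnitigs

Maximal unitigs partition the arc set: every arc whose tail is not a
degree-(1,1) node starts a unitig that is extended forward through
degree-(1,1) nodes; leftover arcs lie on isolated degree-(1,1) cycles,
which are reported once each as a circular unitig broken at the smallest
node id. The characterization used for cores: a maximal unitig
`(w_1, …, w_ℓ)` is the core of a maximal simple omnitig iff (a) its own
core is itself (automatic for `ℓ ≥ 2`), (b) if `w_1` has exactly one
outgoing arc it has no incoming arcs, and (c) if `w_ℓ` has exactly one
incoming arc it has no outgoing arcs. The enumeration iterates the maximal
unitigs, applies the constant-time endpoint test, and emits the univocal
extension of each passing unitig — `O(m + out)` overall, where `out` is
the total output length.

Single-node unitigs can never arise from the arc partition, and a core
always has ≥ 2 nodes; `is_core_of_maximal` nevertheless accepts a
single-node walk when conditions (b) and (c) hold and its univocal
extension has a core, for callers that test hand-built walks.

### Cyclic degenerate regions

On graphs containing cycles of in/out-degree-one nodes attached to the
rest of the graph (e.g. a self-loop on a join), walks with a core can wind
around the cycle arbitrarily often, so *no* truly maximal simple omnitig
exists there. The univocal extension therefore stops on the first repeated
arc per direction. This cycle guard bounds every extension by `O(m)` per
direction; it cannot trigger on de Bruijn graphs of genomes whose repeats
have branching flanks, which is the error-free model the safety guarantees
address. Isolated cycles (whole components of degree-(1,1) nodes) are
passed through as circular unitigs, flagged, and excluded from core
testing.

On doubled graphs every simple omnitig appears together with its
reverse-complement mirror; by default the lexicographically smaller member
of each pair is reported (`dedup_rc=False` keeps both). All outputs are
sorted by (first node id, length, arc ids), so enumeration is
deterministic.

## The brute-force oracle

`brute_force_simple_omnitigs` is an independent cross-check used by the
tests: a depth-first enumeration of all walks up to a length bound, pruned
with the monotone rule that once an inner split occurs strictly after the
first inner join, no right-extension can ever have a core again. A walk is
kept iff it has a core, its arcs are duplicate-free within each of the
three regions (left of core / core / right of core — the same
once-per-direction convention as the cycle guard), and it is unextendable:
no one-arc extension using an arc not already present on that side of the
core yields a walk that still has a core. The one-step test is sound
because any contiguous subwalk (of length ≥ 2) of a simple omnitig itself
has a core: in a simple omnitig all inner splits precede all inner joins,
and the property is inherited by contiguous subwalks. Isolated cycles are
detected by a separate scan and canonicalised exactly as the unitig route
does. The oracle shares only the core *definition* with the production
algorithm — not the unitig partition, the endpoint test, or the extension
code — and the two are compared as sets of (node sequence, arc sequence)
pairs on hundreds of random multigraphs.

## Safety verification

For a genome of linear chromosomes, the boundary set `L` holds the first
and last (k−1)-mers of every chromosome (circular chromosomes contribute
nothing). The guarantee verified empirically: a simple omnitig none of
whose *inner* nodes (`w_2..w_{ℓ−1}`; endpoints exempt) lies in `L` spells
a substring of some chromosome. The converse is not asserted — walks
touching chromosome ends can still be safe under graph-topology conditions
not modelled here — so non-applicable walks are reported with their actual
substring status rather than judged. Substring checks against circular
chromosomes are rotation-aware: the pattern is searched in a periodic
extension of the chromosome and must start within the first period, which
also covers spelled strings longer than the chromosome (a closed walk
spells `|chromosome| + k − 1` characters). The unitig baseline applies the
same machinery with the stricter expectation that every unitig is safe,
which holds unconditionally in the error-free perfect-coverage model.
Sequencing errors and coverage gaps are outside the model: with them even
unitigs lose the guarantee.

## Contiguity metrics

EAxmax: per reference base, the length (reference span) of the longest
alignment block covering it, 0 if uncovered; the per-base values are
sorted descending and the value at index `⌊x/100·G⌋` (0-based, clamped to
`[0, G−1]`) is reported. The floor-and-clamp indexing makes the metric
well defined for every `x` in `[0, 100]` and matches the reading "x% of
genomic positions are covered by an alignment of length ≥ ℓ"; a
`--index-mode ceil` flag exposes the alternative rounding. Alignment
length is the reference span of the block — query-side gaps do not change
which reference bases are covered. The genome-wide variant concatenates
the per-base arrays of all references before taking percentiles and is the
CLI default; `--per-reference` computes each reference separately. The
implementation is vectorised (numpy maximum over slices); a literal
per-base Python loop (`eaxmax_bruteforce`) serves as its test oracle.

Unique-misassembly merging is greedy left-to-right over sorted positions:
a position joins the open cluster iff it is < `X` from the previous member
*and* < `X` from the cluster minimum; the second condition (span guard)
prevents transitive chains from merging into one cluster much longer than
`X`. `X` defaults to 3000 bp, the usual extensive-misassembly threshold
for large genomes. Positions are clustered per reference sequence.
Misassembly *detection* is an input (a 2-column TSV of reference and
position produced by an external evaluator), not a computation.

Homopolymer compression collapses maximal runs to one character; the
coordinate map associates each compressed position with the first raw
position of its run, so compressed-space alignment coordinates can be
lifted back.

## Synthetic data

Generators are pure functions of their spec (single seeded RNG stream per
call; the CLI default seed is 0). Planted repeats produce one chromosome
`X R Y R Z` (`copies` ≥ 2 exact copies of a random unit, default 2 copies
of 30 bp with 50 bp flanks); planted bubbles produce a diploid-style
chromosome pair `A B C` / `A D C` with `B ≠ D` (default 20 bp arms, 50 bp
flanks). With `unique_k` set, draws are rejected (up to 1000 attempts)
until every duplicated (k−1)-mer lies inside a planted span, which
guarantees the structure appears in the de Bruijn graph exactly as
designed. Feasibility depends on k: at k=7 there are only 4096 distinct
6-mers, so uniqueness is attainable only for genomes of roughly ≤ 100 bp;
the defaults are sized for k=11. The generator emulates error-free,
perfect-coverage genomes only — no read sampling, sequencing errors or
coverage profiles — so passing tests speak to algorithmic correctness in
the error-free model, not to robustness on real read data.

## Problem sizes and numerical choices

The verification suites run at desk scale, chosen to finish in seconds
while exercising tangled graphs: 200 random multigraphs with `n ≤ 12`,
`m ≤ 25` for oracle equivalence; 100 random linear genomes (2–4
chromosomes of 100–500 bp, `k ∈ {5, 7, 11}`) and 100 circular genomes for
the safety guarantees — at k=5 a 500 bp chromosome revisits most 4-mers,
which produces heavily tangled graphs; 100 random EAxmax instances with
`G ≤ 10⁴` and ≤ 50 alignment blocks; 50 random bidirected graphs for the
doubled-graph symmetry. Walks are compared exactly (node and arc id
sequences); all metrics are integer-valued, so no floating-point
tolerances are involved anywhere.

## Known limitations

* Full omnitigs, multi-safe walks and the complete safe-walk
  characterization for linear genomes are out of scope; simple omnitigs
  are safe-but-not-complete.
* The safety guarantee is vacuous under sequencing errors or coverage
  gaps; the package never claims otherwise.
* FASTA output of walks is only defined on de Bruijn-style graphs whose
  segments are uniform-length sequence nodes; for general GFA inputs the
  CLI reports node paths instead (overlap-aware sequence merging is not
  implemented).
* The "length dominance" of simple omnitigs over unitigs holds on genome
  de Bruijn graphs but can fail on arbitrary cyclic multigraphs, where the
  cycle guard truncates extensions; the tests assert it only in the
  genome setting.
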