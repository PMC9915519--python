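# simpletigs

Safe contigs beyond unitigs for genome assembly graphs.

Most assemblers report **unitigs** — walks whose inner nodes have in- and
out-degree one — because unitigs are *safe*: on an error-free,
perfect-coverage de Bruijn graph their spelled strings are guaranteed
substrings of the genome. Unitigs stop at every branching node, though, so
repeats and bubbles fragment the assembly more than necessary. **Simple
omnitigs** extend further while keeping the safety guarantee: a simple
omnitig is a walk `W = (w_1, …, w_ℓ)` that has a *core* — a subwalk from
its last inner split `w_j` to its first inner join `w_i` with `j < i`.
Equivalently, it is the *univocal extension* of its core: every inner node
left of the core has in-degree one, every inner node right of it has
out-degree one, so any walk through the core that does not start or end
strictly inside `W` must traverse all of `W`.

`simpletigs` is a library + CLI for working with these objects:

* **Graph model** — directed multigraphs with parallel arcs and self-loops;
  bidirected (GFA) graphs converted to mirror-symmetric doubled graphs.
* **de Bruijn layer** — k-spectra of linear/circular multi-chromosome
  genomes, arc-centric de Bruijn graphs, walk spelling.
* **Tig algorithms** — maximal unitig enumeration (`O(m)`), the
  core-of-maximal characterization, univocal extension, and maximal
  simple-omnitig enumeration in `O(m + out)` time, plus an exhaustive
  brute-force oracle for cross-checking on small graphs.
* **Safety verification** — a simple omnitig of a multi-chromosome linear
  genome is guaranteed safe whenever none of its inner nodes lies in the
  boundary set `L` (the first/last (k−1)-mers of the chromosomes); on a
  single circular chromosome every simple omnitig is safe. Both guarantees
  are checked empirically against generated genomes.
* **Contiguity metrics** — the EAxmax family: for each reference base take
  the length of the longest alignment covering it, sort these per-base
  values descending, and report the value at index `x/100·G`. An EAxmax of
  `ℓ` means x% of reference positions are covered by an alignment of length
  ≥ `ℓ`; using the per-base *maximum* keeps the metric robust when contigs
  overlap. Also: homopolymer compression with coordinate lifting, and
  merging of misassembly positions less than `X` bp apart into unique
  misassemblies (span capped below `X`, default 3000).
* **Synthetic data** — seeded generators of random genomes, genomes with
  planted exact repeats and bubbles (unique flanks enforced by rejection
  sampling), and random graphs.

## Worked example

Simulate a 69 bp genome containing two exact copies of a 12 bp repeat `R`
with unique 15 bp flanks (`X R Y R Z`), build its de Bruijn graph at k=7,
and compare unitigs with simple omnitigs:

```sh
$ cat repeat.json
{"n_chromosomes": 0, "seed": 1, "unique_k": 7,
 "features": [{"type": "repeat", "copies": 2, "unit_length": 12, "flank_length": 15}]}

$ tigs simulate --spec repeat.json --out genome.fa --manifest manifest.json
$ tigs build-dbg --genome genome.fa --k 7 --out dbg.gfa
$ tigs unitigs --graph dbg.gfa --plain --out utg.fa
$ tigs simple-omnitigs --graph dbg.gfa --plain --out so.fa
```

The genome and the four maximal unitigs — the repeat `R` forms its own
unitig and truncates its flanking contexts:

```
>chr1
TTAAGTGTCGAGCTACGGACCGCGGTGCATCACTTCTCATGTCGGACCGCGGTGAGCCAGAAGGCTGCA

>utg_0 core=0 circular=false
CGGACCGCGGTG                               # the repeat unit's unitig
>utg_1 core=1 circular=false
GCGGTGAGCCAGAAGGCTGCA
>utg_2 core=2 circular=false
GCGGTGCATCACTTCTCATGTCGGACC
>utg_3 core=3 circular=false
TTAAGTGTCGAGCTACGGACC
```

The three maximal simple omnitigs instead carry the repeat together with
its contexts; `so_1` spans the genome from the first to the second copy of
`R` in one contig:

```
>so_0 core=1 circular=false
CGGACCGCGGTGAGCCAGAAGGCTGCA
>so_1 core=2 circular=false
CGGACCGCGGTGCATCACTTCTCATGTCGGACCGCGGTG
>so_2 core=3 circular=false
TTAAGTGTCGAGCTACGGACCGCGGTG
```

All of them are verified substrings of the genome (exit status would be 2
otherwise):

```
$ tigs verify-safety --genome genome.fa --k 7
walk_id  length  applicable  safe  witness_chr  witness_offset
0        22      True        True  chr1         42
1        34      True        True  chr1         15
2        22      True        True  chr1         0
```

`applicable` records whether the walk's inner nodes avoid the boundary set
`L`; applicable walks are the ones the safety guarantee covers.

EAxmax from a PAF alignment (two blocks of lengths 8 and 5 on a 10 bp
reference; position 5–7 are covered by both, so their per-base maximum
is 8):

```
$ tigs eaxmax --paf aln.paf --x 50,75,90
reference    x   eaxmax
genome-wide  50  8
genome-wide  75  8
genome-wide  90  5
```

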