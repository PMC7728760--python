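# Methods

## The model

`lcbkit` decomposes a collection of closely related assembled genomes into
*locally collinear blocks* (LCBs): sets of edge-disjoint genomic walks
through a de Bruijn graph, each at least `m` base pairs long, free of
internal rearrangements, and held together by a single *carrying path*.

The de Bruijn graph `G(S, k)` of a sequence collection `S` has every k-mer
as a vertex and one directed edge per occurrence of a (k+1)-mer; edges
generated by the same (k+1)-mer are *parallel*.  A walk is *genomic* if its
edges are consecutive occurrences in one input sequence, so each contig
strand is one genomic walk.  Two homologous sequences appear in the graph as
a *chain*: an alternation of parallel edges (identical sequence) and
*bubbles* — pairs of walks that share their endpoint vertices, are otherwise
vertex-disjoint, and are each at most `b` edges long — which model
substitutions and short indels flanked by identical context.  More than two
homologous sequences tangle, so the block is anchored instead on a carrying
path `p_a`, a vertex-simple path that forms a long chain with every walk of
the block.

Given a carrying path and a genomic walk `p`, let `q2` be the longest
contiguous subpath of `p_a` that forms a chain with a subwalk of `p`, and
write `p_a = q1 q2 q3`.  The walk's score is

```
f(p_a, p) = 0                          if |p| < m
          = |p| - (|q1| + |q3|)^2      if |p| >= m and |q1|, |q3| <= b
          = -inf                       otherwise
```

and a block's score is the sum over its walks.  Long chains are rewarded,
hanging ends of the carrying path are penalised quadratically, and short
walks are ignored.  All lengths — `|p|`, `|q1|`, `|q3|`, and the bounds `b`
and `m` — are counted in underlying (k+1)-mer edges even on the compacted
graph (a compacted edge contributes its stored step length); the formula
mixes them additively, so a single unit is required, and that unit is the
base-pair scale on which the defaults `m = 50`, `b = 200` are expressed.

## The algorithm

The finder is greedy, seed-and-extend:

1. **Seeds.** Every edge class of the compacted graph is tried once, in
   lexicographic order of the canonical (strand-min) spelled sequence.
   A seed initialises the carrying path with one edge and the block with one
   single-edge walk per unused parallel occurrence.
2. **Phases.** While the block score is non-negative, compute the
   b-extension of every walk (the longest genomic continuation of at most
   `b` edges, truncated at fragment ends and before used edges), pick the
   target vertex visited by the most extensions among those reachable from
   the carrying path's end, and extend the carrying path there by the
   shortest such extension.  For every appended vertex, each unused edge
   ending at it either lengthens the nearest walk whose b-extension contains
   it, or starts a new walk.  The best-scoring intermediate state is
   remembered and restored at the end.
3. **Left extension.** The procedure is symmetric; it is rerun on a reversed
   view of the graph starting from the best rightward state.
4. **Output.** A block is reported if its definitional rescoring is positive
   and it retains at least two walks of length >= `m` with individually
   positive scores.  The reported walks' edges (and their reverse-complement
   twins) are marked used and never re-enter later blocks.

Double-strandedness is handled with the comprehensive graph — the union of
the graph of every fragment and of its reverse complement — with used-edge
marks shared between strand twins, so a block on one strand excludes its
mirror image.

### Scoring during the greedy phases

Recomputing the chain decomposition from its definition after every append
would be quadratic, so each walk carries an incremental record: the last
vertex where it met the carrying path, the run of consecutive valid bubbles
ending there, and the best run seen.  Appended segments are matched to
carrying-path vertices greedily (the carrying path is vertex-simple, so the
matching is unambiguous up to monotonicity).  This estimate drives the
greedy decisions only; every *reported* block is rescored with the exact
dynamic programme over matched vertex pairs, and the tests verify that the
stored scores equal that definitional recomputation.

Two deliberate deviations from the strictest literal reading, both needed
for the algorithm to function:

- A walk whose chain with the carrying path is still empty contributes 0
  rather than `|p| - |p_a|^2`.  Freshly spawned single-edge walks otherwise
  poison the block score at small `m` and halt all extension immediately
  (demonstrable by hand on the three-string worked example).
- Blocks keep only walks with strictly positive scores, and only those
  walks' edges are marked used; marking the score-0 stubs would sterilise
  the regions they touch for later seeds.

### Compacted-graph semantics

The compacted graph keeps junction k-mers (>= 2 distinct in- or
out-neighbours; self-loops count their vertex once) plus the first and last
k-mer of every fragment as sentinels, so that every genomic position lies on
a compacted edge and compaction is exactly lossless.  Compaction is an
acceleration, not a change of model, which forces two liftings:

- Two parallel compacted edges (identical spelled sequence) are a valid
  chain link at *any* step length: on the ordinary graph they are a chain of
  unit parallel-edge bubbles.  Bubble side-length limits apply only to sides
  that differ.
- A b-extension always enters the immediate successor edge even when that
  edge's step length alone exceeds `b`: an unbranched run offers no choice,
  and the lookahead fast-forwards through it junction to junction.
- Bubble interior-disjointness is checked over junction vertices; interior
  non-junction k-mers of two compacted edges are not compared.

High-frequency repeats are tamed by abundance pruning: junction k-mers
occurring more than `a` times (both strands combined) are dropped from the
junction set before edge construction, sentinels excepted.  Blocks with
copy number above `a` may consequently be missed.

### Determinism

All tie-breaks are fixed: seed order is lexicographic; extension targets
break ties by most votes, then shortest extension, then smallest vertex;
chain ties prefer the leftmost (smallest `q1`) split.  Incoming edges at a
vertex are processed in the order of their physical, strand-invariant
identity (fragment, plus-strand index), which makes the output equivariant
under reverse-complementing the whole input: mirrored coordinates, flipped
strands, same blocks.  The optional batch mode explores seeds speculatively
against frozen used-marks and replays conflicting seeds serially in order,
so its result equals the serial run for every batch size.

## Parameters

| name | default | unit | meaning |
|------|---------|------|---------|
| `k`  | 25 (preset `mammalian`), 15 (preset `bacterial`) | bp | k-mer/vertex size; smaller k tolerates more divergence but tangles the graph |
| `b`  | 200 | (k+1)-mer edges ~ bp | maximum bubble side length and lookahead; bounds the indel/variant size bridged inside a block |
| `m`  | 50  | edges ~ bp | minimum collinear walk length; controls fragmentation vs. minimum reportable homology |
| `a`  | 150 | occurrences | abundance pruning threshold for junction k-mers |

The method targets closely related genomes; recall decays once root-to-leaf
divergence approaches ~0.09 substitutions per site, and beyond that a more
sensitive (and slower) aligner is the right tool.

## Block output and alignment

Internally all coordinates are 0-based, half-open, forward-strand;
conversions to 1-based GFF3 and to MAF's reverse-strand start convention
happen only in the writers.  A reported walk occupies
`[jpos[first], jpos[last])` of its strand — the trailing k-mer's bases
belong to whichever block continues there — so blocks tile without overlap;
a final sweep clips the rare residual overlap between opposite-strand twins
(earlier-discovered blocks win, both ends clipped symmetrically).

Per-block multiple alignment is center-star with unit costs (match 0,
mismatch 1, indel 1): the center minimises the summed pairwise edit
distance (ties: first index), the pairwise step is edlib's global
alignment, and rows merge under "once a gap, always a gap".  Center-star is
adequate here because block rows are near-identical by construction; it is
not a general-purpose MSA and makes no claim of optimality beyond the
pairwise level (the tests verify pairwise optimality and a sum-of-pairs
sanity bound).  The pipeline can skip this stage entirely when only block
coordinates are needed.

## Evaluation metrics

An alignment is an equivalence relation over genomic positions: every
column relates the positions of every pair of rows holding valid
nucleotides (gaps contribute nothing).  Against a truth relation `H` and a
prediction `A`:
`recall = 1 - |H\A|/|H|`, `precision = 1 - |A\H|/|A|`.  Position pairs are
strand-annotated and compared up to a joint strand flip.  Coverage is the
fraction of total genome length inside blocks; nucleotide identity is
matches over alignment length including gaps; `pi(c)` is the average number
of pairwise nucleotide differences in a column, counting a pair only when
both characters are valid DNA, with `C(|c|, 2)` as the denominator.

## The synthetic-genome generator

A uniform i.i.d. ACGT ancestor is evolved independently into each genome —
a star phylogeny, chosen because the method's tolerance is phrased as
root-to-leaf distance and a star isolates that one parameter.  Per genome:
Bernoulli substitutions per site (uniform over the three alternatives),
indel events at a per-site rate with geometric lengths (insertions carry no
ancestry; deletions remove it), then a fixed number of in-place inversions
(ancestry reversed, strands flipped) and tandem duplications (the copy
inherits the segment's ancestry).  Defaults: 50 kbp ancestor, 3 genomes,
0.02 substitutions/site, indel rate 0.002 with mean length 3, one inversion
of 500–2000 bp and one duplication of 200–1000 bp per genome — a regime a
bacteriologist would recognise as same-species strains.  The exact truth
relation (all position pairs descending from one ancestral position,
including within-genome paralogy from duplications) falls out of the
bookkeeping; output is byte-identical under a fixed seed.

What the generator does *not* emulate: context-dependent mutation,
rate heterogeneity, large-scale gain/loss, translocations between contigs,
and real repeat families.  Passing tests on this data show the machinery
recovers planted homology under idealised noise; they do not certify recall
on genomes with heavy repeat content.

One structural note on the column-homogeneity check: with three genomes at
0.02 substitutions/site from the ancestor, a three-row alignment column is
constant with probability about `0.98^3 ≈ 0.94`, so the fraction of columns
with `pi(c) <= 0.1` is bounded near 94–95% *by the simulation conditions
themselves*, regardless of aligner quality; the corresponding test asserts
the 95% figure and documents this bound.

## Problem sizes and numerical choices

The test suite and the reproduction script run the full pipeline on three
50 kbp genomes (seconds on one CPU) and fuzz the component algorithms on
thousands of small random instances; the mathematical core (chain
decomposition) is checked against an exhaustive enumeration oracle on
graphs small enough to enumerate.  Scores are small integers represented in
floating point; `-inf` is the only non-finite value and short-circuits
block sums.  Degenerate inputs — empty FASTA records, contigs shorter than
`k`, non-ACGT runs, all-used seed classes, single-occurrence seeds — are
rejected or skipped explicitly rather than special-cased downstream.

## Known limitations

- The greedy carrying path is a heuristic; no optimality guarantee exists,
  and blocks may fragment at rearrangement boundaries or where a late-joining
  homolog would leave hanging ends longer than `b` (the scoring forbids
  those states by design).
- Seeds whose class has a single unused occurrence are skipped (they cannot
  satisfy the two-walk output rule); homology visible only through such
  seeds shifts to neighbouring seeds, with a small recall cost at block
  edges.
- Runtime is Python-scale: desk-sized genomes (up to a few hundred kbp) are
  comfortable; chromosome-scale inputs are out of scope.
- The trailing k bases of each fragment's final block are not covered by any
  block (interval convention); coverage loses at most k bases per fragment.
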