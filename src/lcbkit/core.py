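"""Walks, b-extensions, bubbles, chains and the collinearity score.

A *bubble* is a pair of walks sharing start and end vertices, disjoint
otherwise, with both sides at most ``b`` edges long; it is the graph
signature of a substitution or small indel flanked by identical sequence.
A *chain* is a series of bubbles, each a proper continuation of the
previous one.  Given a carrying path ``p_a`` and a genomic walk ``p``, the
score of the walk is::

    f(p_a, p) = 0                          if |p| < m
              = |p| - (|q1| + |q3|)**2     if |p| >= m and |q1|, |q3| <= b
              = -inf                       otherwise

where ``q2`` is the longest subpath of ``p_a`` forming a chain with ``p``
and ``p_a = q1 q2 q3``.  All lengths are measured in underlying
(k+1)-mer edges, including on the compacted graph where an edge
contributes its stored step length: the recommended block parameters
(m = 50, b = 200) are on the base-pair scale, so mixing |p| and |q|
additively requires a single unit.

The score of a block is the sum of its walks' scores against the block's
carrying path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

NEG_INF = -math.inf


@dataclass(frozen=True)
class CollinearWalk:
    """A genomic interval interpreted as a walk on a (compacted) graph.

    ``lo``/``hi`` index edges of the fragment strand, half-open; the walk
    visits junction occurrences ``lo .. hi`` inclusive.
    """

    fi: int
    strand: str
    lo: int
    hi: int

    def __post_init__(self):
        if self.hi <= self.lo:
            raise ValueError("a walk has at least one edge")

    @property
    def n_edges(self) -> int:
        return self.hi - self.lo


@dataclass(frozen=True)
class VWalk:
    """A walk reduced to what chains care about: vertices and step lengths.

    ``cum[i]`` is the number of underlying (k+1)-mer edges from the first
    vertex to vertex ``i`` (``cum[0] == 0``); ``occ`` optionally identifies
    the genomic occurrence so that a walk is never a bubble with itself.
    """

    vertices: tuple
    cum: tuple
    occ: tuple | None = None
    # spelled sequence per edge: lets chain checks recognise parallel
    # compacted edges (identical runs), which decompose into unit bubbles
    labels: tuple | None = None

    def __post_init__(self):
        if len(self.vertices) != len(self.cum) or len(self.vertices) < 1:
            raise ValueError("vertices and cum must align")
        if self.labels is not None and len(self.labels) != len(self.vertices) - 1:
            raise ValueError("one label per edge")

    @property
    def length(self) -> int:
        """Total length in underlying edges."""
        return self.cum[-1]

    def segment_vertices(self, i0: int, i1: int) -> Sequence:
        return self.vertices[i0 : i1 + 1]


def vwalk_from_compacted(graph, walk: CollinearWalk) -> VWalk:
    vers = graph.jver[walk.fi, walk.strand][walk.lo : walk.hi + 1]
    pos = graph.jpos[walk.fi, walk.strand]
    cum = tuple(pos[i] - pos[walk.lo] for i in range(walk.lo, walk.hi + 1))
    labels = tuple(
        graph.spelled(walk.fi, walk.strand, i) for i in range(walk.lo, walk.hi)
    )
    return VWalk(tuple(vers), cum, occ=(walk.fi, walk.strand, walk.lo, walk.hi),
                 labels=labels)


def vwalk_from_ordinary(graph, frag_idx: int, strand: str = "+",
                        lo: int = 0, hi: int | None = None) -> VWalk:
    """Genomic walk of an ordinary graph: one step per edge."""
    seq = graph.fragments[frag_idx].strand_seq(strand)
    if hi is None:
        hi = len(seq) - graph.k
    vers = tuple(seq[p : p + graph.k] for p in range(lo, hi + 1))
    labels = tuple(seq[p : p + graph.k + 1] for p in range(lo, hi))
    return VWalk(vers, tuple(range(hi - lo + 1)), occ=(frag_idx, strand, lo, hi),
                 labels=labels)


# ---------------------------------------------------------------------------
# b-extension
# ---------------------------------------------------------------------------


def b_extension(graph, walk: CollinearWalk, b: int, blocked=None) -> CollinearWalk | None:
    """Longest genomic walk continuing ``walk`` with at most ``b`` edges.

    The extension starts at the successor of the walk's last edge and is
    truncated at the fragment end and immediately before the first blocked
    (used) edge; ``None`` when empty.  ``blocked`` defaults to the graph's
    used-edge marks.

    On a compacted graph the immediate successor edge is always included
    even when its step length alone exceeds ``b``: an unbranched run offers
    no choice and the lookahead fast-forwards through it junction to
    junction, exactly as it would traverse the run edge by edge on the
    ordinary graph.
    """
    if b < 1:
        raise ValueError(f"b must be >= 1, got {b}")
    if blocked is None:
        blocked = graph.is_used
    fi, strand = walk.fi, walk.strand
    n = graph.n_edges(fi, strand)
    pos = graph.jpos[fi, strand]
    j = walk.hi
    base = pos[j]
    while (
        j < n
        and (j == walk.hi or pos[j + 1] - base <= b)
        and not blocked(fi, strand, j)
    ):
        j += 1
    if j == walk.hi:
        return None
    return CollinearWalk(fi, strand, walk.hi, j)


# ---------------------------------------------------------------------------
# bubbles
# ---------------------------------------------------------------------------


def _sides_form_bubble(x_vertices, y_vertices, x_len: int, y_len: int, b: int) -> bool:
    if x_vertices[0] != y_vertices[0] or x_vertices[-1] != y_vertices[-1]:
        return False
    if x_len > b or y_len > b or x_len < 1 or y_len < 1:
        return False
    shared = set(x_vertices) & set(y_vertices)
    return shared <= {x_vertices[0], x_vertices[-1]}


def is_bubble(x: VWalk, y: VWalk, b: int) -> bool:
    """Do the two walks form a bubble?  Two distinct parallel edges do; a
    walk never forms a bubble with itself (same occurrence)."""
    if x.occ is not None and x.occ == y.occ:
        return False
    return _sides_form_bubble(x.vertices, y.vertices, x.length, y.length, b)


# ---------------------------------------------------------------------------
# chain decomposition
# ---------------------------------------------------------------------------


@dataclass
class ChainSplit:
    """Decomposition p_a = q1 q2 q3 against one walk, lengths in edges."""

    q1_len: int
    q2_len: int
    q3_len: int
    # bubble list: ((pa_i0, pa_i1), (p_j0, p_j1)) vertex-index ranges
    bubbles: list[tuple[tuple[int, int], tuple[int, int]]] = field(default_factory=list)

    @property
    def n_bubbles(self) -> int:
        return len(self.bubbles)


def decompose_chain(p_a: VWalk, p: VWalk, b: int) -> ChainSplit:
    """Longest contiguous subpath ``q2`` of ``p_a`` that forms a chain with
    a subwalk of ``p``; ties prefer the leftmost (smallest ``q1``) chain.

    Works by dynamic programming over matched vertex pairs: a chain is a
    monotone sequence of pairs where each consecutive pair of pairs bounds a
    valid bubble (both sides <= b edges, interiors disjoint).
    """
    where_in_p: dict = {}
    for j, v in enumerate(p.vertices):
        where_in_p.setdefault(v, []).append(j)
    matches = [
        (i, j)
        for i, v in enumerate(p_a.vertices)
        for j in where_in_p.get(v, ())
    ]
    total = p_a.length

    def bubble_ok(i0, j0, i1, j1) -> bool:
        # parallel edges (one compacted edge on each side, identical spelled
        # sequence) are a chain of unit bubbles in the underlying graph and
        # are valid whatever their compacted step length
        if (
            i1 == i0 + 1
            and j1 == j0 + 1
            and p_a.labels is not None
            and p.labels is not None
            and p_a.labels[i0] == p.labels[j0]
        ):
            return True
        return _sides_form_bubble(
            p_a.segment_vertices(i0, i1),
            p.segment_vertices(j0, j1),
            p_a.cum[i1] - p_a.cum[i0],
            p.cum[j1] - p.cum[j0],
            b,
        )

    # reach[t]: smallest q2 start offset (p_a cum) of any chain ending at t
    reach: dict[int, int] = {}
    parent: dict[int, int] = {}
    for t, (i1, j1) in enumerate(matches):
        best = None
        best_s = None
        for s in range(t - 1, -1, -1):
            i0, j0 = matches[s]
            if i0 >= i1 or j0 >= j1:
                continue
            # matches are sorted by i: once the carrying-path span exceeds b
            # and we are past the adjacent-edge (parallel) candidates, no
            # earlier match can bound a bubble
            if p_a.cum[i1] - p_a.cum[i0] > b and i0 < i1 - 1:
                break
            if not bubble_ok(i0, j0, i1, j1):
                continue
            start = min(reach.get(s, p_a.cum[i0]), p_a.cum[i0])
            if best is None or start < best or (start == best and matches[s] < matches[best_s]):
                best, best_s = start, s
        if best is not None:
            reach[t] = best
            parent[t] = best_s

    if not reach:
        # no chain at all: q2 empty; leftmost split puts everything in q3
        return ChainSplit(0, 0, total, [])

    def chain_key(t):
        i1, _ = matches[t]
        q2 = p_a.cum[i1] - reach[t]
        return (-q2, reach[t], matches[t])

    end = min(reach, key=chain_key)
    bubbles = []
    t = end
    while t in parent:
        s = parent[t]
        bubbles.append(((matches[s][0], matches[t][0]), (matches[s][1], matches[t][1])))
        t = s
    bubbles.reverse()
    i_start = bubbles[0][0][0]
    i_end = bubbles[-1][0][1]
    q1 = p_a.cum[i_start]
    q2 = p_a.cum[i_end] - q1
    return ChainSplit(q1, q2, total - q1 - q2, bubbles)


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------


def score_split(p_len: int, split: ChainSplit, m: int, b: int) -> float:
    if m < 1 or b < 1:
        raise ValueError("m and b must be >= 1")
    if p_len < m:
        return 0.0
    if split.q1_len <= b and split.q3_len <= b:
        return float(p_len - (split.q1_len + split.q3_len) ** 2)
    return NEG_INF


def score_walk(p_a: VWalk, p: VWalk, m: int, b: int) -> float:
    """Collinearity score of one walk against a carrying path."""
    if p.length < m:  # short walks are ignored before any decomposition
        return 0.0
    return score_split(p.length, decompose_chain(p_a, p, b), m, b)


def score_block(p_a: VWalk, walks: Sequence[VWalk], m: int, b: int) -> float:
    """Sum of walk scores against the given carrying path (the greedy
    stand-in for the maximisation over all possible carrying paths)."""
    total = 0.0
    for p in walks:
        s = score_walk(p_a, p, m, b)
        if s == NEG_INF:
            return NEG_INF
        total += s
    return total
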