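"""Greedy seed-and-extend reconstruction of locally collinear blocks.

Seeds are edge classes of the compacted graph, visited in lexicographic
canonical-key order.  A seed initialises a carrying path and one collinear
walk per unused parallel occurrence; phases then extend the carrying path
by the genomic walk reaching the vertex most visited by the walks'
b-extensions, walks are lengthened so as to keep forming chains with the
carrying path, and the highest-scoring intermediate state is remembered.
After rightward termination the procedure is rerun leftward (on a reversed
view of the graph).  Edges of accepted blocks are marked used, together
with their strand twins, and never re-enter later blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterator, Sequence

from lcbkit.core import (
    NEG_INF,
    CollinearWalk,
    VWalk,
    b_extension,
    decompose_chain,
    score_split,
    vwalk_from_compacted,
)
from lcbkit.graph import CompactedGraph
from lcbkit.io import BlockRecord, Occurrence


# ---------------------------------------------------------------------------
# reversed view of a compacted graph (for leftward extension)
# ---------------------------------------------------------------------------


class ReversedView:
    """Expose a compacted graph with every fragment strand read backwards.

    Reversed edge ``j`` of a strand with ``n`` edges is underlying edge
    ``n - 1 - j``; vertices keep their labels (they are not complemented:
    chains only compare vertex equality), and used marks are shared with
    the underlying graph.
    """

    def __init__(self, cg: CompactedGraph):
        self.cg = cg
        self.k = cg.k
        self.double_stranded = cg.double_stranded
        self.fragments = cg.fragments
        self._jpos_cache: dict = {}
        self._jver_cache: dict = {}
        self._out_edges: dict | None = None
        self.jpos = _RevDict(self, "pos")
        self.jver = _RevDict(self, "ver")

    def n_edges(self, fi, strand):
        return self.cg.n_edges(fi, strand)

    def _rev_edge(self, fi, strand, i):
        return self.cg.n_edges(fi, strand) - 1 - i

    def step(self, fi, strand, i):
        return self.cg.step(fi, strand, self._rev_edge(fi, strand, i))

    def head_vertex(self, fi, strand, i):
        return self.cg.tail_vertex(fi, strand, self._rev_edge(fi, strand, i))

    def tail_vertex(self, fi, strand, i):
        return self.cg.head_vertex(fi, strand, self._rev_edge(fi, strand, i))

    def is_used(self, fi, strand, i):
        return self.cg.is_used(fi, strand, self._rev_edge(fi, strand, i))

    def spelled(self, fi, strand, i):
        # the same strand read backwards: reversed, not complemented
        return self.cg.spelled(fi, strand, self._rev_edge(fi, strand, i))[::-1]

    def plus_index(self, fi, strand, i):
        return self.cg._plus_index(fi, strand, self._rev_edge(fi, strand, i))

    @property
    def in_edges(self):
        # reversed in-edges are underlying out-edges
        if self._out_edges is None:
            out: dict = {}
            for (fi, strand), vers in sorted(self.cg.jver.items()):
                n = len(vers) - 1
                for i in range(n):
                    out.setdefault(vers[i], []).append(
                        (fi, strand, n - 1 - i)  # reversed index
                    )
            for lst in out.values():
                lst.sort(key=lambda occ: (occ[0], self.plus_index(*occ), occ[1]))
            self._out_edges = out
        return self._out_edges


class _RevDict:
    """Lazy mirrored jpos/jver lookup for :class:`ReversedView`."""

    def __init__(self, view: ReversedView, kind: str):
        self.view, self.kind = view, kind

    def __getitem__(self, key):
        cache = self.view._jpos_cache if self.kind == "pos" else self.view._jver_cache
        if key not in cache:
            if self.kind == "pos":
                pos = self.view.cg.jpos[key]
                last = pos[-1] if pos else 0
                cache[key] = [last - p for p in reversed(pos)]
            else:
                cache[key] = list(reversed(self.view.cg.jver[key]))
        return cache[key]


def plus_index(graph, fi, strand, i):
    if isinstance(graph, ReversedView):
        return graph.plus_index(fi, strand, i)
    return graph._plus_index(fi, strand, i)


# ---------------------------------------------------------------------------
# walk state with incremental chain tracking
# ---------------------------------------------------------------------------


@dataclass
class WalkState:
    """One collinear walk plus the chain it currently forms with p_a.

    ``anchor_*`` is the last vertex where the walk met the carrying path;
    ``cur`` is the run of consecutive valid bubbles ending at that anchor
    and ``best`` the best run seen so far (both as (pa_start, pa_end) pairs
    of carrying-path vertex indices).  A final definitional rescoring of
    reported blocks replaces these incremental estimates.
    """

    fi: int
    strand: str
    lo: int
    hi: int
    anchor_pa: int
    anchor_occ: int
    cur: tuple | None = None
    best: tuple | None = None

    def as_walk(self) -> CollinearWalk:
        return CollinearWalk(self.fi, self.strand, self.lo, self.hi)

    def freeze(self) -> tuple:
        return (self.fi, self.strand, self.lo, self.hi,
                self.anchor_pa, self.anchor_occ, self.cur, self.best)

    @staticmethod
    def thaw(t: tuple) -> "WalkState":
        return WalkState(*t)


@dataclass
class CollinearBlock:
    """A carrying path with its edge-disjoint collinear walks."""

    carrying: VWalk
    walks: list[CollinearWalk]
    walk_scores: list[float]
    score: float


@dataclass
class UsedMarks:
    """Monotone per-edge-occurrence marks, shared between strand twins.

    Thin facade over the graph's own mark store so callers can pass an
    explicit accounting object where the algorithm boxes mention one.
    """

    graph: CompactedGraph

    def is_used(self, fi, strand, i) -> bool:
        return self.graph.is_used(fi, strand, i)

    def mark(self, fi, strand, i) -> None:
        self.graph.mark_used(fi, strand, i)


# ---------------------------------------------------------------------------
# the per-seed builder
# ---------------------------------------------------------------------------


class BlockBuild:
    """State of Find-collinear-blocks for a single seed."""

    def __init__(self, graph, b: int, m: int):
        self.g = graph
        self.b = b
        self.m = m
        self.pa_vertices: list = []
        self.pa_cum: list[int] = []
        self.pa_labels: list[str] = []  # spelled sequence per carrying edge
        self.pa_index: dict = {}
        self.walks: list[WalkState] = []
        self.by_strand: dict[tuple[int, str], list[WalkState]] = {}
        self.coverage: dict[int, set[int]] = {}
        self.best_f: float = 0.0
        self.best_snap: tuple | None = None

    # -- plumbing -----------------------------------------------------------

    def blocked(self, fi, strand, i) -> bool:
        if self.g.is_used(fi, strand, i):
            return True
        return plus_index(self.g, fi, strand, i) in self.coverage.get(fi, ())

    def _cover(self, fi, strand, lo, hi) -> None:
        cov = self.coverage.setdefault(fi, set())
        for i in range(lo, hi):
            cov.add(plus_index(self.g, fi, strand, i))

    def _append_pa(self, vertex, step: int, label: str | None = None) -> int:
        self.pa_vertices.append(vertex)
        self.pa_cum.append((self.pa_cum[-1] if self.pa_cum else 0) + step)
        if label is not None:
            self.pa_labels.append(label)
        idx = len(self.pa_vertices) - 1
        self.pa_index[vertex] = idx
        return idx

    def _add_walk(self, w: WalkState) -> None:
        self.walks.append(w)
        self.by_strand.setdefault((w.fi, w.strand), []).append(w)
        self._cover(w.fi, w.strand, w.lo, w.hi)

    # -- seeding ------------------------------------------------------------

    def init_from_seed(self, seed_key: str, occurrences: Sequence[tuple]) -> None:
        fi0, s0, i0 = occurrences[0]
        u = self.g.tail_vertex(fi0, s0, i0)
        v = self.g.head_vertex(fi0, s0, i0)
        self._append_pa(u, 0)
        self._append_pa(v, self.g.step(fi0, s0, i0), self.g.spelled(fi0, s0, i0))
        for fi, strand, i in occurrences:
            if self.g.is_used(fi, strand, i):
                continue
            self._add_walk(
                WalkState(fi, strand, i, i + 1, anchor_pa=1, anchor_occ=i + 1,
                          cur=(0, 1), best=None)
            )

    # -- scoring ------------------------------------------------------------

    def _best_run(self, w: WalkState) -> tuple | None:
        runs = [r for r in (w.best, w.cur) if r is not None]
        if not runs:
            return None
        return max(runs, key=lambda r: (self.pa_cum[r[1]] - self.pa_cum[r[0]], -r[0]))

    def walk_score(self, w: WalkState) -> float:
        pos = self.g.jpos[w.fi, w.strand]
        length = pos[w.hi] - pos[w.lo]
        if length < self.m:
            return 0.0
        run = self._best_run(w)
        if run is None:
            # not yet chaining with p_a: treated like the too-short case
            return 0.0
        q1 = self.pa_cum[run[0]]
        q3 = self.pa_cum[-1] - self.pa_cum[run[1]]
        if q1 > self.b or q3 > self.b:
            return NEG_INF
        return float(length - (q1 + q3) ** 2)

    def f(self) -> float:
        total = 0.0
        for w in self.walks:
            s = self.walk_score(w)
            if s == NEG_INF:
                return NEG_INF
            total += s
        return total

    def _maybe_snapshot(self) -> None:
        f = self.f()
        if f > self.best_f:
            self.best_f = f
            self.best_snap = (
                len(self.pa_vertices),
                tuple(w.freeze() for w in self.walks),
            )

    # -- chain bookkeeping --------------------------------------------------

    def _bubble_ok(self, pa0, occ0, pa1, occ1, fi, strand) -> bool:
        # parallel compacted edges (identical spelled sequence) decompose
        # into unit bubbles on the ordinary graph: valid at any step length
        if (
            pa1 == pa0 + 1
            and occ1 == occ0 + 1
            and self.pa_labels[pa0] == self.g.spelled(fi, strand, occ0)
        ):
            return True
        if self.pa_cum[pa1] - self.pa_cum[pa0] > self.b:
            return False
        pos = self.g.jpos[fi, strand]
        if pos[occ1] - pos[occ0] > self.b:
            return False
        vers = self.g.jver[fi, strand]
        side_a = self.pa_vertices[pa0 : pa1 + 1]
        side_b = vers[occ0 : occ1 + 1]
        shared = set(side_a) & set(side_b)
        return shared <= {side_a[0], side_a[-1]}

    def _advance_chain(self, w: WalkState, old_hi: int, new_hi: int) -> None:
        """Anchor the freshly appended part of a walk on the carrying path."""
        vers = self.g.jver[w.fi, w.strand]
        for occ in range(old_hi + 1, new_hi + 1):
            idx = self.pa_index.get(vers[occ])
            if idx is None or idx <= w.anchor_pa:
                continue
            if self._bubble_ok(w.anchor_pa, w.anchor_occ, idx, occ, w.fi, w.strand):
                if w.cur is not None and w.cur[1] == w.anchor_pa:
                    w.cur = (w.cur[0], idx)
                else:
                    self._retire_cur(w)
                    w.cur = (w.anchor_pa, idx)
            else:
                self._retire_cur(w)
                w.cur = None
            w.anchor_pa, w.anchor_occ = idx, occ

    def _retire_cur(self, w: WalkState) -> None:
        if w.cur is None:
            return
        if w.best is None:
            w.best = w.cur
        else:
            w.best = max(
                (w.best, w.cur),
                key=lambda r: (self.pa_cum[r[1]] - self.pa_cum[r[0]], -r[0]),
            )
        w.cur = None

    # -- Box 2: Update-collinear-walks -------------------------------------

    def update_collinear_walks(self, vertex, pa_idx: int) -> None:
        for fi, strand, i in self.g.in_edges.get(vertex, ()):
            if self.blocked(fi, strand, i):
                continue
            pos = self.g.jpos[fi, strand]
            # nearest walk whose b-extension contains edge i (the immediate
            # successor edge is reachable whatever its compacted length)
            cand = None
            for w in self.by_strand.get((fi, strand), ()):
                if w.hi > i:
                    continue
                if pos[i + 1] - pos[w.hi] > self.b and i > w.hi:
                    continue
                if cand is not None and pos[w.hi] <= pos[cand.hi]:
                    continue
                if any(self.blocked(fi, strand, e) for e in range(w.hi, i)):
                    continue
                cand = w
            if cand is not None:
                old_hi = cand.hi
                cand.hi = i + 1
                self._cover(fi, strand, old_hi, i + 1)
                self._advance_chain(cand, old_hi, cand.hi)
            else:
                u = self.g.tail_vertex(fi, strand, i)
                w = WalkState(fi, strand, i, i + 1,
                              anchor_pa=pa_idx, anchor_occ=i + 1)
                u_idx = self.pa_index.get(u)
                if (
                    u_idx is not None
                    and u_idx < pa_idx
                    and self._bubble_ok(u_idx, i, pa_idx, i + 1, fi, strand)
                ):
                    w.cur = (u_idx, pa_idx)
                self._add_walk(w)

    # -- Box 1 lines 10-14: pick the extension walk r ------------------------

    def choose_extension(self):
        """Return (source walk, last edge index) of the chosen walk r."""
        w0 = self.pa_vertices[-1]
        exts = []
        for w in self.walks:
            ext = b_extension(self.g, w.as_walk(), self.b, blocked=self.blocked)
            if ext is not None:
                exts.append((w, ext))
        if not exts:
            return None
        votes: dict = {}
        for w, ext in exts:
            vers = self.g.jver[w.fi, w.strand]
            for v in set(vers[ext.lo + 1 : ext.hi + 1]):
                votes[v] = votes.get(v, 0) + 1
        # candidate targets: on an extension leaving the carrying path's end,
        # truncated at the first vertex already on the path (path property)
        cands: dict = {}
        for w, ext in exts:
            vers = self.g.jver[w.fi, w.strand]
            if vers[w.hi] != w0:
                continue
            pos = self.g.jpos[w.fi, w.strand]
            base = pos[w.hi]
            prefix: list = []
            for e in range(ext.lo, ext.hi):
                v = vers[e + 1]
                if v in self.pa_index:
                    break
                prefix.append(v)
                key = (pos[e + 1] - base, tuple(prefix), (w.fi, w.strand, w.lo))
                if v not in cands or key < cands[v][0]:
                    cands[v] = (key, w, e)
        if not cands:
            return None
        t = min(cands, key=lambda v: (-votes.get(v, 0), cands[v][0][0], v))
        _, w, e_end = cands[t]
        return w, e_end

    # -- the phase loop ------------------------------------------------------

    def extend(self, max_phases: int = 10**9) -> None:
        self._maybe_snapshot()  # the seed state itself may be the best one
        phases = 0
        while self.f() >= 0 and phases < max_phases:
            phases += 1
            choice = self.choose_extension()
            if choice is None:
                break
            w, e_end = choice
            fi, strand = w.fi, w.strand
            vers = self.g.jver[fi, strand]
            start = w.hi
            for e in range(start, e_end + 1):
                idx = self._append_pa(
                    vers[e + 1], self.g.step(fi, strand, e),
                    self.g.spelled(fi, strand, e),
                )
                self.update_collinear_walks(vers[e + 1], idx)
                self._maybe_snapshot()

    # -- snapshot handling ---------------------------------------------------

    def restore_best(self) -> bool:
        """Rewind to the best snapshot; False when nothing scored > 0."""
        if self.best_snap is None:
            return False
        pa_len, walk_tuples = self.best_snap
        del self.pa_vertices[pa_len:]
        del self.pa_cum[pa_len:]
        del self.pa_labels[max(0, pa_len - 1):]
        self.pa_index = {v: i for i, v in enumerate(self.pa_vertices)}
        self.walks = [WalkState.thaw(t) for t in walk_tuples]
        self.by_strand = {}
        self.coverage = {}
        for w in self.walks:
            self.by_strand.setdefault((w.fi, w.strand), []).append(w)
            self._cover(w.fi, w.strand, w.lo, w.hi)
        return True


def _flip_state(build: BlockBuild, graph) -> BlockBuild:
    """Map a builder's state onto the opposite orientation of the graph."""
    out = BlockBuild(graph, build.b, build.m)
    n = len(build.pa_vertices)
    total = build.pa_cum[-1]
    out.pa_vertices = list(reversed(build.pa_vertices))
    out.pa_cum = [total - build.pa_cum[n - 1 - j] for j in range(n)]
    out.pa_labels = [lab[::-1] for lab in reversed(build.pa_labels)]
    out.pa_index = {v: i for i, v in enumerate(out.pa_vertices)}
    out.best_f = build.best_f

    def flip_run(run):
        if run is None:
            return None
        return (n - 1 - run[1], n - 1 - run[0])

    for w in build.walks:
        nv = len(build.g.jver[w.fi, w.strand])
        fw = WalkState(
            w.fi,
            w.strand,
            nv - 1 - w.hi,
            nv - 1 - w.lo,
            anchor_pa=n - 1 - w.anchor_pa,
            anchor_occ=nv - 1 - w.anchor_occ,
            cur=flip_run(w.cur),
            best=flip_run(w.best),
        )
        # after flipping, the anchor is the walk's *start*; further bubbles
        # must continue from the walk's current end, so re-anchor there if
        # the end vertex lies on the carrying path
        end_v = graph.jver[fw.fi, fw.strand][fw.hi]
        idx = out.pa_index.get(end_v)
        if idx is not None:
            fw.anchor_pa, fw.anchor_occ = idx, fw.hi
            run = max(
                (r for r in (fw.cur, fw.best) if r is not None),
                key=lambda r: (out.pa_cum[r[1]] - out.pa_cum[r[0]], -r[0]),
                default=None,
            )
            if run is not None and run[1] == idx:
                fw.cur, fw.best = run, None
            else:
                fw.cur, fw.best = None, run
        out._add_walk(fw)
    return out


# ---------------------------------------------------------------------------
# seed iteration and the top-level algorithm
# ---------------------------------------------------------------------------


def seed_iterator(graph: CompactedGraph, used: UsedMarks | None = None) -> Iterator[str]:
    """Distinct edge classes in lexicographic canonical-key order, skipping
    classes whose occurrences are all used."""
    check = used.is_used if used is not None else graph.is_used
    for key in sorted(graph.classes):
        if any(not check(*occ) for occ in graph.classes[key]):
            yield key


def init_block(seed_key: str, graph: CompactedGraph, b: int, m: int) -> BlockBuild:
    """Carrying path seeded with one edge; one walk per unused parallel
    occurrence of the seed class (both strands, via the canonical key)."""
    occs = [o for o in graph.classes[seed_key] if not graph.is_used(*o)]
    if not occs:
        raise ValueError(f"seed class {seed_key} has no unused occurrence")
    build = BlockBuild(graph, b, m)
    build.init_from_seed(seed_key, occs)
    return build


def find_block_from_seed(
    seed_key: str, graph: CompactedGraph, b: int, m: int
) -> CollinearBlock | None:
    """Box-1 exploration of one seed, rightward then leftward; returns the
    best block if its score is positive and it keeps >= 2 walks of length
    >= m, else None."""
    build = init_block(seed_key, graph, b, m)
    build.extend()
    if not build.restore_best():
        return None
    rev = ReversedView(graph) if not isinstance(graph, ReversedView) else graph.cg
    flipped = _flip_state(build, rev)
    flipped.best_f = build.best_f
    flipped.best_snap = (len(flipped.pa_vertices), tuple(w.freeze() for w in flipped.walks))
    flipped.extend()
    flipped.restore_best()
    final = _flip_state(flipped, graph)

    # definitional rescoring of the final state
    p_a = VWalk(tuple(final.pa_vertices), tuple(final.pa_cum),
                occ=("pa", seed_key), labels=tuple(final.pa_labels))
    kept: list[CollinearWalk] = []
    kept_scores: list[float] = []
    total = 0.0
    for w in final.walks:
        walk = w.as_walk()
        pos = graph.jpos[w.fi, w.strand]
        length = pos[w.hi] - pos[w.lo]
        if length < m:
            continue
        split = decompose_chain(p_a, vwalk_from_compacted(graph, walk), b)
        s = score_split(length, split, m, b)
        if s > 0:
            kept.append(walk)
            kept_scores.append(s)
            total += s
    if len(kept) < 2 or total <= 0:
        return None
    return CollinearBlock(p_a, kept, kept_scores, total)


def _mark_block(graph, block: CollinearBlock, used: UsedMarks) -> None:
    for w in block.walks:
        for e in range(w.lo, w.hi):
            used.mark(w.fi, w.strand, e)


def find_collinear_blocks(
    graph: CompactedGraph,
    b: int = 200,
    m: int = 50,
    batch_size: int | None = None,
) -> list[CollinearBlock]:
    """Run the full greedy algorithm over all seeds.

    Seeds whose class has fewer than two unused occurrences are skipped
    (they cannot yield a reportable block).  With ``batch_size`` set, seeds
    are explored speculatively against a frozen view of the used marks and
    an arbiter replays conflicting seeds serially, reproducing the serial
    result exactly.
    """
    used = UsedMarks(graph)
    blocks: list[CollinearBlock] = []
    keys = sorted(graph.classes)

    def live_occs(key):
        return [o for o in graph.classes[key] if not graph.is_used(*o)]

    if batch_size is None or batch_size <= 1:
        for key in keys:
            if len(live_occs(key)) < 2:
                continue
            blk = find_block_from_seed(key, graph, b, m)
            if blk is not None:
                _mark_block(graph, blk, used)
                blocks.append(blk)
        return blocks

    # speculative batches with a serial arbiter
    pending = [k for k in keys if len(live_occs(k)) >= 2]
    pos = 0
    while pos < len(pending):
        batch = pending[pos : pos + batch_size]
        pos += batch_size
        results = []
        for key in batch:
            if len(live_occs(key)) < 2:
                results.append((key, None, None))
                continue
            graph.read_log = set()
            blk = find_block_from_seed(key, graph, b, m)
            reads = graph.read_log
            graph.read_log = None
            results.append((key, blk, reads))
        writes: set = set()
        for key, blk, reads in results:
            if reads is None:
                continue
            if reads & writes:
                # conflict: replay serially against the real marks
                if len(live_occs(key)) < 2:
                    continue
                blk = find_block_from_seed(key, graph, b, m)
            if blk is None:
                continue
            _mark_block(graph, blk, used)
            for w in blk.walks:
                for e in range(w.lo, w.hi):
                    writes.add((w.fi, plus_index(graph, w.fi, w.strand, e)))
            blocks.append(blk)
    return blocks


# ---------------------------------------------------------------------------
# conversion to genomic block records
# ---------------------------------------------------------------------------


def blocks_to_records(
    graph: CompactedGraph, blocks: Sequence[CollinearBlock]
) -> list[BlockRecord]:
    """Convert walks to non-overlapping forward-strand genomic intervals.

    A walk occupies ``[jpos[lo], jpos[hi])`` in strand coordinates (the
    trailing k-mer belongs to whichever block continues there); a final
    sweep trims the rare residual overlap between opposite-strand twins so
    block occurrences partition their positions exactly.
    """
    records: list[BlockRecord] = []
    for bid, blk in enumerate(blocks, start=1):
        occs = []
        for w in blk.walks:
            frag = graph.fragments[w.fi]
            pos = graph.jpos[w.fi, w.strand]
            start, end = frag.to_forward(w.strand, pos[w.lo], pos[w.hi])
            occs.append(
                Occurrence(frag.genome_id, frag.seq_id, start, end, w.strand)
            )
        records.append(BlockRecord(bid, occs, score=blk.score))

    # overlap-resolution sweep (cross-strand twins can overlap by < k bases):
    # earlier-discovered blocks keep their span, later occurrences are
    # clipped at whichever end overlaps -- symmetric, so the result of
    # reverse-complemented input mirrors exactly
    taken: dict = {}
    for rec in records:  # records are in block-discovery order
        for j, occ in enumerate(rec.occurrences):
            ivals = taken.setdefault((occ.genome_id, occ.seq_id), [])
            start, end = occ.start, occ.end
            for s, e in ivals:
                if e <= start or s >= end:
                    continue
                if s <= start:
                    start = max(start, e)
                elif e >= end:
                    end = min(end, s)
                else:  # an earlier interval strictly inside: give up the walk
                    start = end
                    break
            if start >= end:
                rec.occurrences[j] = None
                continue
            if (start, end) != (occ.start, occ.end):
                rec.occurrences[j] = replace(occ, start=start, end=end)
            ivals.append((start, end))
    out = []
    for rec in records:
        rec.occurrences = [o for o in rec.occurrences if o is not None]
        if len(rec.occurrences) >= 2:
            out.append(rec)
    for new_id, rec in enumerate(out, start=1):
        rec.block_id = new_id
    return out
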