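"""Ordinary, comprehensive and compacted de Bruijn graphs.

Vertices are k-mers; every occurrence of a (k+1)-mer in an input strand is
one directed edge, and edges generated by the same (k+1)-mer are parallel.
Runs of non-ACGT characters split contigs into fragments: no k-mer spans
them.  The comprehensive graph is the union of the graph of every fragment
and of its reverse complement, which is how double-strandedness is handled.

The compacted graph keeps only junction k-mers (>=2 distinct out- or
in-neighbours) plus the first/last k-mer of every fragment as sentinels, so
every genomic position still lies on some compacted edge.  A compacted edge
between consecutive junction occurrences remembers its spelled sequence and
its length in (k+1)-mer steps; compaction is lossless.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from lcbkit.io import SequenceRecord, revcomp

_ACGT_RUN = re.compile("[ACGT]+")


class ParameterError(ValueError):
    pass


class GraphConsistencyError(ValueError):
    pass


@dataclass(frozen=True)
class Fragment:
    """Maximal ACGT run of one contig; the unit sequences walk along."""

    frag_idx: int
    genome_idx: int
    seq_idx: int
    genome_id: str
    seq_id: str
    contig_start: int  # offset of the fragment within its contig
    seq: str
    contig_len: int

    def strand_seq(self, strand: str) -> str:
        return self.seq if strand == "+" else revcomp(self.seq)

    def to_forward(self, strand: str, start: int, end: int) -> tuple[int, int]:
        """Map a strand-coordinate interval to forward contig coordinates."""
        if strand == "+":
            lo, hi = start, end
        else:
            lo, hi = len(self.seq) - end, len(self.seq) - start
        return self.contig_start + lo, self.contig_start + hi


def split_fragments(records: Sequence[SequenceRecord]) -> list[Fragment]:
    frags = []
    genome_ids: list[str] = []
    for rec in records:
        if rec.genome_id not in genome_ids:
            genome_ids.append(rec.genome_id)
    seq_ids: dict[str, list[str]] = {g: [] for g in genome_ids}
    for rec in records:
        if rec.seq_id in seq_ids[rec.genome_id]:
            raise ValueError(f"duplicate contig {rec.seq_id} in genome {rec.genome_id}")
        seq_ids[rec.genome_id].append(rec.seq_id)
        for m in _ACGT_RUN.finditer(rec.sequence):
            frags.append(
                Fragment(
                    frag_idx=len(frags),
                    genome_idx=genome_ids.index(rec.genome_id),
                    seq_idx=seq_ids[rec.genome_id].index(rec.seq_id),
                    genome_id=rec.genome_id,
                    seq_id=rec.seq_id,
                    contig_start=m.start(),
                    seq=m.group(),
                    contig_len=rec.length,
                )
            )
    return frags


@dataclass(frozen=True)
class GraphEdge:
    """One occurrence of a (k+1)-mer on one strand of one fragment."""

    frag_idx: int
    strand: str
    offset: int  # 0-based start, in strand coordinates
    kp1mer: str

    @property
    def pos(self) -> int:
        return self.offset


class DeBruijnGraph:
    """Multigraph of all k-mers / (k+1)-mer occurrences of the input."""

    def __init__(self, fragments: list[Fragment], k: int, strands: tuple[str, ...]):
        self.k = k
        self.fragments = fragments
        self.strands = strands
        # edge classes: (k+1)-mer -> occurrences, in (frag, strand, offset) order
        self.edge_classes: dict[str, list[GraphEdge]] = {}
        self.vertex_counts: dict[str, int] = {}
        for frag in fragments:
            for strand in strands:
                seq = frag.strand_seq(strand)
                for off in range(len(seq) - k + 1):
                    self.vertex_counts[seq[off : off + k]] = (
                        self.vertex_counts.get(seq[off : off + k], 0) + 1
                    )
                for off in range(len(seq) - k):
                    kp1 = seq[off : off + k + 1]
                    self.edge_classes.setdefault(kp1, []).append(
                        GraphEdge(frag.frag_idx, strand, off, kp1)
                    )

    # -- basic queries ------------------------------------------------------

    @property
    def vertices(self) -> set[str]:
        return set(self.vertex_counts)

    @property
    def double_stranded(self) -> bool:
        return len(self.strands) == 2

    def n_edge_occurrences(self) -> int:
        return sum(len(v) for v in self.edge_classes.values())

    def parallel_edges(self, kp1mer: str) -> list[GraphEdge]:
        return list(self.edge_classes.get(kp1mer, []))

    def fragment(self, frag_idx: int) -> Fragment:
        return self.fragments[frag_idx]

    def next_edge(self, edge: GraphEdge) -> GraphEdge | None:
        """Successor edge in the same strand of the same fragment, or None."""
        frag = self.fragments[edge.frag_idx]
        seq = frag.strand_seq(edge.strand)
        if seq[edge.offset : edge.offset + self.k + 1] != edge.kp1mer:
            raise LookupError(f"edge {edge} does not belong to this graph")
        off = edge.offset + 1
        if off > len(seq) - self.k - 1:
            return None
        return GraphEdge(edge.frag_idx, edge.strand, off, seq[off : off + self.k + 1])

    def twin(self, edge: GraphEdge) -> GraphEdge:
        """The same genomic location read on the opposite strand."""
        if not self.double_stranded:
            raise LookupError("twin edges exist only in the comprehensive graph")
        frag = self.fragments[edge.frag_idx]
        strand = "-" if edge.strand == "+" else "+"
        off = len(frag.seq) - self.k - 1 - edge.offset
        return GraphEdge(edge.frag_idx, strand, off, revcomp(edge.kp1mer))

    def genomic_walk_vertices(self, frag_idx: int, strand: str = "+") -> list[str]:
        seq = self.fragments[frag_idx].strand_seq(strand)
        return [seq[i : i + self.k] for i in range(len(seq) - self.k + 1)]


def _check_k(records: Sequence[SequenceRecord], k: int, frags: list[Fragment]):
    if k <= 1:
        raise ParameterError(f"k must be >= 2, got {k}")
    if not any(len(f.seq) > k for f in frags):
        warnings.warn("no fragment longer than k: the graph has no edges", stacklevel=3)


def build_graph(records: Sequence[SequenceRecord], k: int) -> DeBruijnGraph:
    """Single-strand de Bruijn graph of the input records."""
    frags = split_fragments(records)
    _check_k(records, k, frags)
    return DeBruijnGraph(frags, k, strands=("+",))


def comprehensive(records: Sequence[SequenceRecord], k: int) -> DeBruijnGraph:
    """Double-stranded graph: union with the reverse-complement strands."""
    frags = split_fragments(records)
    _check_k(records, k, frags)
    return DeBruijnGraph(frags, k, strands=("+", "-"))


# ---------------------------------------------------------------------------
# Junctions, abundance pruning, compaction
# ---------------------------------------------------------------------------


def find_junctions(g: DeBruijnGraph) -> set[str]:
    """K-mers with >=2 distinct out- or in-neighbours, plus fragment-end
    sentinels (kept so every contig remains representable after compaction).
    Self-loops contribute their vertex once to each neighbour set."""
    out_nb: dict[str, set[str]] = {}
    in_nb: dict[str, set[str]] = {}
    k = g.k
    for kp1 in g.edge_classes:
        u, v = kp1[:k], kp1[1:]
        out_nb.setdefault(u, set()).add(v)
        in_nb.setdefault(v, set()).add(u)
    junctions = {
        v
        for v in g.vertices
        if len(out_nb.get(v, ())) >= 2 or len(in_nb.get(v, ())) >= 2
    }
    junctions |= sentinel_junctions(g)
    return junctions


def sentinel_junctions(g: DeBruijnGraph) -> set[str]:
    k = g.k
    out = set()
    for frag in g.fragments:
        if len(frag.seq) < k:
            continue
        for strand in g.strands:
            seq = frag.strand_seq(strand)
            out.add(seq[:k])
            out.add(seq[len(seq) - k :])
    return out


def prune_abundance(junctions: set[str], g: DeBruijnGraph, a: int) -> set[str]:
    """Drop junction k-mers occurring more than ``a`` times (both strands
    combined) before compacted-edge construction; sentinels are retained."""
    if a < 1:
        raise ParameterError(f"abundance threshold must be >= 1, got {a}")
    sentinels = sentinel_junctions(g)
    # vertex_counts already sums both strands when the graph is comprehensive
    return {v for v in junctions if g.vertex_counts.get(v, 0) <= a or v in sentinels}


class CompactedGraph:
    """Junction occurrences per fragment strand plus compacted edges.

    A compacted edge is the run between two consecutive junction occurrences;
    it stores its spelled sequence (the fingerprint distinguishing parallel
    candidates that spell differently) and its length in (k+1)-mer steps.
    Edge occurrences are addressed as ``(frag_idx, strand, i)``; on the
    comprehensive graph the twin of ``(f, '+', i)`` is ``(f, '-', n-1-i)``
    and twins share "used" marks.
    """

    def __init__(self, g: DeBruijnGraph, junctions: set[str]):
        k = self.k = g.k
        self.double_stranded = g.double_stranded
        self.strands = g.strands
        self.fragments = g.fragments
        self.junctions = junctions
        missing = sentinel_junctions(g) - junctions
        if missing:
            raise GraphConsistencyError(
                f"junction set is missing fragment-end sentinels, e.g. {sorted(missing)[:3]}"
            )
        bad = junctions - g.vertices
        if bad:
            raise GraphConsistencyError(f"junctions not in graph: {sorted(bad)[:3]}")

        # ordered junction occurrences per fragment strand
        self.jpos: dict[tuple[int, str], list[int]] = {}
        self.jver: dict[tuple[int, str], list[str]] = {}
        for frag in g.fragments:
            for strand in g.strands:
                seq = frag.strand_seq(strand)
                if len(seq) < k:
                    self.jpos[frag.frag_idx, strand] = []
                    self.jver[frag.frag_idx, strand] = []
                    continue
                pos = [
                    p for p in range(len(seq) - k + 1) if seq[p : p + k] in junctions
                ]
                self.jpos[frag.frag_idx, strand] = pos
                self.jver[frag.frag_idx, strand] = [seq[p : p + k] for p in pos]
        if self.double_stranded:
            for frag in g.fragments:
                n_p = len(self.jpos[frag.frag_idx, "+"])
                n_m = len(self.jpos[frag.frag_idx, "-"])
                if n_p != n_m:
                    raise GraphConsistencyError(
                        "junction occurrences are not strand-symmetric on "
                        f"fragment {frag.frag_idx}"
                    )

        # edge classes keyed canonically
        self.classes: dict[str, list[tuple[int, str, int]]] = {}
        self.in_edges: dict[str, list[tuple[int, str, int]]] = {}
        for (fi, strand), pos in sorted(self.jpos.items()):
            vers = self.jver[fi, strand]
            for i in range(len(pos) - 1):
                sp = self.spelled(fi, strand, i)
                occ = (fi, strand, i)
                if not self.double_stranded:
                    self.classes.setdefault(sp, []).append(occ)
                else:
                    key = self.canonical_key(sp)
                    # occurrences are listed in the canonical spelling only,
                    # which dedups strand twins (each genomic location shows
                    # up once); a palindromic spelling keeps only '+'
                    if sp == key and (sp != revcomp(sp) or strand == "+"):
                        self.classes.setdefault(key, []).append(occ)
                self.in_edges.setdefault(vers[i + 1], []).append((fi, strand, i))
        # order in-edge occurrences by their physical (strand-invariant)
        # identity so the greedy walk updates are strand-equivariant
        for lst in self.in_edges.values():
            lst.sort(key=lambda occ: (occ[0], self._plus_index(*occ), occ[1]))
        self._used: dict[int, list[bool]] = {
            f.frag_idx: [False] * max(0, len(self.jpos.get((f.frag_idx, "+"), [])) - 1)
            for f in g.fragments
        }
        # when set (speculative batch exploration), is_used records what it
        # was asked, so an arbiter can detect conflicts between seeds
        self.read_log: set | None = None

    # -- geometry -----------------------------------------------------------

    def n_edges(self, fi: int, strand: str) -> int:
        return max(0, len(self.jpos[fi, strand]) - 1)

    def step(self, fi: int, strand: str, i: int) -> int:
        pos = self.jpos[fi, strand]
        return pos[i + 1] - pos[i]

    def spelled(self, fi: int, strand: str, i: int) -> str:
        pos = self.jpos[fi, strand]
        seq = self.fragments[fi].strand_seq(strand)
        return seq[pos[i] : pos[i + 1] + self.k]

    def canonical_key(self, spelled: str) -> str:
        return min(spelled, revcomp(spelled)) if self.double_stranded else spelled

    def edge_key(self, fi: int, strand: str, i: int) -> str:
        return self.canonical_key(self.spelled(fi, strand, i))

    def head_vertex(self, fi: int, strand: str, i: int) -> str:
        return self.jver[fi, strand][i + 1]

    def tail_vertex(self, fi: int, strand: str, i: int) -> str:
        return self.jver[fi, strand][i]

    def twin(self, fi: int, strand: str, i: int) -> tuple[int, str, int]:
        if not self.double_stranded:
            raise LookupError("twins exist only on the comprehensive graph")
        other = "-" if strand == "+" else "+"
        return fi, other, self.n_edges(fi, other) - 1 - i

    def _plus_index(self, fi: int, strand: str, i: int) -> int:
        if strand == "+" or not self.double_stranded:
            return i
        return self.n_edges(fi, "+") - 1 - i

    # -- used marks (shared between strand twins) ---------------------------

    def is_used(self, fi: int, strand: str, i: int) -> bool:
        pi = self._plus_index(fi, strand, i)
        if self.read_log is not None:
            self.read_log.add((fi, pi))
        return self._used[fi][pi]

    def mark_used(self, fi: int, strand: str, i: int) -> None:
        self._used[fi][self._plus_index(fi, strand, i)] = True

    def any_unused(self, occurrences: Iterable[tuple[int, str, int]]) -> bool:
        return any(not self.is_used(*occ) for occ in occurrences)

    # -- reconstruction -----------------------------------------------------

    def decompress(self) -> list[str]:
        """Spell every fragment back from its '+' strand compacted edges."""
        out = []
        for frag in self.fragments:
            pos = self.jpos[frag.frag_idx, "+"]
            if len(pos) < 2:
                out.append(frag.seq)
                continue
            parts = [self.spelled(frag.frag_idx, "+", 0)]
            for i in range(1, len(pos) - 1):
                parts.append(self.spelled(frag.frag_idx, "+", i)[self.k :])
            out.append("".join(parts))
        return out

    def write_gfa(self, path) -> None:
        """Debug dump: GFA1 with junction-to-junction segments."""
        seen: dict[str, int] = {}
        links = set()
        lines = ["H\tVN:Z:1.0"]
        for (fi, strand), pos in sorted(self.jpos.items()):
            prev = None
            for i in range(len(pos) - 1):
                key = self.edge_key(fi, strand, i)
                if key not in seen:
                    seen[key] = len(seen) + 1
                    lines.append(f"S\t{seen[key]}\t{key}")
                if prev is not None:
                    links.add((prev, seen[key]))
                prev = seen[key]
        lines += [f"L\t{a}\t+\t{b}\t+\t{self.k}M" for a, b in sorted(links)]
        from pathlib import Path

        Path(path).write_text("\n".join(lines) + "\n")


def compact(g: DeBruijnGraph, junctions: set[str]) -> CompactedGraph:
    return CompactedGraph(g, junctions)


def build_compacted(
    records: Sequence[SequenceRecord],
    k: int,
    a: int | None = None,
    double_stranded: bool = True,
) -> CompactedGraph:
    """Convenience pipeline: graph -> junctions -> pruning -> compaction."""
    g = comprehensive(records, k) if double_stranded else build_graph(records, k)
    junctions = find_junctions(g)
    if a is not None:
        junctions = prune_abundance(junctions, g, a)
    return compact(g, junctions)
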