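"""Center-star multiple alignment of block occurrences.

Blocks of closely related genomes are near-identical, so a simple global
strategy suffices: pick the center sequence minimising the summed unit-cost
(match 0, mismatch 1, indel 1) pairwise distance to the others, align every
other sequence to the center (edlib, Needleman-Wunsch mode), and merge with
the "once a gap, always a gap" rule.  Ties choose the first index, so the
output is deterministic.
"""

from __future__ import annotations

from typing import Sequence

import edlib

from lcbkit.io import AlignedBlock, AlignedRow, BlockRecord, Occurrence, SequenceRecord, revcomp


class AlignmentError(ValueError):
    pass


def _pairwise(query: str, target: str) -> tuple[str, str]:
    """Unit-cost global alignment; returns (query_aligned, target_aligned)."""
    res = edlib.align(query, target, mode="NW", task="path")
    nice = edlib.getNiceAlignment(res, query, target)
    return nice["query_aligned"], nice["target_aligned"]


def align_strings(sequences: Sequence[str]) -> list[str]:
    """Gapped rows of the center-star alignment, in input order."""
    if len(sequences) < 2:
        raise AlignmentError("need at least two sequences to align")
    for i, s in enumerate(sequences):
        if not s:
            raise AlignmentError(f"sequence {i} is empty")
    n = len(sequences)
    if len(set(sequences)) == 1:
        return list(sequences)

    # center = argmin of summed pairwise edit distance (max summed identity)
    dist = [[0] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            d = edlib.align(sequences[i], sequences[j], mode="NW", task="distance")[
                "editDistance"
            ]
            dist[i][j] = dist[j][i] = d
    center = min(range(n), key=lambda i: (sum(dist[i]), i))
    ctr = sequences[center]
    L = len(ctr)

    # per row: chars aligned to each center position, plus insertions before
    # each center position (index L = after the last)
    subs: list[list[str]] = []
    inss: list[list[str]] = []
    for i, seq in enumerate(sequences):
        if i == center:
            subs.append(list(ctr))
            inss.append([""] * (L + 1))
            continue
        qa, ta = _pairwise(seq, ctr)
        sub = []
        ins = [""] * (L + 1)
        cpos = 0
        for qc, tc in zip(qa, ta):
            if tc == "-":
                ins[cpos] += qc
            else:
                sub.append(qc)
                cpos += 1
        subs.append(sub)
        inss.append(ins)

    gap_w = [max(len(ins[c]) for ins in inss) for c in range(L + 1)]
    rows = []
    for sub, ins in zip(subs, inss):
        parts = []
        for c in range(L):
            parts.append(ins[c] + "-" * (gap_w[c] - len(ins[c])))
            parts.append(sub[c])
        parts.append(ins[L] + "-" * (gap_w[L] - len(ins[L])))
        rows.append("".join(parts))
    return rows


def align_block(
    sequences: Sequence[str],
    block_id: int = 0,
    occurrences: Sequence[Occurrence] | None = None,
    src_sizes: Sequence[int] | None = None,
) -> AlignedBlock:
    """Align one block's sequences; metadata defaults to synthetic rows."""
    rows = align_strings(sequences)
    blk = AlignedBlock(block_id=block_id)
    for i, text in enumerate(rows):
        if occurrences is None:
            occ = Occurrence(f"seq{i}", f"seq{i}", 0, len(sequences[i]), "+")
            size = len(sequences[i])
        else:
            occ = occurrences[i]
            size = src_sizes[i] if src_sizes is not None else occ.end
        blk.rows.append(AlignedRow(occ, text, size))
    return blk


def align_all(
    blocks: Sequence[BlockRecord], genomes: Sequence[SequenceRecord]
) -> list[AlignedBlock]:
    """Extract every occurrence's sequence (strand-aware) and align it."""
    contigs = {(rec.genome_id, rec.seq_id): rec.sequence for rec in genomes}
    out = []
    for blk in sorted(blocks, key=lambda b: b.block_id):
        seqs = []
        sizes = []
        for occ in blk.occurrences:
            contig = contigs.get((occ.genome_id, occ.seq_id))
            if contig is None or occ.end > len(contig):
                raise AlignmentError(
                    f"occurrence {occ} lies outside the provided contigs"
                )
            s = contig[occ.start : occ.end]
            seqs.append(s if occ.strand == "+" else revcomp(s))
            sizes.append(len(contig))
        out.append(align_block(seqs, blk.block_id, blk.occurrences, sizes))
    return out
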