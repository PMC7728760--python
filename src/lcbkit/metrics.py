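"""Alignment evaluation: position-pair recall/precision, coverage,
nucleotide identity and per-column average nucleotide differences.

An alignment is viewed as an equivalence relation over genomic positions:
every column of every block relates the positions it aligns.  Recall and
precision compare a predicted relation A with a truth relation H::

    recall    = 1 - |H \\ A| / |H|
    precision = 1 - |A \\ H| / |A|

The per-column statistic pi(c) is the average number of pairwise
nucleotide differences, counting a pair only when both characters are
valid DNA characters; it proxies precision when no ground truth exists.
"""

from __future__ import annotations

from math import comb
from typing import Iterable, Sequence

import numpy as np

from lcbkit.io import AlignedBlock, BlockRecord, SequenceRecord

_VALID = frozenset("ACGT")


class MetricError(ValueError):
    """Metric undefined on this input (e.g. empty relation)."""


# interning of (genome_id, seq_id) pairs, shared so that relations built
# independently (truth vs prediction) remain directly comparable
_SEQ_IDS: dict[tuple[str, str], int] = {}


def _sid(genome_id: str, seq_id: str) -> int:
    key = (genome_id, seq_id)
    if key not in _SEQ_IDS:
        _SEQ_IDS[key] = len(_SEQ_IDS)
    return _SEQ_IDS[key]


class HomologyRelation:
    """Symmetric set of aligned position pairs, strand-annotated.

    A pair is stored as (endpoint_a, endpoint_b, same_strand) with the
    endpoints ordered, so membership is invariant under swapping the
    endpoints or flipping both strands jointly.
    """

    def __init__(self):
        self._pairs: set[tuple[int, int, int, int, bool]] = set()

    def __len__(self) -> int:
        return len(self._pairs)

    def add(
        self,
        a: tuple[str, str, int, str],
        b: tuple[str, str, int, str],
    ) -> None:
        key = self._key(a, b)
        if key is not None:
            self._pairs.add(key)

    @staticmethod
    def _key(a, b):
        ga, sa, pa, ta = a
        gb, sb, pb, tb = b
        ia, ib = _sid(ga, sa), _sid(gb, sb)
        if (ia, pa) == (ib, pb):
            return None  # no self-pairs
        same = ta == tb
        if (ia, pa) > (ib, pb):
            ia, pa, ib, pb = ib, pb, ia, pa
        return (ia, pa, ib, pb, same)

    def __contains__(self, pair) -> bool:
        return self._key(*pair) in self._pairs

    def add_bulk(self, sid_a: int, pos_a, strand_a: str,
                 sid_b: int, pos_b, strand_b: str) -> None:
        same = strand_a == strand_b
        pairs = self._pairs
        for pa, pb in zip(pos_a, pos_b):
            if (sid_a, pa) < (sid_b, pb):
                pairs.add((sid_a, pa, sid_b, pb, same))
            elif (sid_a, pa) > (sid_b, pb):
                pairs.add((sid_b, pb, sid_a, pa, same))

    def difference_size(self, other: "HomologyRelation") -> int:
        return len(self._pairs - other._pairs)

    def to_tsv(self, path) -> None:
        names = {v: k for k, v in _SEQ_IDS.items()}
        with open(path, "w") as fh:
            fh.write("genome_a\tseq_a\tpos_a\tgenome_b\tseq_b\tpos_b\tsame_strand\n")
            for ia, pa, ib, pb, same in sorted(self._pairs):
                ga, sa = names[ia]
                gb, sb = names[ib]
                fh.write(f"{ga}\t{sa}\t{pa}\t{gb}\t{sb}\t{pb}\t{int(same)}\n")

    @classmethod
    def from_tsv(cls, path) -> "HomologyRelation":
        rel = cls()
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("genome_a"):
                raise MetricError(f"{path}: missing truth-table header")
            for line in fh:
                ga, sa, pa, gb, sb, pb, same = line.rstrip("\n").split("\t")
                rel.add(
                    (ga, sa, int(pa), "+"),
                    (gb, sb, int(pb), "+" if same == "1" else "-"),
                )
        return rel


def relation_from_maf(aligned_blocks: Iterable[AlignedBlock]) -> HomologyRelation:
    """Relation induced by the alignment: one pair per column per pair of
    rows with valid nucleotides in that column; gaps contribute nothing."""
    rel = HomologyRelation()
    for blk in aligned_blocks:
        rows = []
        for row in blk.rows:
            arr = np.frombuffer(row.text.encode("ascii"), dtype=np.uint8)
            nongap = arr != ord("-")
            valid = np.isin(arr, np.frombuffer(b"ACGT", dtype=np.uint8))
            idx = np.cumsum(nongap) - 1
            occ = row.occurrence
            if occ.strand == "+":
                pos = occ.start + idx
            else:
                pos = occ.end - 1 - idx
            rows.append((occ, valid, pos))
        for i in range(len(rows)):
            occ_i, val_i, pos_i = rows[i]
            sid_i = _sid(occ_i.genome_id, occ_i.seq_id)
            for j in range(i + 1, len(rows)):
                occ_j, val_j, pos_j = rows[j]
                mask = val_i & val_j
                rel.add_bulk(
                    sid_i, pos_i[mask].tolist(), occ_i.strand,
                    _sid(occ_j.genome_id, occ_j.seq_id), pos_j[mask].tolist(),
                    occ_j.strand,
                )
    return rel


def recall(H: HomologyRelation, A: HomologyRelation) -> float:
    """1 - |H \\ A| / |H|: the fraction of true pairs recovered."""
    if len(H) == 0:
        raise MetricError("recall undefined: empty truth relation")
    return 1.0 - H.difference_size(A) / len(H)


def precision(H: HomologyRelation, A: HomologyRelation) -> float:
    """1 - |A \\ H| / |A|: the fraction of predicted pairs that are true."""
    if len(A) == 0:
        raise MetricError("precision undefined: empty predicted relation")
    return 1.0 - A.difference_size(H) / len(A)


def coverage(blocks: Sequence[BlockRecord], genomes: Sequence[SequenceRecord]) -> float:
    """Fraction of total genome length included in some block occurrence."""
    total = sum(rec.length for rec in genomes)
    if total == 0:
        return 0.0
    by_seq: dict = {}
    for blk in blocks:
        for occ in blk.occurrences:
            by_seq.setdefault((occ.genome_id, occ.seq_id), []).append(
                (occ.start, occ.end)
            )
    covered = 0
    for ivals in by_seq.values():
        ivals.sort()
        cur_s, cur_e = ivals[0]
        for s, e in ivals[1:]:
            if s > cur_e:
                covered += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        covered += cur_e - cur_s
    return covered / total


def pi_column(column: Sequence[str]) -> float:
    """Average number of pairwise nucleotide differences in one column.

    A pair counts 1 only when both characters are valid, distinct DNA
    characters; the denominator is C(|c|, 2) regardless of gaps.
    """
    n = len(column)
    if n < 2:
        raise MetricError("pi undefined on columns with fewer than 2 rows")
    diffs = 0
    for i in range(n):
        ci = column[i]
        if ci not in _VALID:
            continue
        for j in range(i + 1, n):
            cj = column[j]
            if cj in _VALID and ci != cj:
                diffs += 1
    return diffs / comb(n, 2)


def pi_profile(aligned_blocks: Iterable[AlignedBlock]) -> np.ndarray:
    """pi(c) for every column of every block with >= 2 rows (vectorised)."""
    out = []
    valid_bytes = np.frombuffer(b"ACGT", dtype=np.uint8)
    for blk in aligned_blocks:
        if len(blk.rows) < 2:
            continue
        mat = np.vstack(
            [np.frombuffer(r.text.encode("ascii"), dtype=np.uint8) for r in blk.rows]
        )
        valid = np.isin(mat, valid_bytes)
        n = mat.shape[0]
        diffs = np.zeros(mat.shape[1], dtype=np.int64)
        for i in range(n):
            for j in range(i + 1, n):
                diffs += (mat[i] != mat[j]) & valid[i] & valid[j]
        out.append(diffs / comb(n, 2))
    return np.concatenate(out) if out else np.array([])


def nucleotide_identity(row_a: str, row_b: str) -> float:
    """Matched nucleotides over alignment length, gaps included."""
    if len(row_a) != len(row_b):
        raise MetricError("rows of unequal aligned length")
    if not row_a:
        raise MetricError("empty alignment")
    matches = sum(
        1 for a, b in zip(row_a, row_b) if a == b and a in _VALID
    )
    return matches / len(row_a)


def identity_bins(
    values: Sequence[float], width: float = 0.05, lo: float = 0.0, hi: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Left-closed identity histogram (the last bin includes ``hi``)."""
    edges = np.arange(lo, hi + width / 2, width)
    counts, _ = np.histogram(values, bins=np.append(edges, np.inf))
    counts[-2] += counts[-1]
    return edges, counts[:-1]
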