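"""Genome input and block/alignment output.

Internal coordinates are 0-based, half-open, on the forward strand;
conversion to the 1-based GFF3 convention and the reverse-strand MAF
convention happens only at the format boundary.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import AlignIO, SeqIO

# Full IUPAC nucleotide alphabet; characters outside ACGT are kept in the
# sequence but never enter a k-mer (they act as fragment breakers downstream).
IUPAC_CHARS = frozenset("ACGTURYSWKMBDHVN")

_COMPLEMENT = str.maketrans("ACGTURYSWKMBDHVN", "TGCAAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


class FastaError(ValueError):
    """Malformed or empty FASTA input."""


class FormatError(ValueError):
    """Inconsistent records handed to a writer."""


@dataclass(frozen=True)
class SequenceRecord:
    """One contig of one genome, uppercased on ingest."""

    genome_id: str
    seq_id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Occurrence:
    """One placement of a block: a genomic interval plus its strand."""

    genome_id: str
    seq_id: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    strand: str  # "+" or "-"

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class BlockRecord:
    """A locally collinear block: >=2 pairwise non-overlapping occurrences."""

    block_id: int
    occurrences: list[Occurrence]
    score: float | None = None


@dataclass
class AlignedRow:
    """One gapped row of an aligned block.

    ``text`` with gaps stripped equals the occurrence's genomic sequence
    (reverse-complemented for '-' strand rows); ``src_size`` is the length
    of the source contig, needed for the MAF reverse-strand convention.
    """

    occurrence: Occurrence
    text: str
    src_size: int


@dataclass
class AlignedBlock:
    block_id: int
    rows: list[AlignedRow] = field(default_factory=list)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0].text) if self.rows else 0


def _line_of_offset(path, offset: int) -> int:
    text = Path(path).read_text()
    return text.count("\n", 0, offset) + 1


def read_fasta(path, genome_id: str) -> list[SequenceRecord]:
    """Read one genome (possibly many contigs) from a FASTA file.

    Lowercase is normalised to uppercase; characters outside the IUPAC
    nucleotide alphabet are rejected with the offending line number.
    """
    path = Path(path)
    raw = path.read_text()
    if not raw.strip():
        raise FastaError(f"{path}: empty input, no sequences found")
    first = next(l for l in raw.splitlines() if l.strip())
    if not first.startswith(">"):
        raise FastaError(f"{path}: line 1: expected FASTA header starting with '>'")

    records = []
    seen = set()
    for rec in SeqIO.parse(_stdio.StringIO(raw), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise FastaError(f"{path}: empty contig {rec.id}")
        bad = set(seq) - IUPAC_CHARS
        if bad:
            pos = min(seq.index(c) for c in bad)
            # locate the character in the raw text for a line-numbered error
            hdr = raw.index(">" + rec.description.split()[0] if rec.description else ">")
            line = _line_of_offset(path, raw.find(seq[pos], hdr) if raw.find(seq[pos], hdr) >= 0 else hdr)
            raise FastaError(
                f"{path}: line {line}: contig {rec.id} contains non-IUPAC "
                f"character {sorted(bad)[0]!r}"
            )
        if rec.id in seen:
            raise FastaError(f"{path}: duplicate contig id {rec.id}")
        seen.add(rec.id)
        records.append(SequenceRecord(genome_id=genome_id, seq_id=rec.id, sequence=seq))
    if not records:
        raise FastaError(f"{path}: empty input, no sequences found")
    return records


def write_fasta(records: Sequence[SequenceRecord], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.seq_id}\n")
            for i in range(0, rec.length, width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3 block coordinates
# ---------------------------------------------------------------------------

GFF_SOURCE = "lcbkit"
GFF_TYPE = "collinear_block"


def _check_blocks(blocks: Iterable[BlockRecord]) -> None:
    per_seq: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for blk in blocks:
        if len(blk.occurrences) < 2:
            raise FormatError(f"block {blk.block_id} has fewer than 2 occurrences")
        for occ in blk.occurrences:
            per_seq.setdefault((occ.genome_id, occ.seq_id), []).append((occ.start, occ.end))
    for key, ivals in per_seq.items():
        ivals.sort()
        for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
            if s2 < e1:
                raise FormatError(f"overlapping occurrences on {key}: [{s1},{e1}) and [{s2},{e2})")


def write_blocks_gff(blocks: Sequence[BlockRecord], path) -> None:
    """Write blocks as GFF3, one feature per occurrence (1-based inclusive)."""
    _check_blocks(blocks)
    lines = ["##gff-version 3"]
    for blk in sorted(blocks, key=lambda b: b.block_id):
        score = "." if blk.score is None else f"{blk.score:g}"
        for occ in sorted(blk.occurrences, key=lambda o: (o.genome_id, o.seq_id, o.start)):
            seqid = f"{occ.genome_id}.{occ.seq_id}"
            lines.append(
                "\t".join(
                    [
                        seqid,
                        GFF_SOURCE,
                        GFF_TYPE,
                        str(occ.start + 1),
                        str(occ.end),
                        score,
                        occ.strand,
                        ".",
                        f"ID=block_{blk.block_id}",
                    ]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_blocks_gff(path) -> list[BlockRecord]:
    """Parse a GFF3 file written by :func:`write_blocks_gff` back to records."""
    blocks: dict[int, BlockRecord] = {}
    for raw in Path(path).read_text().splitlines():
        if not raw or raw.startswith("#"):
            continue
        cols = raw.split("\t")
        if len(cols) != 9:
            raise FormatError(f"bad GFF line: {raw!r}")
        seqid, _src, _type, start, end, score, strand, _phase, attrs = cols
        genome_id, seq_id = seqid.split(".", 1)
        ident = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)["ID"]
        block_id = int(ident.removeprefix("block_"))
        occ = Occurrence(genome_id, seq_id, int(start) - 1, int(end), strand)
        blk = blocks.setdefault(
            block_id,
            BlockRecord(block_id, [], None if score == "." else float(score)),
        )
        blk.occurrences.append(occ)
    return [blocks[b] for b in sorted(blocks)]


# ---------------------------------------------------------------------------
# MAF aligned blocks
# ---------------------------------------------------------------------------


def write_maf(aligned_blocks: Sequence[AlignedBlock], path) -> None:
    """Write aligned blocks in MAF.

    Reverse-strand rows follow the MAF convention: ``start`` counts from the
    start of the reverse-complemented source and the text is the
    reverse-complemented sequence.
    """
    with open(path, "w") as fh:
        fh.write("##maf version=1 scoring=none\n")
        fh.write(f"# generated by {GFF_SOURCE}\n")
        for blk in aligned_blocks:
            if not blk.rows:
                continue
            ncol = len(blk.rows[0].text)
            for row in blk.rows:
                if len(row.text) != ncol:
                    raise FormatError(
                        f"block {blk.block_id}: ragged rows "
                        f"({len(row.text)} != {ncol} columns)"
                    )
                ungapped = len(row.text) - row.text.count("-")
                if ungapped != row.occurrence.length:
                    raise FormatError(
                        f"block {blk.block_id}: row length {ungapped} does not "
                        f"match occurrence span {row.occurrence.length}"
                    )
            fh.write("\na label=block_%d\n" % blk.block_id)
            for row in blk.rows:
                occ = row.occurrence
                if occ.strand == "+":
                    start = occ.start
                else:
                    start = row.src_size - occ.end
                src = f"{occ.genome_id}.{occ.seq_id}"
                fh.write(
                    f"s {src} {start} {occ.length} {occ.strand} {row.src_size} {row.text}\n"
                )
        fh.write("\n")


def read_maf(path) -> list[AlignedBlock]:
    """Read a MAF file into AlignedBlocks (via Biopython's MAF parser)."""
    out = []
    with open(path) as fh:
        for bid, msa in enumerate(AlignIO.parse(fh, "maf")):
            blk = AlignedBlock(block_id=bid)
            for seqrec in msa:
                ann = seqrec.annotations
                genome_id, seq_id = seqrec.id.split(".", 1)
                strand = "+" if ann["strand"] in (1, "+") else "-"
                size, src_size, start = ann["size"], ann["srcSize"], ann["start"]
                fwd_start = start if strand == "+" else src_size - start - size
                occ = Occurrence(genome_id, seq_id, fwd_start, fwd_start + size, strand)
                blk.rows.append(AlignedRow(occ, str(seqrec.seq).upper(), src_size))
            out.append(blk)
    return out
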