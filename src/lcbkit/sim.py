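"""Synthetic closely related genomes with exact homology ground truth.

A uniform random ancestor is evolved independently into each genome (a
star phylogeny, so the single divergence parameter is the root-to-leaf
distance): per-site substitutions, short geometric indels, then a fixed
number of inversions (reverse complement in place) and tandem segmental
duplications.  Every surviving position remembers the ancestral position
and orientation it descends from, so the exact set of homologous position
pairs — the truth relation all evaluation metrics compare against — is
known by construction.  Inserted bases carry no ancestry; duplicated
copies inherit the ancestry of the segment they copy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from lcbkit.io import SequenceRecord
from lcbkit.metrics import HomologyRelation

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class EvolutionParams:
    """Evolutionary regime of the simulation.

    Rates are per site on the branch from the most recent common ancestor
    to each leaf; the defaults emulate closely related genomes (strains of
    one species) at 0.02 substitutions/site to the MRCA, with occasional
    short indels and one inversion and one tandem duplication per genome.
    """

    ancestor_len: int = 50_000
    n_genomes: int = 3
    substitution_rate: float = 0.02
    indel_rate: float = 0.002
    indel_mean_len: float = 3.0
    n_inversions: int = 1
    inversion_len: tuple[int, int] = (500, 2000)
    n_duplications: int = 1
    duplication_len: tuple[int, int] = (200, 1000)
    seed: int = 0

    def validate(self) -> None:
        for name in ("substitution_rate", "indel_rate"):
            r = getattr(self, name)
            if not 0.0 <= r <= 1.0:
                raise SimulationError(f"{name} must be in [0, 1], got {r}")
        if self.ancestor_len < 1 or self.n_genomes < 1:
            raise SimulationError("ancestor_len and n_genomes must be positive")
        if self.indel_mean_len < 1:
            raise SimulationError("indel_mean_len must be >= 1")
        for name in ("inversion_len", "duplication_len"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise SimulationError(f"{name} must be a positive range")


@dataclass
class GenomeAncestry:
    """Per-position ancestry of one simulated genome."""

    genome_id: str
    anc: np.ndarray  # ancestral position, -1 for inserted bases
    strand: np.ndarray  # +1 forward, -1 inverted relative to the ancestor
    log: list[str] = field(default_factory=list)


@dataclass
class TruthMap:
    """Ground-truth homology of a simulated dataset."""

    ancestries: list[GenomeAncestry]
    seq_id: str = "chr1"

    def relation(self) -> HomologyRelation:
        """All pairs of positions descending from one ancestral position
        (cross-genome, plus within-genome pairs created by duplication)."""
        by_anc: dict[int, list[tuple[str, int, str]]] = {}
        for ga in self.ancestries:
            anc = ga.anc
            strand = ga.strand
            for pos in range(len(anc)):
                a = anc[pos]
                if a >= 0:
                    by_anc.setdefault(int(a), []).append(
                        (ga.genome_id, pos, "+" if strand[pos] > 0 else "-")
                    )
        rel = HomologyRelation()
        for entries in by_anc.values():
            if len(entries) < 2:
                continue
            for i in range(len(entries)):
                gi, pi, si = entries[i]
                for j in range(i + 1, len(entries)):
                    gj, pj, sj = entries[j]
                    rel.add((gi, self.seq_id, pi, si), (gj, self.seq_id, pj, sj))
        return rel


def _evolve(
    codes: np.ndarray, params: EvolutionParams, rng: np.random.Generator, gid: str
) -> tuple[np.ndarray, GenomeAncestry]:
    n0 = len(codes)
    codes = codes.copy()
    anc = np.arange(n0, dtype=np.int64)
    strand = np.ones(n0, dtype=np.int8)
    log: list[str] = []

    # point substitutions: uniform over the three alternative bases
    mask = rng.random(n0) < params.substitution_rate
    codes[mask] = (codes[mask] + rng.integers(1, 4, size=int(mask.sum()))) % 4
    log.append(f"substitutions\t{int(mask.sum())}")

    # indels: geometric lengths, insertions and deletions equally likely;
    # applied right to left so earlier event positions stay valid
    sites = np.flatnonzero(rng.random(n0) < params.indel_rate)
    is_ins = rng.random(len(sites)) < 0.5
    lengths = rng.geometric(1.0 / params.indel_mean_len, size=len(sites))
    for p, ins, length in zip(sites[::-1], is_ins[::-1], lengths[::-1]):
        if ins:
            new = rng.integers(0, 4, size=length).astype(codes.dtype)
            codes = np.insert(codes, p, new)
            anc = np.insert(anc, p, np.full(length, -1, dtype=anc.dtype))
            strand = np.insert(strand, p, np.ones(length, dtype=strand.dtype))
            log.append(f"insertion\t{p}\t{length}")
        else:
            stop = min(p + length, len(codes))
            codes = np.delete(codes, slice(p, stop))
            anc = np.delete(anc, slice(p, stop))
            strand = np.delete(strand, slice(p, stop))
            log.append(f"deletion\t{p}\t{stop - p}")

    # inversions: reverse complement in place, ancestry strands flip
    for _ in range(params.n_inversions):
        lo_len, hi_len = params.inversion_len
        length = int(rng.integers(lo_len, hi_len + 1))
        length = min(length, len(codes))
        start = int(rng.integers(0, len(codes) - length + 1))
        sl = slice(start, start + length)
        codes[sl] = (3 - codes[sl])[::-1]
        anc[sl] = anc[sl][::-1]
        strand[sl] = -strand[sl][::-1]
        log.append(f"inversion\t{start}\t{length}")

    # tandem duplications: the copy inherits the segment's ancestry
    for _ in range(params.n_duplications):
        lo_len, hi_len = params.duplication_len
        length = int(rng.integers(lo_len, hi_len + 1))
        length = min(length, len(codes))
        start = int(rng.integers(0, len(codes) - length + 1))
        sl = slice(start, start + length)
        codes = np.insert(codes, start + length, codes[sl])
        anc = np.insert(anc, start + length, anc[sl])
        strand = np.insert(strand, start + length, strand[sl])
        log.append(f"duplication\t{start}\t{length}")

    return codes, GenomeAncestry(gid, anc, strand, log)


def simulate(params: EvolutionParams) -> tuple[list[SequenceRecord], TruthMap]:
    """Draw an ancestor and evolve ``n_genomes`` independent descendants."""
    params.validate()
    streams = np.random.SeedSequence(params.seed).spawn(params.n_genomes + 1)
    anc_rng = np.random.default_rng(streams[0])
    ancestor = anc_rng.integers(0, 4, size=params.ancestor_len).astype(np.uint8)

    records = []
    ancestries = []
    for g in range(params.n_genomes):
        rng = np.random.default_rng(streams[g + 1])
        gid = f"g{g + 1}"
        codes, ga = _evolve(ancestor, params, rng, gid)
        seq = _BASES[codes].tobytes().decode("ascii")
        records.append(SequenceRecord(gid, "chr1", seq))
        ancestries.append(ga)
    return records, TruthMap(ancestries)


def worked_example_fixtures() -> dict:
    """Tiny named inputs used throughout the tests.

    ``substitution_pair``: two 8 bp strings differing by one substitution,
    whose k=2 graph walks form a single chain of four bubbles.
    ``three_way``: the same pair plus a third string, the smallest input
    where a carrying path is needed because the bubbles tangle.
    ``hanging_ends``: a walk of four edges chaining with the middle of a
    six-vertex carrying path, leaving one hanging edge on each side — the
    canonical score-zero configuration.
    """
    sub_pair = [
        SequenceRecord("s1", "c1", "GCACGTCC"),
        SequenceRecord("s2", "c1", "GCACTTCC"),
    ]
    return {
        "substitution_pair": {"records": sub_pair, "k": 2, "b": 4, "m": 1},
        "three_way": {
            "records": sub_pair + [SequenceRecord("s3", "c1", "CACGTTCC")],
            "k": 2,
            "b": 4,
            "m": 1,
        },
        "hanging_ends": {
            "records": [
                SequenceRecord("sa", "c1", "GACGTAT"),
                SequenceRecord("sp", "c1", "CACGTA"),
            ],
            "k": 2,
            "b": 4,
            "m": 4,
        },
    }
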