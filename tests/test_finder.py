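"""Seed-and-extend block reconstruction: worked examples and invariants."""

import numpy as np
import pytest

from lcbkit.core import score_split, decompose_chain, vwalk_from_compacted
from lcbkit.finder import (
    blocks_to_records,
    find_block_from_seed,
    find_collinear_blocks,
    init_block,
    seed_iterator,
)
from lcbkit.graph import (
    build_compacted,
    build_graph,
    compact,
    find_junctions,
    sentinel_junctions,
)
from lcbkit.io import SequenceRecord, write_blocks_gff
from lcbkit.sim import EvolutionParams, simulate


def recs(*named):
    return [SequenceRecord(g, "c1", s) for g, s in named]


def rand_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def block_signature(graph, blocks):
    out = []
    for blk in blocks_to_records(graph, blocks):
        out.append(
            (blk.block_id,
             tuple(sorted((o.genome_id, o.seq_id, o.start, o.end, o.strand)
                          for o in blk.occurrences)))
        )
    return out


class TestSeedIterator:
    def test_lexicographic_classes(self):
        g = build_graph(recs(("g1", "GCACGTCC")), 2)
        cg = compact(g, g.vertices | sentinel_junctions(g))
        assert list(seed_iterator(cg)) == ["ACG", "CAC", "CGT", "GCA", "GTC", "TCC"]

    def test_all_used_yields_nothing(self):
        g = build_graph(recs(("g1", "GCACGTCC")), 2)
        cg = compact(g, g.vertices | sentinel_junctions(g))
        for i in range(cg.n_edges(0, "+")):
            cg.mark_used(0, "+", i)
        assert list(seed_iterator(cg)) == []

    def test_consumed_classes_skipped_after_block(self, examples):
        fx = examples["three_way"]
        graph = build_compacted(fx["records"], k=2, a=100, double_stranded=False)
        find_collinear_blocks(graph, b=4, m=1)
        for key in seed_iterator(graph):
            assert any(not graph.is_used(*occ) for occ in graph.classes[key])


class TestInitBlock:
    def test_one_walk_per_parallel_occurrence(self, examples):
        fx = examples["substitution_pair"]
        graph = build_compacted(fx["records"], k=2, a=100)
        # the seed edge out of "GC" compacts to the shared run GC..AC
        key = graph.edge_key(0, "+", 0)
        assert key == "GCAC"
        build = init_block(key, graph, b=4, m=1)
        assert len(build.walks) == 2

    def test_single_occurrence_seed(self):
        graph = build_compacted(recs(("g1", "GCACGTCC")), k=2, a=100,
                                double_stranded=False)
        # compact to unit edges to make the class explicit
        build = init_block(list(graph.classes)[0], graph, b=4, m=1)
        assert len(build.walks) == 1

    def test_used_occurrence_excluded(self, examples):
        fx = examples["substitution_pair"]
        graph = build_compacted(fx["records"], k=2, a=100)
        key = graph.edge_key(0, "+", 0)
        fi, strand, i = graph.classes[key][0]
        graph.mark_used(fi, strand, i)
        build = init_block(key, graph, b=4, m=1)
        assert len(build.walks) == 1


class TestFindBlockFromSeed:
    def test_three_way_block_one_walk_per_sequence(self, examples):
        fx = examples["three_way"]
        graph = build_compacted(fx["records"], k=2, a=100, double_stranded=False)
        blk = find_block_from_seed("GCA", graph, b=4, m=1)
        assert blk is not None and len(blk.walks) == 3
        genomes = {graph.fragments[w.fi].genome_id for w in blk.walks}
        assert genomes == {"s1", "s2", "s3"}
        assert blk.score == 17.0  # 6 + 6 + 5 against the shared carrying path

    def test_lone_seed_yields_none(self):
        rng = np.random.default_rng(0)
        graph = build_compacted(
            recs(("g1", rand_seq(rng, 300))), k=15, a=150
        )
        key = next(iter(seed_iterator(graph)))
        assert find_block_from_seed(key, graph, b=200, m=50) is None

    def test_planted_repeat_scores_twice_its_edges(self):
        rng = np.random.default_rng(5)
        L, k = 200, 15
        repeat = rand_seq(rng, L)
        g1 = rand_seq(rng, 300) + repeat + rand_seq(rng, 300)
        g2 = rand_seq(rng, 300) + repeat + rand_seq(rng, 300)
        graph = build_compacted(recs(("g1", g1), ("g2", g2)), k=k, a=150)
        multi = [key for key, occs in graph.classes.items() if len(occs) == 2]
        assert multi
        blk = find_block_from_seed(multi[0], graph, b=200, m=50)
        assert blk is not None and len(blk.walks) == 2
        # the walks span the *maximal* shared string: the planted repeat
        # plus however far the random flanks happen to agree
        ext_left = 0
        while g1[300 - 1 - ext_left] == g2[300 - 1 - ext_left]:
            ext_left += 1
        ext_right = 0
        while g1[300 + L + ext_right] == g2[300 + L + ext_right]:
            ext_right += 1
        shared_edges = L + ext_left + ext_right - k
        assert blk.score == 2 * shared_edges  # no hanging ends on either walk

    def test_leftward_extension_recovers_full_region(self):
        rng = np.random.default_rng(9)
        shared = rand_seq(rng, 300)
        g1 = rand_seq(rng, 250) + shared + rand_seq(rng, 250)
        g2 = rand_seq(rng, 250) + shared + rand_seq(rng, 250)
        graph = build_compacted(recs(("g1", g1), ("g2", g2)), k=15, a=150)
        # seed at the rightmost shared class: only leftward extension can
        # recover the rest of the shared region
        def occ_pos(key):
            fi, s, i = graph.classes[key][0]
            return graph.jpos[fi, s][i]
        multi = [key for key, occs in graph.classes.items() if len(occs) == 2]
        key = max(multi, key=occ_pos)
        blk = find_block_from_seed(key, graph, b=200, m=50)
        assert blk is not None
        assert blk.score >= 2 * (300 - 15) - 60  # nearly the whole region


class TestTandemDuplication:
    def test_nearest_walk_extended_both_copies_recovered(self):
        rng = np.random.default_rng(13)
        L = 150
        repeat = rand_seq(rng, L)
        g1 = rand_seq(rng, 200) + repeat + repeat + rand_seq(rng, 200)
        g2 = rand_seq(rng, 200) + repeat + rand_seq(rng, 200)
        records = recs(("g1", g1), ("g2", g2))
        graph = build_compacted(records, k=15, a=150)
        blocks = find_collinear_blocks(graph, b=200, m=50)
        recs_out = blocks_to_records(graph, blocks)
        copy1 = (200, 200 + L)
        copy2 = (200 + L, 200 + 2 * L)
        def covered(interval):
            s, e = interval
            return sum(
                max(0, min(o.end, e) - max(o.start, s))
                for b in recs_out for o in b.occurrences if o.genome_id == "g1"
            )
        assert covered(copy1) >= L - 40
        assert covered(copy2) >= L - 40


class TestFindCollinearBlocks:
    def test_unrelated_genomes_give_no_blocks(self):
        rng = np.random.default_rng(17)
        graph = build_compacted(
            recs(("g1", rand_seq(rng, 400)), ("g2", rand_seq(rng, 400))),
            k=15, a=150,
        )
        assert find_collinear_blocks(graph, b=200, m=50) == []

    def test_identical_genomes_single_cover(self, tmp_path):
        rng = np.random.default_rng(21)
        s = rand_seq(rng, 1200)
        records = recs(("g1", s), ("g2", s))
        graph = build_compacted(records, k=15, a=150)
        blocks = find_collinear_blocks(graph, b=200, m=50)
        out = blocks_to_records(graph, blocks)
        # the GFF writer enforces the pairwise non-overlap invariant
        write_blocks_gff(out, tmp_path / "b.gff")
        for gid in ("g1", "g2"):
            covered = sum(o.length for b in out for o in b.occurrences
                          if o.genome_id == gid)
            assert covered >= 1200 - 50

    def test_deterministic_rerun(self, small_sim):
        records, _ = small_sim
        sigs = []
        for _ in range(2):
            graph = build_compacted(records, k=15, a=150)
            sigs.append(block_signature(graph, find_collinear_blocks(graph, b=200, m=50)))
        assert sigs[0] == sigs[1]

    def test_batch_modes_identical(self, small_sim):
        records, _ = small_sim
        sigs = []
        for batch in (None, 7):
            graph = build_compacted(records, k=15, a=150)
            sigs.append(
                block_signature(
                    graph, find_collinear_blocks(graph, b=200, m=50, batch_size=batch)
                )
            )
        assert sigs[0] == sigs[1]


class TestBlockInvariants:
    def test_global_edge_disjointness(self, small_sim_blocks):
        graph, blocks = small_sim_blocks
        seen = set()
        for blk in blocks:
            for w in blk.walks:
                for e in range(w.lo, w.hi):
                    key = (w.fi, graph._plus_index(w.fi, w.strand, e))
                    assert key not in seen
                    seen.add(key)

    def test_walks_are_genomic(self, small_sim_blocks):
        graph, blocks = small_sim_blocks
        for blk in blocks:
            for w in blk.walks:
                frag = graph.fragments[w.fi]
                seq = frag.strand_seq(w.strand)
                pos = graph.jpos[w.fi, w.strand]
                spelled = graph.spelled(w.fi, w.strand, w.lo)
                for e in range(w.lo + 1, w.hi):
                    spelled += graph.spelled(w.fi, w.strand, e)[graph.k:]
                assert spelled == seq[pos[w.lo] : pos[w.hi] + graph.k]

    def test_scores_recompute_and_are_positive(self, small_sim_blocks):
        graph, blocks = small_sim_blocks
        for blk in blocks:
            total = 0.0
            for w, stored in zip(blk.walks, blk.walk_scores):
                vw = vwalk_from_compacted(graph, w)
                split = decompose_chain(blk.carrying, vw, b=200)
                s = score_split(vw.length, split, m=50, b=200)
                assert s == stored > 0
                total += s
            assert total == blk.score > 0

    def test_every_block_has_two_walks_of_min_length(self, small_sim_blocks):
        graph, blocks = small_sim_blocks
        for blk in blocks:
            assert len(blk.walks) >= 2
            for w in blk.walks:
                pos = graph.jpos[w.fi, w.strand]
                assert pos[w.hi] - pos[w.lo] >= 50
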