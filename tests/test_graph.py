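"""De Bruijn graph construction, junctions, pruning and compaction."""

import re

import hypothesis as hyp
import hypothesis.strategies as st
import numpy as np
import pytest

from lcbkit.graph import (
    ParameterError,
    build_compacted,
    build_graph,
    compact,
    comprehensive,
    find_junctions,
    prune_abundance,
    sentinel_junctions,
)
from lcbkit.io import SequenceRecord, revcomp


def recs(*seqs, genome="g1"):
    return [SequenceRecord(genome, f"c{i+1}", s) for i, s in enumerate(seqs)]


def brute_census(seqs, k):
    """Independent oracle: substring enumeration."""
    vertices = set()
    edges = 0
    for s in seqs:
        for frag in re.findall("[ACGT]+", s):
            vertices |= {frag[i : i + k] for i in range(len(frag) - k + 1)}
            edges += max(0, len(frag) - k)
    return vertices, edges


class TestBuildGraph:
    def test_worked_example_census(self):
        g = build_graph(recs("GCACGTCC"), 2)
        assert g.vertices == {"GC", "CA", "AC", "CG", "GT", "TC", "CC"}
        assert g.n_edge_occurrences() == 6

    def test_parallel_edge_class(self):
        g = build_graph(recs("GCACGTCC", "GCACTTCC"), 2)
        assert len(g.parallel_edges("GCA")) == 2

    def test_n_breaks_fragments(self):
        g = build_graph(recs("ACGNACG"), 2)
        assert g.vertices == {"AC", "CG"}
        assert len(g.parallel_edges("ACG")) == 2
        assert g.n_edge_occurrences() == 2  # nothing spans the N

    def test_k_too_small_rejected(self):
        with pytest.raises(ParameterError):
            build_graph(recs("ACGT"), 1)

    def test_no_long_fragment_warns(self):
        with pytest.warns(UserWarning, match="no fragment longer"):
            build_graph(recs("ACG"), 3)

    @pytest.mark.parametrize("seed", range(5))
    def test_census_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        seqs = [
            "".join(rng.choice(list("ACGTN"), p=[0.24] * 4 + [0.04], size=rng.integers(10, 200)))
            for _ in range(3)
        ]
        g = build_graph(recs(*seqs), 3)
        vertices, edges = brute_census(seqs, 3)
        assert g.vertices == vertices
        assert g.n_edge_occurrences() == edges


class TestNextEdge:
    def test_successor(self):
        g = build_graph(recs("GCACGTCC"), 2)
        e = g.parallel_edges("GCA")[0]
        nxt = g.next_edge(e)
        assert (nxt.kp1mer, nxt.offset) == ("CAC", 1)

    def test_last_edge_has_no_successor(self):
        g = build_graph(recs("GCACGTCC"), 2)
        e = g.parallel_edges("TCC")[0]
        assert g.next_edge(e) is None

    def test_no_successor_across_n(self):
        g = build_graph(recs("ACGNACG"), 2)
        for e in g.parallel_edges("ACG"):
            assert g.next_edge(e) is None

    def test_chains_enumerate_each_fragment_once(self):
        g = build_graph(recs("GCACGTCC", "ACGTACGT"), 3)
        seen = set()
        starts = [
            e
            for cls in g.edge_classes.values()
            for e in cls
            if e.offset == 0
        ]
        for e in starts:
            cur = e
            while cur is not None:
                key = (cur.frag_idx, cur.strand, cur.offset)
                assert key not in seen
                seen.add(key)
                cur = g.next_edge(cur)
        assert len(seen) == g.n_edge_occurrences()


class TestComprehensive:
    def test_double_counts(self):
        g = comprehensive(recs("GCACGTCC"), 2)
        assert g.n_edge_occurrences() == 12

    def test_palindromic_input_symmetric(self):
        g = comprehensive(recs("ACGT"), 2)
        fwd = sorted(e.kp1mer for e in sum((g.parallel_edges(c) for c in g.edge_classes), [])
                     if e.strand == "+")
        rev = sorted(e.kp1mer for e in sum((g.parallel_edges(c) for c in g.edge_classes), [])
                     if e.strand == "-")
        assert fwd == rev

    def test_twin_is_involution(self):
        g = comprehensive(recs("GCACGTCC", "ACGTTACG"), 3)
        for cls in g.edge_classes.values():
            for e in cls:
                t = g.twin(e)
                assert t.kp1mer == revcomp(e.kp1mer)
                assert g.twin(t) == e


class TestJunctions:
    def test_branch_points_of_worked_example(self):
        g = build_graph(recs("GCACGTCC", "GCACTTCC"), 2)
        j = find_junctions(g)
        assert "AC" in j  # out-neighbours CG and CT
        assert "TC" in j  # in-neighbours GT and TT

    def test_unique_kmers_only_sentinels(self):
        g = build_graph(recs("GATTCA"), 2)
        assert find_junctions(g) == sentinel_junctions(g) == {"GA", "CA"}

    def test_self_loop_counts_once(self):
        g = build_graph(recs("AAAA"), 2)
        # AA's only neighbour is itself: not a branching junction
        assert find_junctions(g) == {"AA"}  # sentinel only
        g2 = build_graph(recs("AAAC"), 2)
        assert "AA" in find_junctions(g2)  # now out-neighbours {AA, AC}


class TestPruning:
    def test_infinite_threshold_is_identity(self):
        g = comprehensive(recs("GCACGTCC", "GCACTTCC"), 2)
        j = find_junctions(g)
        assert prune_abundance(j, g, 10**9) == j

    def test_threshold_semantics(self):
        # "AC" occurs 3 times on the forward strands alone
        g = build_graph(recs("ACAACA"), 2)
        j = find_junctions(g)
        assert "AC" in j
        pruned = prune_abundance(j, g, 2)
        assert "AC" not in pruned or "AC" in sentinel_junctions(g)

    def test_bad_threshold(self):
        g = build_graph(recs("ACGT"), 2)
        with pytest.raises(ParameterError):
            prune_abundance(set(), g, 0)

    def test_high_copy_repeat_pruned_flanks_still_found(self):
        from lcbkit.finder import blocks_to_records, find_collinear_blocks

        rng = np.random.default_rng(0)
        flank_a = "".join(rng.choice(list("ACGT"), size=400))
        flank_b = "".join(rng.choice(list("ACGT"), size=400))
        repeat = "ACGTTGCAGT" * 200
        g1 = flank_a + repeat + flank_b
        g2 = flank_a + flank_b
        records = [SequenceRecord("g1", "c1", g1), SequenceRecord("g2", "c1", g2)]
        graph = build_compacted(records, k=9, a=150)
        # repeat-internal junction k-mers occur ~200 times > a: gone
        assert not any(km in graph.junctions for km in
                       {repeat[i:i+9] for i in range(15, 25)})
        blocks = blocks_to_records(graph, find_collinear_blocks(graph, b=100, m=50))
        covered_g2 = sum(o.length for b in blocks for o in b.occurrences
                         if o.genome_id == "g2")
        assert covered_g2 >= 600  # both flanks recovered


class TestCompaction:
    @hyp.given(
        seqs=st.lists(st.text(alphabet="ACGT", min_size=4, max_size=50),
                      min_size=1, max_size=3),
        k=st.integers(min_value=2, max_value=4),
    )
    @hyp.settings(max_examples=200, derandomize=True, deadline=None)
    def test_lossless_reconstruction_property(self, seqs, k):
        if not any(len(s) > k for s in seqs):
            return
        g = comprehensive(recs(*seqs), k)
        cg = compact(g, find_junctions(g))
        assert cg.decompress() == [f.seq for f in cg.fragments]

    def test_lossless_reconstruction_fuzz(self):
        rng = np.random.default_rng(42)
        for trial in range(1000):
            k = int(rng.integers(2, 5))
            seqs = [
                "".join(rng.choice(list("ACGT"), size=int(rng.integers(k + 1, 60))))
                for _ in range(int(rng.integers(1, 3)))
            ]
            g = comprehensive(recs(*seqs), k)
            cg = compact(g, find_junctions(g))
            assert cg.decompress() == [f.seq for f in cg.fragments]

    def test_all_vertices_reproduces_ordinary_graph(self):
        g = build_graph(recs("GCACGTCC"), 2)
        cg = compact(g, g.vertices | sentinel_junctions(g))
        assert cg.n_edges(0, "+") == 6
        assert all(cg.step(0, "+", i) == 1 for i in range(6))
        spelled = [cg.spelled(0, "+", i) for i in range(6)]
        assert spelled == ["GCA", "CAC", "ACG", "CGT", "GTC", "TCC"]

    def test_same_endpoints_different_spelling_distinct_classes(self):
        # two junction-to-junction runs with equal endpoints must not merge
        # unless they spell the same sequence
        g = build_graph(recs("ACGGTA", "ACGTA", "ACTTA", "ACA"), 2)
        j = find_junctions(g)
        cg = compact(g, j)
        by_ends = {}
        for key, occs in cg.classes.items():
            fi, s, i = occs[0]
            by_ends.setdefault(
                (cg.tail_vertex(fi, s, i), cg.head_vertex(fi, s, i)), set()
            ).add(key)
        assert any(len(keys) > 1 for keys in by_ends.values())

    def test_strand_symmetric_compacted_graph(self):
        g = comprehensive(recs("GCACGTCCA", "TTGCACTTC"), 3)
        cg = compact(g, find_junctions(g))
        for frag in cg.fragments:
            n_p = cg.n_edges(frag.frag_idx, "+")
            for i in range(n_p):
                fi, s, j = cg.twin(frag.frag_idx, "+", i)
                assert cg.spelled(fi, s, j) == revcomp(cg.spelled(frag.frag_idx, "+", i))
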