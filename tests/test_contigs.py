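import numpy as np
import pytest

from seedsgraph import SimSpec, assemble, simulate_genome, simulate_reads
from seedsgraph.clustering import Seed, SeedMember
from seedsgraph.contigs import (
    Scaffold,
    consensus_column,
    extract_contigs,
    resolve_repeats,
    scaffold,
    scaffold_sequences,
    thread_reads,
)
from seedsgraph.io import Read, ReadSet, reverse_complement
from seedsgraph.pipeline import RunConfig
from seedsgraph.seeds_graph import SeedsGraph

from conftest import random_seq


def linear_graph(pats, members=None):
    """SeedsGraph that is one chain-edge path over the given patterns."""
    g = SeedsGraph()
    for i, p in enumerate(pats):
        mem = members[i] if members else [SeedMember(i, 0, 1, p)]
        g.seeds[i] = Seed(i, p, mem)
        g.g.add_node(i)
    for i in range(len(pats) - 1):
        g.g.add_edge(i, i + 1, kind="chain", weight=0, flip=False)
    return g


class TestConsensusColumn:
    @pytest.mark.parametrize(
        "bases,expected",
        [(["A", "A", "A", "G"], "A"), (["A", "G"], "N"), ([], "N")],
    )
    def test_cases(self, bases, expected):
        assert consensus_column(bases) == expected


class TestThreadReads:
    def test_center_read_threads_full_chain(self, rng):
        pats = [random_seq(rng, 20) for _ in range(5)]
        members = [[SeedMember(0, 20 * i, 1, p)] for i, p in enumerate(pats)]
        g = linear_graph(pats, members)
        reads = ReadSet(reads=[Read(0, "c", "".join(pats))])
        paths = thread_reads(g, reads)
        assert paths[0] == [0, 1, 2, 3, 4]

    def test_unthreaded_read_has_empty_path(self, rng):
        g = linear_graph([random_seq(rng, 20)])
        reads = ReadSet(reads=[Read(0, "x", "ACGT" * 10), Read(1, "y", "ACGT" * 10)])
        paths = thread_reads(g, reads)
        assert paths[1] == []


class TestExtractContigs:
    def test_linear_graph_splices_exactly(self, rng):
        pats = [random_seq(rng, 20) for _ in range(4)]
        ctgs = extract_contigs(linear_graph(pats), min_length=0)
        assert len(ctgs) == 1
        seq = ctgs[0].seq
        expected = "".join(pats)
        assert seq in (expected, reverse_complement(expected))

    def test_branch_breaks_contigs(self, rng):
        # 0 -> 1 -> {2, 3}: no contig may span node 1's branch
        g = SeedsGraph()
        pats = [random_seq(rng, 20) for _ in range(4)]
        for i, p in enumerate(pats):
            g.seeds[i] = Seed(i, p, [SeedMember(i, 0, 1, p)])
            g.g.add_node(i)
        for u, v in ((0, 1), (1, 2), (1, 3)):
            g.g.add_edge(u, v, kind="chain", weight=0, flip=False)
        ctgs = extract_contigs(g, min_length=0)
        joined = pats[0] + pats[1]
        assert any(
            c.seq in (joined, reverse_complement(joined)) for c in ctgs
        )
        for c in ctgs:
            for bad in (pats[1] + pats[2], pats[1] + pats[3]):
                assert bad not in c.seq
                assert reverse_complement(bad) not in c.seq

    def test_empty_graph(self):
        assert extract_contigs(SeedsGraph()) == []

    def test_min_length_filter(self, rng):
        pats = [random_seq(rng, 20) for _ in range(2)]
        assert extract_contigs(linear_graph(pats), min_length=100) == []


def x_fixture(rng):
    """Fig. 4a topology: a->r->c and b->r->d with mates a<->c, b<->d."""
    pats = {n: random_seq(rng, 20) for n in "abrcd"}
    sids = {n: i for i, n in enumerate("abrcd")}
    mates = {0: 1, 1: 0, 2: 3, 3: 2}
    anchor = {0: "a", 1: "c", 2: "b", 3: "d"}
    reads = [
        Read(rid, f"r{rid}", pats[anchor[rid]], mate_id=mates[rid])
        for rid in range(4)
    ]
    rs = ReadSet(reads=reads, paired=True, insert_size=60)
    graph = SeedsGraph()
    for n, sid in sids.items():
        members = [
            SeedMember(rid, 0, 1, pats[n]) for rid, a in anchor.items() if a == n
        ]
        graph.seeds[sid] = Seed(sid, pats[n], members)
        graph.g.add_node(sid)
    for u, v in (("a", "r"), ("b", "r"), ("r", "c"), ("r", "d")):
        graph.g.add_edge(sids[u], sids[v], kind="chain", weight=0, flip=False)
    read_paths = {rid: [sids[anchor[rid]]] for rid in range(4)}
    return graph, read_paths, rs, pats, sids


class TestResolveRepeats:
    def test_x_topology_duplicates_shared_node(self, rng):
        graph, read_paths, rs, pats, sids = x_fixture(rng)
        graph = resolve_repeats(graph, read_paths, rs, insert_size=60)
        assert sids["r"] not in graph.seeds  # original replaced by copies
        assert len(graph.seeds) == 6
        ctgs = extract_contigs(graph, min_length=0)
        seqs = {c.seq for c in ctgs} | {reverse_complement(c.seq) for c in ctgs}
        assert pats["a"] + pats["r"] + pats["c"] in seqs
        assert pats["b"] + pats["r"] + pats["d"] in seqs

    def test_unsupported_repeat_left_intact(self, rng):
        graph, read_paths, rs, pats, sids = x_fixture(rng)
        # break the mate evidence: all reads unpaired
        for r in rs.reads:
            r.mate_id = None
        rs.paired = False
        graph = resolve_repeats(graph, read_paths, rs, insert_size=60)
        assert sids["r"] in graph.seeds

    def test_parallel_path_insert_selection(self, rng):
        # s -> x -> t (150 bp) and s -> y1 -> y2 -> t (600 bp), insert 180:
        # only the short path satisfies the constraint for the spanning pair
        g = SeedsGraph()
        pats = [random_seq(rng, 20) for _ in range(5)]  # s, x, t, y1, y2
        for i, p in enumerate(pats):
            g.seeds[i] = Seed(i, p, [SeedMember(i % 3, 0, 1, p)])
            g.g.add_node(i)
        s, x, t, y1, y2 = range(5)
        g.seeds[s].members = [SeedMember(0, 0, 1, pats[s])]
        g.seeds[t].members = [SeedMember(1, 0, 1, pats[t])]
        fill = lambda n: "N" * n  # noqa: E731
        def chain_edge(u, v, gap):
            g.g.add_edge(
                u, v, kind="chain", weight=gap, flip=False,
                seg_fwd=fill(gap) + pats[v], seg_rev=fill(gap) + reverse_complement(pats[u]),
            )
        # short: 3*20 + 45 + 45 = 150
        chain_edge(s, x, 45)
        chain_edge(x, t, 45)
        # long: 4*20 + 260 + 260 = 600
        chain_edge(s, y1, 260)
        chain_edge(y1, y2, 0)
        chain_edge(y2, t, 260)
        reads = [
            Read(0, "a", pats[s], mate_id=1),
            Read(1, "b", pats[t], mate_id=0),
            Read(2, "c", pats[x], mate_id=None),
        ]
        reads[2].mate_id = None
        rs = ReadSet(reads=reads[:2], paired=True, insert_size=180)
        read_paths = {0: [s], 1: [t]}
        g = resolve_repeats(g, read_paths, rs, insert_size=180, insert_tol=0.2)
        assert y1 not in g.seeds and y2 not in g.seeds
        assert x in g.seeds

    def test_repeat_without_spanning_pairs_untouched(self, rng):
        g = SeedsGraph()
        pats = [random_seq(rng, 20) for _ in range(5)]
        for i, p in enumerate(pats):
            g.seeds[i] = Seed(i, p, [SeedMember(i, 0, 1, p)])
            g.g.add_node(i)
        for u, v in ((0, 2), (1, 2), (2, 3), (2, 4)):
            g.g.add_edge(u, v, kind="chain", weight=0, flip=False)
        reads = [Read(i, f"r{i}", pats[i], mate_id=i + 1 if i % 2 == 0 else i - 1) for i in range(4)]
        rs = ReadSet(reads=reads, paired=True, insert_size=60)
        read_paths = {i: [] for i in range(4)}  # no threading evidence at all
        g2 = resolve_repeats(g, read_paths, rs, insert_size=60)
        assert set(g2.seeds) == {0, 1, 2, 3, 4}


class TestScaffold:
    def test_no_mate_pairs_gives_singletons(self, rng):
        ctgs = extract_contigs(linear_graph([random_seq(rng, 20)] ), min_length=0)
        rs = ReadSet(reads=[Read(0, "r", "ACGT" * 10)], paired=False)
        scaffolds = scaffold(ctgs, rs, insert_size=180, seeds={})
        assert len(scaffolds) == len(ctgs)
        assert all(len(s.parts) == 1 for s in scaffolds)

    def test_scaffolds_are_collinear_with_genome(self):
        spec = SimSpec(genome_length=6000, coverage=30, error_rate=0.0, rng_seed=2)
        genome, _ = simulate_genome(spec)
        reads = simulate_reads(genome, spec)
        res = assemble(reads, RunConfig())
        rc = reverse_complement(genome)
        G = len(genome)
        placements = {}
        for c in res.contigs:
            p = genome.find(c.seq)
            if p >= 0:
                placements[c.contig_id] = (p, p + len(c.seq), 1)
                continue
            p = rc.find(c.seq)
            if p >= 0:
                placements[c.contig_id] = (G - p - len(c.seq), G - p, -1)
        multi = [s for s in res.scaffolds if len(s.parts) >= 2]
        assert multi, "expected at least one multi-contig scaffold at 30x"
        for sc in multi:
            placed = [
                (placements[cid][0], placements[cid][2] * orient)
                for cid, orient, _ in sc.parts
                if cid in placements
            ]
            if len(placed) < 2:
                continue
            starts = [p for p, _ in placed]
            genome_orient = {o for _, o in placed}
            assert len(genome_orient) == 1, "scaffold mixes genome orientations"
            if genome_orient == {1}:
                assert starts == sorted(starts)
            else:
                assert starts == sorted(starts, reverse=True)

    def test_two_replicons_never_coscaffolded(self):
        spec_a = SimSpec(genome_length=3000, coverage=30, error_rate=0.0, rng_seed=3)
        spec_b = SimSpec(genome_length=3000, coverage=30, error_rate=0.0, rng_seed=4)
        genome_a, _ = simulate_genome(spec_a)
        genome_b, _ = simulate_genome(spec_b)
        reads_a = simulate_reads(genome_a, spec_a)
        reads_b = simulate_reads(genome_b, spec_b)
        merged = []
        offset = len(reads_a)
        for r in reads_a:
            merged.append(r)
        for r in reads_b.reads:
            merged.append(
                Read(
                    r.read_id + offset,
                    r.name + "_b",
                    r.seq,
                    mate_id=r.mate_id + offset,
                    source_offset=r.source_offset,
                    source_strand=r.source_strand,
                )
            )
        rs = ReadSet(reads=merged, paired=True, insert_size=180)
        res = assemble(rs, RunConfig())
        rc_a = reverse_complement(genome_a)
        rc_b = reverse_complement(genome_b)

        def replicon(seq):
            if genome_a.find(seq) >= 0 or rc_a.find(seq) >= 0:
                return "a"
            if genome_b.find(seq) >= 0 or rc_b.find(seq) >= 0:
                return "b"
            return None

        origin = {c.contig_id: replicon(c.seq) for c in res.contigs}
        for sc in res.scaffolds:
            reps = {origin[cid] for cid, _, _ in sc.parts if origin[cid]}
            assert len(reps) <= 1

    def test_scaffold_sequences_gap_rendering(self, rng):
        seq1, seq2 = random_seq(rng, 120), random_seq(rng, 120)
        from seedsgraph.contigs import Contig

        contigs = [
            Contig(0, [], seq1), Contig(1, [], seq2),
        ]
        sc = Scaffold(0, [(0, 1, 30), (1, -1, 0)])
        (name, rendered), = scaffold_sequences([sc], contigs)
        assert rendered == seq1 + "N" * 30 + reverse_complement(seq2)
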