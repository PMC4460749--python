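"""Shared fixtures and check helpers for the assembler test suite."""

from __future__ import annotations

import numpy as np
import pytest

from seedsgraph import SimSpec, simulate_genome, simulate_reads
from seedsgraph.io import Read, ReadSet


def make_reads(seqs, paired=False, insert_size=None) -> ReadSet:
    """Wrap raw sequences into a ReadSet; interleaved mates when paired."""
    reads = [Read(i, f"r{i}", s.upper()) for i, s in enumerate(seqs)]
    if paired:
        for i in range(0, len(reads) - 1, 2):
            reads[i].mate_id = i + 1
            reads[i + 1].mate_id = i
    return ReadSet(reads=reads, paired=paired, insert_size=insert_size)


def random_seq(rng, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), n))


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_sim():
    """3 kb error-free simulated dataset shared by integration tests."""
    spec = SimSpec(genome_length=3000, coverage=30, error_rate=0.0, rng_seed=1)
    genome, _ = simulate_genome(spec)
    reads = simulate_reads(genome, spec)
    return genome, reads, spec


def check_chain_invariants(chains, reads, params):
    """Partition, seed soundness, non-overlap, coverage — raised on breach."""
    from seedsgraph.io import reverse_complement

    seen: set[int] = set()
    for chain in chains:
        assert not (chain.member_ids & seen), "chains must not share reads"
        seen |= chain.member_ids
        l = params.l
        center = reads[chain.center_id]
        for i in range(len(chain.starts) - 1):
            assert chain.starts[i] + l <= chain.starts[i + 1], (
                "fresh chain windows must be disjoint and ascending"
            )
        cover = {rid: 0 for rid in chain.member_ids}
        for seed, ws in zip(chain.seeds, chain.starts):
            for mem in seed.members:
                read = reads[mem.seq_id]
                oriented = read.seq if mem.strand == 1 else reverse_complement(read.seq)
                window = oriented[mem.offset : mem.offset + l]
                assert window == mem.window
                # pattern match with n wildcard
                for a, b in zip(window, seed.pattern):
                    assert b == "n" or a == b, "member conflicts with pattern"
                cover[mem.seq_id] = cover.get(mem.seq_id, 0) + l
            # members stay within e mismatches of the center window
            if chain.starts and 0 <= ws and ws + l <= len(center.seq):
                cwin = center.seq[ws : ws + l]
                for mem in seed.members:
                    mm = sum(1 for a, b in zip(mem.window, cwin) if a != b)
                    assert mm < params.e
        for rid in chain.member_ids:
            if rid == chain.center_id:
                continue
            assert cover.get(rid, 0) / len(reads[rid].seq) >= params.h
    assert seen == {r.read_id for r in reads}, "chains must partition the read set"
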