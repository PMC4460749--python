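"""Read clustering into seed chains.

A cluster grows around a randomly selected center read ``r_c``: every read
sharing a retained k-mer with the center is aligned to it by the shared k-mer
offsets, validated window-by-window against the center with fewer than ``e``
mismatches per l-mer window, and condensed into an ordered chain of
non-overlapping l-mer seeds.  Columns where accepted members disagree become
the wildcard ``n`` in the seed pattern — this is where sequencing errors are
absorbed.  Beyond both ends of the center, seeds are built from member-vs-
member column consensus.  Finally members whose fraction of bases covered by
the chain's seed windows falls below ``h`` are evicted, and the chain's
members are removed from the read pool, so chains partition the read set.

Coordinates: a chain lives on the center's coordinate line (center base 0 at
coordinate 0); a member with ``shift`` s occupies ``[s, s + len)`` there, in
its aligned orientation (the read itself for forward members, its reverse
complement for reverse members).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .io import Read, ReadSet, reverse_complement
from .kmer_index import KmerGroupSet, decode_offset

__all__ = [
    "AlignedMember",
    "SeedMember",
    "Seed",
    "SeedsChain",
    "AssemblyParams",
    "select_center",
    "gather_candidates",
    "extend_to_lmer",
    "build_cluster",
    "cluster_all",
]


class AlignedMember(NamedTuple):
    seq_id: int
    shift: int
    strand: int  # +1 forward, -1 reverse


class SeedMember(NamedTuple):
    seq_id: int
    offset: int  # window start within the aligned (oriented) read
    strand: int
    window: str  # the member's l bases under the window, center orientation


@dataclass
class Seed:
    seed_id: int
    pattern: str
    members: list[SeedMember] = field(default_factory=list)
    next_id: int | None = None
    next_distance: int | None = None


@dataclass
class SeedsChain:
    chain_id: int
    center_id: int
    seeds: list[Seed] = field(default_factory=list)
    starts: list[int] = field(default_factory=list)  # window start per seed, chain coords
    member_ids: set[int] = field(default_factory=set)
    consensus: str = ""
    origin: int = 0  # chain coordinate of consensus[0]

    def span(self) -> tuple[int, int]:
        if not self.seeds:
            return (0, 0)
        l = len(self.seeds[0].pattern)
        return (self.starts[0], self.starts[-1] + l)

    def relink(self) -> None:
        """Recompute each seed's next link from the layout."""
        l = len(self.seeds[0].pattern) if self.seeds else 0
        for i, s in enumerate(self.seeds):
            if i + 1 < len(self.seeds):
                s.next_id = self.seeds[i + 1].seed_id
                s.next_distance = self.starts[i + 1] - (self.starts[i] + l)
            else:
                s.next_id = None
                s.next_distance = None


@dataclass
class AssemblyParams:
    """Tunable parameters of the assembler.

    k, l : k-mer / seed lengths (k < l).  t : max distinct reads sharing a
    retained k-mer.  e : per-window mismatch bound (strict).  h : minimum
    member coverage ratio by chain seeds.  q : minimum seed suffix-prefix
    overlap for a graph edge (strict).  branch_support : second-allele read
    count at which extension beyond the center stops.
    """

    k: int = 11
    l: int = 20
    t: int = 100
    e: int = 3
    h: float = 0.5
    q: int = 14
    rng_seed: int = 0
    insert_size: int = 180
    branch_support: int = 3

    def __post_init__(self):
        if not self.k < self.l:
            raise ValueError(f"k must be < l (got k={self.k}, l={self.l})")
        if not 0 < self.h <= 1:
            raise ValueError("h must be in (0, 1]")
        if self.e < 0:
            raise ValueError("e must be >= 0")
        if self.q < 1:
            raise ValueError("q must be >= 1")
        if self.t < 2:
            raise ValueError("t must be >= 2")


def select_center(remaining, rng: np.random.Generator) -> int:
    """Uniformly random element of ``remaining`` under the seeded generator."""
    ids = sorted(remaining)
    if not ids:
        raise ValueError("cannot select a center from an empty set")
    return ids[int(rng.integers(len(ids)))]


def gather_candidates(
    center: Read, groups: KmerGroupSet, allowed: set[int] | None = None
) -> list[AlignedMember]:
    """Collect and align every read sharing a retained k-mer with the center.

    Each shared k-mer votes for a (shift, strand); a read's votes are
    reconciled to the majority, ties broken by smaller \\|shift\\|, then
    forward strand.  The center itself appears first with shift 0, forward.
    """
    k = groups.k
    seq = center.seq
    votes: dict[int, Counter] = {}
    for oc in range(len(seq) - k + 1):
        kmer = seq[oc : oc + k]
        if "N" in kmer:
            continue
        grp = groups.get(kmer)
        if grp is None:
            continue
        for sid, coded in grp.members:
            if sid == center.read_id:
                continue
            if allowed is not None and sid not in allowed:
                continue
            off, strand = decode_offset(coded)
            votes.setdefault(sid, Counter())[(oc - off, strand)] += 1
    out = [AlignedMember(center.read_id, 0, 1)]
    for sid in sorted(votes):
        best = max(
            votes[sid].items(),
            key=lambda kv: (kv[1], -abs(kv[0][0]), kv[0][1], -kv[0][0]),
        )[0]
        out.append(AlignedMember(sid, best[0], best[1]))
    return out


def extend_to_lmer(center: Read, kmer_offset: int, l: int, k: int) -> tuple[int, str] | None:
    """Extend the k-mer window at ``kmer_offset`` symmetrically to length l.

    ceil((l-k)/2) bases to the left, the remainder to the right, clamped to
    the read bounds.  Returns (window_start, window) or None if the read is
    shorter than l.
    """
    m = len(center.seq)
    if m < l:
        return None
    left = math.ceil((l - k) / 2)
    start = kmer_offset - left
    start = max(0, min(start, m - l))
    return start, center.seq[start : start + l]


def _aligned_seq(read: Read, strand: int) -> str:
    return read.seq if strand == 1 else reverse_complement(read.seq)


def _mismatches(a: str, b: str, limit: int) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            n += 1
            if n >= limit:
                return n
    return n


class _Cand(NamedTuple):
    sid: int
    shift: int
    strand: int
    aligned: str  # oriented sequence


def _column_counts(cands: list[_Cand], ws: int, l: int) -> list[Counter]:
    """Base counts per window column over candidates fully covering it."""
    cols = [Counter() for _ in range(l)]
    for c in cands:
        if c.shift <= ws and ws + l <= c.shift + len(c.aligned):
            win = c.aligned[ws - c.shift : ws - c.shift + l]
            for i, b in enumerate(win):
                cols[i][b] += 1
    return cols


def _majority(counter: Counter) -> str:
    if not counter:
        return "N"
    ranked = sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))
    if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
        return "N"
    return ranked[0][0]


def build_cluster(
    center: Read,
    candidates: list[AlignedMember],
    reads: ReadSet,
    params: AssemblyParams,
    chain_id: int = 0,
    seed_id_start: int = 0,
) -> SeedsChain:
    """Condense one cluster into a chain of non-overlapping seeds.

    Sweeps the center's k-mer windows left to right, admits candidates with
    fewer than ``e`` mismatches in some window, emits non-overlapping seeds
    whose disputed columns are ``n``, then extends seed emission beyond both
    ends of the center from member consensus, and finally evicts members
    whose seed-window coverage is below ``h``.
    """
    k, l, e, h = params.k, params.l, params.e, params.h
    cands = [
        _Cand(a.seq_id, a.shift, a.strand, _aligned_seq(reads[a.seq_id], a.strand))
        for a in candidates
        if a.seq_id != center.read_id
    ]
    in_c: dict[int, _Cand] = {}
    seeds: list[Seed] = []
    starts: list[int] = []
    next_seed_id = seed_id_start
    m = len(center.seq)

    def emit(ws: int, pattern_ref: str, members: list[SeedMember]) -> None:
        nonlocal next_seed_id
        # wildcard columns where members disagree with the reference
        cols = list(pattern_ref)
        for mem in members:
            for i, b in enumerate(mem.window):
                if b != cols[i] and cols[i] != "n":
                    cols[i] = "n"
        seeds.append(Seed(next_seed_id, "".join(cols), members))
        starts.append(ws)
        next_seed_id += 1

    # --- sweep the center's k-mers ---
    last_end = None
    for oc in range(max(0, m - k + 1)):
        ext = extend_to_lmer(center, oc, l, k)
        if ext is None:
            break
        ws, window = ext
        if "N" in window:
            continue
        # admission: a candidate joins C when some window it fully covers
        # has < e mismatches against the center; partial-overlap comparisons
        # would let single-k-mer coincidences through on a handful of columns
        for c in cands:
            if c.sid in in_c:
                continue
            if not (c.shift <= ws and ws + l <= c.shift + len(c.aligned)):
                continue
            mm = _mismatches(
                c.aligned[ws - c.shift : ws - c.shift + l], window, e
            )
            if mm < e:
                in_c[c.sid] = c
        if last_end is not None and ws < last_end:
            continue
        members = [SeedMember(center.read_id, ws, 1, window)]
        for c in in_c.values():
            if c.shift <= ws and ws + l <= c.shift + len(c.aligned):
                win = c.aligned[ws - c.shift : ws - c.shift + l]
                if _mismatches(win, window, e) < e:
                    members.append(SeedMember(c.sid, ws - c.shift, c.strand, win))
        emit(ws, window, members)
        last_end = ws + l

    accepted = list(in_c.values())

    # --- seeds outside the center (member-vs-member consensus) ---
    def extend_outside(start_from: int, direction: int) -> None:
        ws = start_from if direction > 0 else start_from - l
        while True:
            cols = _column_counts(accepted, ws, l)
            covering = cols[0].total() if cols[0] else 0
            if not covering or any(not c for c in cols):
                return
            # branch stop: a second allele backed by several reads means two
            # genomic contexts merged here (repeat boundary); do not extend.
            for c in cols:
                ranked = c.most_common()
                if len(ranked) > 1 and ranked[1][1] >= params.branch_support:
                    return
            ref = "".join(_majority(c) for c in cols)
            if "N" in ref:
                return
            members = []
            for c in accepted:
                if c.shift <= ws and ws + l <= c.shift + len(c.aligned):
                    win = c.aligned[ws - c.shift : ws - c.shift + l]
                    if _mismatches(win, ref, e) < e:
                        members.append(SeedMember(c.sid, ws - c.shift, c.strand, win))
            if not members:
                return
            emit(ws, ref, members)
            ws += direction * l

    if seeds:
        right_from = starts[-1] + l
        left_from = starts[0]
        # order of emission does not matter; layout is sorted afterwards
        extend_outside(right_from, +1)
        extend_outside(left_from, -1)

    # sort seeds by window start and renumber ids in layout order
    order = sorted(range(len(seeds)), key=lambda i: starts[i])
    seeds = [seeds[i] for i in order]
    starts = sorted(starts)
    for i, s in enumerate(seeds):
        s.seed_id = seed_id_start + i

    # --- coverage-ratio eviction ---
    cover = Counter()
    for s in seeds:
        for mem in s.members:
            cover[mem.seq_id] += l
    surviving = {center.read_id}
    for c in accepted:
        if cover[c.sid] / len(c.aligned) >= h:
            surviving.add(c.sid)
    kept_seeds, kept_starts = [], []
    for s, ws in zip(seeds, starts):
        s.members = [mem for mem in s.members if mem.seq_id in surviving]
        if s.members:
            kept_seeds.append(s)
            kept_starts.append(ws)
    for i, s in enumerate(kept_seeds):
        s.seed_id = seed_id_start + i

    chain = SeedsChain(
        chain_id=chain_id,
        center_id=center.read_id,
        seeds=kept_seeds,
        starts=kept_starts,
        member_ids=surviving,
    )
    chain.relink()
    _build_consensus(chain, [c for c in accepted if c.sid in surviving], center)
    return chain


def _build_consensus(chain: SeedsChain, members: list[_Cand], center: Read) -> None:
    """Per-column consensus over the chain span, for gap fill and contigs.

    Columns under a seed window take the majority over that seed's member
    windows (wildcards resolved); other columns take the majority over all
    covering cluster reads, ``N`` when uncovered or tied.
    """
    if not chain.seeds:
        chain.consensus = ""
        chain.origin = 0
        return
    l = len(chain.seeds[0].pattern)
    lo, hi = chain.span()
    cols: list[Counter] = [Counter() for _ in range(hi - lo)]
    for s, ws in zip(chain.seeds, chain.starts):
        for mem in s.members:
            for i, b in enumerate(mem.window):
                cols[ws - lo + i][b] += 1
    all_reads = list(members)
    all_reads.append(_Cand(center.read_id, 0, 1, center.seq))
    for pos in range(hi - lo):
        if not cols[pos]:
            coord = lo + pos
            for c in all_reads:
                if c.shift <= coord < c.shift + len(c.aligned):
                    cols[pos][c.aligned[coord - c.shift]] += 1
    chain.consensus = "".join(_majority(c) for c in cols)
    chain.origin = lo


def cluster_all(
    reads: ReadSet, groups: KmerGroupSet, params: AssemblyParams
) -> list[SeedsChain]:
    """Partition all reads into seed chains (the chain set Q).

    Repeatedly selects a random center from the remaining reads, builds its
    cluster, and removes the chain's members from the pool until empty.
    Deterministic under ``params.rng_seed``.
    """
    rng = np.random.default_rng(params.rng_seed)
    remaining = set(r.read_id for r in reads)
    chains: list[SeedsChain] = []
    seed_id = 0
    chain_id = 0
    while remaining:
        cid = select_center(remaining, rng)
        center = reads[cid]
        cands = gather_candidates(center, groups, allowed=remaining)
        chain = build_cluster(
            center, cands, reads, params, chain_id=chain_id, seed_id_start=seed_id
        )
        chains.append(chain)
        seed_id += len(chain.seeds)
        chain_id += 1
        remaining -= chain.member_ids
    return chains
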