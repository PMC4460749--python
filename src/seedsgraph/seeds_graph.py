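"""Seeds graph construction.

Seeds with the same (wildcard-compatible) pattern are first merged across
chains, pooling their members and re-deriving disputed columns from the
pooled member bases — the spectral-alignment-style error reconciliation.
Chains sharing at least two consecutive seeds are then fused onto a common
coordinate.  The graph has one vertex per surviving seed; edges are the chain
adjacencies (weight = gap to the next seed, negative when windows overlap
after fusion) plus directed cross-chain suffix-prefix overlap edges whose
overlap length exceeds ``q``.  Each pattern pair is additionally tested
against the reverse complement; such hits carry an orientation flag, which
two-strand data requires for correctness.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import networkx as nx

from .clustering import Seed, SeedsChain
from .io import reverse_complement

logger = logging.getLogger(__name__)

__all__ = [
    "SeedsGraph",
    "merge_identical_seeds",
    "merge_chains",
    "suffix_prefix_overlap",
    "build_graph",
    "patterns_compatible",
]


@dataclass
class SeedsGraph:
    """Vertices are seeds; edges are chain links and overlap links.

    ``g`` is a directed multigraph whose nodes are seed ids.  Edge attributes:
    ``kind`` ('chain' or 'overlap'), ``weight`` (next-seed distance for chain
    edges, overlap length for overlap edges), ``flip`` (overlap found against
    the reverse complement), and for chain edges the precomputed forward /
    reverse splice segments used by contig extraction.
    """

    g: nx.MultiDiGraph = field(default_factory=nx.MultiDiGraph)
    seeds: dict[int, Seed] = field(default_factory=dict)
    chains: list[SeedsChain] = field(default_factory=list)

    def edges_by_kind(self, kind: str):
        return [
            (u, v, d) for u, v, d in self.g.edges(data=True) if d["kind"] == kind
        ]


def patterns_compatible(a: str, b: str) -> bool:
    """True when patterns agree at every position where both are concrete."""
    if len(a) != len(b):
        return False
    for x, y in zip(a, b):
        if x != y and x != "n" and y != "n":
            return False
    return True


def _rederive_pattern(members, fallback: str) -> str:
    """Recompute each column from pooled member windows.

    Majority base per column; ``n`` where members still disagree beyond a
    unanimous majority... a column is concrete iff all member bases agree.
    """
    if not members:
        return fallback
    l = len(fallback)
    cols = []
    for i in range(l):
        bases = {m.window[i] for m in members}
        cols.append(bases.pop() if len(bases) == 1 else "n")
    return "".join(cols)


def merge_identical_seeds(
    Q: list[SeedsChain], mode: str = "wildcard"
) -> list[SeedsChain]:
    """Merge seeds with the same pattern across chains (in place on copies).

    ``mode='strict'`` merges only byte-identical patterns; ``'wildcard'``
    (default) also merges wildcard-compatible ones, since ``n`` columns exist
    precisely to absorb sequencing errors.  The smallest seed id survives and
    the merged pattern is re-derived from the pooled members.
    """
    if mode not in ("strict", "wildcard"):
        raise ValueError(f"unknown merge mode {mode!r}")
    all_seeds: list[Seed] = [s for c in Q for s in c.seeds]
    # exact-duplicate buckets first (fast path)
    buckets: dict[str, list[Seed]] = {}
    for s in sorted(all_seeds, key=lambda s: (s.pattern, s.seed_id)):
        buckets.setdefault(s.pattern, []).append(s)

    parent: dict[int, int] = {s.seed_id: s.seed_id for s in all_seeds}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            lo, hi = min(ra, rb), max(ra, rb)
            parent[hi] = lo

    for group in buckets.values():
        for s in group[1:]:
            union(group[0].seed_id, s.seed_id)
    if mode == "wildcard":
        wild = [p for p in buckets if "n" in p]
        pats = sorted(buckets)
        for wp in wild:
            for p in pats:
                if p != wp and patterns_compatible(wp, p):
                    union(buckets[wp][0].seed_id, buckets[p][0].seed_id)

    by_id = {s.seed_id: s for s in all_seeds}
    clusters: dict[int, list[Seed]] = {}
    for s in all_seeds:
        clusters.setdefault(find(s.seed_id), []).append(s)
    merged: dict[int, Seed] = {}
    for root, group in sorted(clusters.items()):
        keeper = by_id[root]
        if len(group) > 1:
            pooled = []
            seen = set()
            for s in sorted(group, key=lambda s: s.seed_id):
                for mem in s.members:
                    key = (mem.seq_id, mem.offset, mem.strand)
                    if key not in seen:
                        seen.add(key)
                        pooled.append(mem)
            keeper.members = pooled
            keeper.pattern = _rederive_pattern(pooled, keeper.pattern)
        merged[root] = keeper

    # rewrite chains to surviving seeds, dropping consecutive duplicates
    for chain in Q:
        new_seeds, new_starts = [], []
        for s, ws in zip(chain.seeds, chain.starts):
            surv = merged[find(s.seed_id)]
            if new_seeds and new_seeds[-1].seed_id == surv.seed_id:
                continue
            new_seeds.append(surv)
            new_starts.append(ws)
        chain.seeds, chain.starts = new_seeds, new_starts
        chain.relink()
    return Q


def _shared_run(a: SeedsChain, b: SeedsChain) -> tuple[int, int, int] | None:
    """Longest run of >= 2 consecutive shared seeds; (ia, ib, length)."""
    ids_b = {s.seed_id: j for j, s in enumerate(b.seeds)}
    best = None
    for i, s in enumerate(a.seeds):
        j = ids_b.get(s.seed_id)
        if j is None:
            continue
        n = 0
        while (
            i + n < len(a.seeds)
            and j + n < len(b.seeds)
            and a.seeds[i + n].seed_id == b.seeds[j + n].seed_id
        ):
            n += 1
        if n >= 2 and (best is None or n > best[2]):
            best = (i, j, n)
    return best


def _fuse(a: SeedsChain, b: SeedsChain, run: tuple[int, int, int]) -> SeedsChain | None:
    ia, ib, n = run
    off = a.starts[ia] - b.starts[ib]
    for d in range(n):
        if b.starts[ib + d] + off != a.starts[ia + d]:
            return None  # inconsistent layouts
    layout: dict[int, tuple[Seed, int]] = {}
    for s, ws in zip(a.seeds, a.starts):
        layout[s.seed_id] = (s, ws)
    for s, ws in zip(b.seeds, b.starts):
        want = ws + off
        if s.seed_id in layout and layout[s.seed_id][1] != want:
            return None
        layout.setdefault(s.seed_id, (s, want))
    items = sorted(layout.values(), key=lambda t: (t[1], t[0].seed_id))
    fused = SeedsChain(
        chain_id=min(a.chain_id, b.chain_id),
        center_id=a.center_id,
        seeds=[s for s, _ in items],
        starts=[ws for _, ws in items],
        member_ids=a.member_ids | b.member_ids,
    )
    fused.relink()
    # splice consensus strings on the common coordinate
    lo = min(a.origin, b.origin + off)
    hi = max(a.origin + len(a.consensus), b.origin + off + len(b.consensus))
    cols = ["N"] * (hi - lo)
    for chain, o in ((b, b.origin + off), (a, a.origin)):
        for i, base in enumerate(chain.consensus):
            if base != "N":
                cols[o - lo + i] = base
    fused.consensus = "".join(cols)
    fused.origin = lo
    return fused


def merge_chains(Q: list[SeedsChain]) -> list[SeedsChain]:
    """Fuse chains sharing >= 2 consecutive seeds until a fixed point.

    A shared run fixes the relative coordinate between the two chains; fused
    chains may contain overlapping windows (negative next distances).
    Inconsistent layouts are left unmerged with a logged warning.
    """
    chains = list(Q)
    changed = True
    refused: set[tuple[int, int]] = set()
    while changed:
        changed = False
        seed_to_chain: dict[int, int] = {}
        for idx, c in enumerate(chains):
            for s in c.seeds:
                seed_to_chain.setdefault(s.seed_id, idx)
        for idx, c in enumerate(chains):
            partner = None
            for s in c.seeds:
                other = seed_to_chain.get(s.seed_id)
                if other is not None and other != idx:
                    pair = (min(idx, other), max(idx, other))
                    if pair in refused:
                        continue
                    run = _shared_run(chains[pair[0]], chains[pair[1]])
                    if run:
                        partner = (pair, run)
                        break
            if partner:
                (i0, i1), run = partner
                fused = _fuse(chains[i0], chains[i1], run)
                if fused is None:
                    logger.warning(
                        "chains %d and %d share seeds with inconsistent layouts; "
                        "left unmerged",
                        chains[i0].chain_id,
                        chains[i1].chain_id,
                    )
                    refused.add((i0, i1))
                    continue
                chains = [x for j, x in enumerate(chains) if j not in (i0, i1)]
                chains.append(fused)
                changed = True
                break
    return chains


def suffix_prefix_overlap(u: Seed, v: Seed) -> int:
    """Largest d with u.pattern's suffix matching v.pattern's prefix.

    Position-wise with ``n`` matching anything; exact otherwise; 0 if none.
    """
    pa, pb = u.pattern, v.pattern
    if len(pa) != len(pb):
        raise ValueError("seed patterns must have equal length")
    l = len(pa)
    for d in range(l - 1, 0, -1):
        if patterns_compatible(pa[l - d :], pb[:d]):
            return d
    return 0


def _overlap_len(pa: str, pb: str, lo: int) -> int:
    """Largest d > lo with suffix(pa, d) compatible with prefix(pb, d)."""
    l = len(pa)
    for d in range(l - 1, lo, -1):
        if patterns_compatible(pa[l - d :], pb[:d]):
            return d
    return 0


def _resolved(seed: Seed) -> str:
    """Seed pattern with wildcards resolved by member majority (N on tie)."""
    out = []
    for i, p in enumerate(seed.pattern):
        cnt = Counter(m.window[i] for m in seed.members)
        if not cnt:
            out.append("N" if p == "n" else p)
            continue
        ranked = sorted(cnt.items(), key=lambda kv: (-kv[1], kv[0]))
        if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
            out.append("N")
        else:
            out.append(ranked[0][0])
    return "".join(out)


def build_graph(Q: list[SeedsChain], q: int) -> SeedsGraph:
    """Build the seeds graph from post-merge chains.

    Chain edges carry precomputed splice segments (gap fill from the chain
    consensus) so downstream contig extraction is self-contained.  Overlap
    edges link seeds of different chains whose suffix-prefix overlap exceeds
    ``q``, both same-strand and against the reverse complement (``flip``).
    """
    if q < 1:
        raise ValueError("q must be >= 1")
    sg = SeedsGraph()
    sg.chains = list(Q)
    chain_of: dict[int, int] = {}
    for c in Q:
        for s in c.seeds:
            sg.seeds[s.seed_id] = s
            chain_of.setdefault(s.seed_id, c.chain_id)
            sg.g.add_node(s.seed_id)
    resolved = {sid: _resolved(s) for sid, s in sg.seeds.items()}

    l = None
    for c in Q:
        if c.seeds:
            l = len(c.seeds[0].pattern)
        for i in range(len(c.seeds) - 1):
            u, v = c.seeds[i], c.seeds[i + 1]
            gap = c.starts[i + 1] - (c.starts[i] + l)
            if gap >= 0:
                a = c.starts[i] + l - c.origin
                fill = c.consensus[a : a + gap] if c.consensus else "N" * gap
                if len(fill) < gap:
                    fill = fill + "N" * (gap - len(fill))
                seg_fwd = fill + resolved[v.seed_id]
                seg_rev = reverse_complement(fill) + reverse_complement(
                    resolved[u.seed_id]
                )
            else:
                o = -gap
                seg_fwd = resolved[v.seed_id][o:]
                seg_rev = reverse_complement(resolved[u.seed_id])[o:]
            sg.g.add_edge(
                u.seed_id,
                v.seed_id,
                kind="chain",
                weight=gap,
                flip=False,
                seg_fwd=seg_fwd,
                seg_rev=seg_rev,
            )

    if l is None:
        return sg

    # Overlap edges.  Plain (wildcard-free) pattern pairs are found through
    # prefix/suffix hash indexes over the q+1..l-1 useful lengths; pairs
    # involving a wildcard pattern fall back to a direct position-wise scan.
    # A flip edge (u, v) records suffix(u) matching prefix(rc(v)), i.e. u
    # followed by the reverse complement of v; the relation is symmetric in
    # (u, v), so flip edges are stored once with u <= v.
    ids = sorted(sg.seeds)
    wildset = {sid for sid in ids if "n" in sg.seeds[sid].pattern}
    plain = [sid for sid in ids if sid not in wildset]
    prefix_index: dict[int, dict[str, list[int]]] = {}
    suffix_index: dict[int, dict[str, list[int]]] = {}
    for d in range(q + 1, l):
        pidx: dict[str, list[int]] = {}
        sidx: dict[str, list[int]] = {}
        for sid in plain:
            pat = sg.seeds[sid].pattern
            pidx.setdefault(pat[:d], []).append(sid)
            sidx.setdefault(pat[l - d :], []).append(sid)
        prefix_index[d] = pidx
        suffix_index[d] = sidx

    seen: set[tuple[int, int, bool]] = set()

    def add_overlap(u: int, v: int, d: int, flip: bool) -> None:
        if u == v and not flip:
            return
        if u != v and chain_of.get(u) == chain_of.get(v):
            return
        key = (u, v, flip)
        if key in seen:
            return
        seen.add(key)
        sg.g.add_edge(u, v, kind="overlap", weight=d, flip=flip)

    for usid in plain:
        pat = sg.seeds[usid].pattern
        for d in range(l - 1, q, -1):
            sfx = pat[l - d :]
            for vsid in prefix_index[d].get(sfx, ()):
                add_overlap(usid, vsid, d, False)
            # flip: suffix(u, d) == rc(suffix(v, d))
            for vsid in suffix_index[d].get(reverse_complement(sfx), ()):
                if usid <= vsid:
                    add_overlap(usid, vsid, d, True)

    for usid in sorted(wildset):
        pat = sg.seeds[usid].pattern
        for vsid in ids:
            if vsid in wildset and vsid < usid:
                continue  # both-wild pairs handled once
            pat_v = sg.seeds[vsid].pattern
            if vsid != usid:
                d = _overlap_len(pat, pat_v, q)
                if d > q:
                    add_overlap(usid, vsid, d, False)
                d = _overlap_len(pat_v, pat, q)
                if d > q:
                    add_overlap(vsid, usid, d, False)
            d = _overlap_len(pat, reverse_complement(pat_v), q)
            if d > q:
                a, b = min(usid, vsid), max(usid, vsid)
                add_overlap(a, b, d, True)
    return sg
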