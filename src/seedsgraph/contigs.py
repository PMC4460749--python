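"""Contig extraction and mate-pair repeat resolution.

Reads are threaded through the seeds graph via their seed memberships; mate
pairs whose ends anchor on opposite sides of a shared linear run of nodes
(a repeat shorter than the insert) let the run be duplicated so each
traversal gets a private copy, and parallel paths between shared endpoints
are arbitrated by the insert-size constraint.  Maximal unambiguous paths of
the resolved graph — every interior node with in-degree and out-degree one —
are emitted as contigs (unitig realization of the Euler-path goal); mate
pairs then order and orient contigs into scaffolds.

Orientation: contig extraction works on an oriented expansion of the graph
with nodes (seed id, +/-1); every stored edge contributes its own and its
reverse-complement traversal, so chains discovered from reverse-strand
centers splice correctly.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import networkx as nx

from .clustering import Seed
from .io import ReadSet, reverse_complement
from .seeds_graph import SeedsGraph, _resolved

logger = logging.getLogger(__name__)

__all__ = [
    "Contig",
    "Scaffold",
    "thread_reads",
    "resolve_repeats",
    "extract_contigs",
    "consensus_column",
    "scaffold",
    "scaffold_sequences",
]


@dataclass
class Contig:
    contig_id: int
    seed_path: list[tuple[int, int]]  # (seed id, orientation)
    seq: str
    supporting_reads: set[int] = field(default_factory=set)
    seed_coords: dict[int, int] = field(default_factory=dict)  # seed id -> pattern start
    seed_orients: dict[int, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class Scaffold:
    scaffold_id: int
    parts: list[tuple[int, int, int]]  # (contig_id, orientation, gap to next part)


def consensus_column(bases) -> str:
    """Strict-majority base of a multiset; ``N`` on tie or empty."""
    cnt = Counter(bases)
    if not cnt:
        return "N"
    ranked = sorted(cnt.items(), key=lambda kv: (-kv[1], kv[0]))
    if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
        return "N"
    return ranked[0][0]


def thread_reads(graph: SeedsGraph, reads: ReadSet) -> dict[int, list[int]]:
    """Ordered seed ids per read, by member offset ascending along the read."""
    hits: dict[int, list[tuple[int, int]]] = defaultdict(list)
    for sid, seed in sorted(graph.seeds.items()):
        for mem in seed.members:
            hits[mem.seq_id].append((mem.offset, sid))
    paths: dict[int, list[int]] = {}
    for r in reads:
        entries = sorted(hits.get(r.read_id, ()))
        paths[r.read_id] = [sid for _, sid in entries]
    return paths


# ---------------------------------------------------------------------------
# repeat resolution
# ---------------------------------------------------------------------------


def _linear_runs(g: nx.MultiDiGraph):
    """Maximal runs entry..exit with in(entry) >= 2, out(exit) >= 2 and a
    strictly linear interior; a single shared node is a run of length 1."""
    runs = []
    for entry in sorted(g.nodes):
        if g.in_degree(entry) < 2:
            continue
        run = [entry]
        node = entry
        while g.out_degree(node) == 1:
            nxt = next(iter(g.successors(node)))
            if g.in_degree(nxt) != 1 or nxt in run:
                break
            run.append(nxt)
            node = nxt
        if g.out_degree(node) >= 2:
            runs.append(run)
    return runs


def _anchor_set(g: nx.MultiDiGraph, start: int, forward: bool, max_hops: int):
    """Seeds on the linear path up/downstream of ``start`` (inclusive)."""
    out = [start]
    node = start
    for _ in range(max_hops):
        nbrs = list(g.successors(node)) if forward else list(g.predecessors(node))
        if len(nbrs) != 1:
            break
        node = nbrs[0]
        if node in out:
            break
        out.append(node)
    return set(out)


def _path_bp(g: nx.MultiDiGraph, path: list[int], l: int) -> int:
    """Base-pair span of a node path (patterns minus overlaps plus gaps)."""
    total = l
    for a, b in zip(path, path[1:]):
        data = next(iter(g[a][b].values()))
        if data["kind"] == "chain":
            total += l + data["weight"]
        else:
            total += l - data["weight"]
    return total


def resolve_repeats(
    graph: SeedsGraph,
    read_paths: dict[int, list[int]],
    mate_pairs: ReadSet,
    insert_size: int,
    insert_tol: float = 0.2,
    max_iter: int = 10,
) -> SeedsGraph:
    """Split repeat-induced tangles using mate-pair evidence.

    (a) a linear run shared by several traversals is duplicated when mate
    pairs pair each entry with a distinct exit; (b) among parallel paths
    between shared endpoints, only the one whose length satisfies the
    insert-size constraint is kept for the spanning pairs; (c) runs without
    spanning evidence are left intact.  Rules iterate to a fixed point
    (capped at ``max_iter``); contradictory constraints leave the graph
    unchanged with a logged warning.
    """
    g = graph.g
    l = next((len(s.pattern) for s in graph.seeds.values()), None)
    if l is None or not mate_pairs.paired:
        return graph
    max_hops = max(2, insert_size // l + 2)
    next_id = max(graph.seeds) + 1 if graph.seeds else 0

    for _ in range(max_iter):
        changed = False
        seed_reads: dict[int, set[int]] = defaultdict(set)
        for rid, path in read_paths.items():
            for sid in path:
                seed_reads[sid].add(rid)

        def reads_on(seed_set: set[int]) -> set[int]:
            out: set[int] = set()
            for sid in seed_set:
                out |= seed_reads.get(sid, set())
            return out

        def pair_support(up_set: set[int], down_set: set[int]) -> int:
            up_reads = reads_on(up_set)
            down_reads = reads_on(down_set)
            n = 0
            for rid in up_reads:
                mate = mate_pairs[rid].mate_id
                if mate is not None and mate in down_reads:
                    n += 1
            return n

        # --- rule (a): duplicate shared runs with matched entries/exits ---
        for run in _linear_runs(g):
            entry, exit_ = run[0], run[-1]
            run_set = set(run)
            preds = sorted(set(g.predecessors(entry)) - run_set)
            succs = sorted(set(g.successors(exit_)) - run_set)
            if len(preds) < 2 or len(preds) != len(succs):
                continue
            # interior must be private to the run
            clean = all(
                not (set(g.predecessors(n)) - run_set) for n in run[1:]
            ) and all(not (set(g.successors(n)) - run_set) for n in run[:-1])
            if not clean:
                continue
            ups = {
                p: _anchor_set(g, p, forward=False, max_hops=max_hops) - run_set
                for p in preds
            }
            downs = {
                s_: _anchor_set(g, s_, forward=True, max_hops=max_hops) - run_set
                for s_ in succs
            }
            support = {
                (p, s_): pair_support(ups[p], downs[s_])
                for p in preds
                for s_ in succs
            }
            order = sorted(support.items(), key=lambda kv: (-kv[1], kv[0]))
            used_p: set[int] = set()
            used_s: set[int] = set()
            matching: list[tuple[int, int]] = []
            for (p, s_), n in order:
                if n < 1 or p in used_p or s_ in used_s:
                    continue
                matching.append((p, s_))
                used_p.add(p)
                used_s.add(s_)
            if len(matching) != len(preds):
                continue  # ambiguous or unsupported pairing; leave intact
            # split: one private copy of the run per matched (entry, exit)
            copies: list[tuple[tuple[int, int], dict[int, int]]] = []
            for p, s_ in sorted(matching):
                mapping: dict[int, int] = {}
                for n in run:
                    seed = graph.seeds[n]
                    graph.seeds[next_id] = Seed(
                        next_id, seed.pattern, list(seed.members)
                    )
                    g.add_node(next_id)
                    mapping[n] = next_id
                    next_id += 1
                for a, b in zip(run, run[1:]):
                    for key in g[a][b]:
                        g.add_edge(mapping[a], mapping[b], **g[a][b][key])
                for key in list(g[p][entry]):
                    g.add_edge(p, mapping[entry], **g[p][entry][key])
                for key in list(g[exit_][s_]):
                    g.add_edge(mapping[exit_], s_, **g[exit_][s_][key])
                copies.append(((p, s_), mapping))
            for n in run:
                g.remove_node(n)
                del graph.seeds[n]
            # reassign read paths to the copy whose flank the read touches
            for rid, path in list(read_paths.items()):
                if not any(sid in run_set for sid in path):
                    continue
                anchors = set(path) - run_set
                mate = mate_pairs[rid].mate_id
                if mate is not None:
                    anchors |= set(read_paths.get(mate, ())) - run_set
                chosen = None
                for (p, s_), mapping in copies:
                    if anchors & (ups[p] | downs[s_]):
                        chosen = mapping
                        break
                if chosen is None:
                    read_paths[rid] = [sid for sid in path if sid not in run_set]
                else:
                    read_paths[rid] = [
                        chosen.get(sid, sid) for sid in path
                    ]
            changed = True
            break  # topology changed; recompute runs

        if changed:
            continue

        # --- rule (b): parallel paths between shared endpoints ---
        for s in sorted(g.nodes):
            if g.out_degree(s) < 2:
                continue
            targets: dict[int, list[list[int]]] = defaultdict(list)
            for f in sorted(set(g.successors(s))):
                node, path = f, [s, f]
                for _ in range(max_hops):
                    if g.in_degree(node) >= 2:
                        break
                    nxts = list(g.successors(node))
                    if len(nxts) != 1:
                        break
                    node = nxts[0]
                    if node in path:
                        break
                    path.append(node)
                if g.in_degree(node) >= 2 and node != s:
                    targets[node].append(path)
            for t, paths_ in sorted(targets.items()):
                if len(paths_) < 2:
                    continue
                interiors = [set(p[1:-1]) for p in paths_]
                all_interior = set().union(*interiors)
                up = _anchor_set(g, s, False, max_hops) - all_interior
                down = _anchor_set(g, t, True, max_hops) - all_interior
                if pair_support(up, down) < 1:
                    continue
                lengths = [_path_bp(g, p, l) for p in paths_]
                lo = insert_size * (1 - insert_tol)
                hi = insert_size * (1 + insert_tol)
                ok = [i for i, ln in enumerate(lengths) if lo <= ln <= hi]
                if not ok:
                    logger.warning(
                        "no path between seeds %d and %d satisfies the "
                        "insert-size constraint; left intact",
                        s,
                        t,
                    )
                    continue
                if len(ok) != 1:
                    continue
                removed = False
                for i, p in enumerate(paths_):
                    if i == ok[0]:
                        continue
                    for n in sorted(set(p[1:-1])):
                        if n in g:
                            g.remove_node(n)
                            graph.seeds.pop(n, None)
                            removed = True
                if removed:
                    for rid, path in list(read_paths.items()):
                        read_paths[rid] = [
                            sid for sid in path if sid in graph.seeds
                        ]
                    changed = True
                    break
            if changed:
                break
        if not changed:
            break
    return graph


# ---------------------------------------------------------------------------
# contig extraction
# ---------------------------------------------------------------------------


def _oriented_graph(graph: SeedsGraph) -> nx.DiGraph:
    """Expand the stored graph into oriented nodes (seed id, +/-1).

    Overlap edges are traversable only where they join chain tails: clusters
    are joined together across the tail seeds at both ends, while overlap
    hits against a chain's interior merely restate sequence the chain
    already spells and would otherwise cut it.
    """
    H = nx.DiGraph()
    resolved = {sid: _resolved(s) for sid, s in graph.seeds.items()}
    chain_out: set[int] = set()
    chain_in: set[int] = set()
    for u, v, data in graph.g.edges(data=True):
        if data["kind"] == "chain":
            chain_out.add(u)
            chain_in.add(v)
    for sid in graph.seeds:
        H.add_node((sid, 1))
        H.add_node((sid, -1))
    for u, v, data in graph.g.edges(data=True):
        if u not in graph.seeds or v not in graph.seeds:
            continue
        if data["kind"] == "chain":
            seg_f = data.get("seg_fwd")
            seg_r = data.get("seg_rev")
            if seg_f is None:
                seg_f = resolved[v]
                seg_r = reverse_complement(resolved[u])
            _add_h_edge(H, (u, 1), (v, 1), seg_f)
            _add_h_edge(H, (v, -1), (u, -1), seg_r)
        else:
            d = data["weight"]
            if not data.get("flip"):
                if u in chain_out or v in chain_in:
                    continue
                _add_h_edge(H, (u, 1), (v, 1), resolved[v][d:])
                _add_h_edge(H, (v, -1), (u, -1), reverse_complement(resolved[u])[d:])
            else:
                if u in chain_out or v in chain_out:
                    continue
                _add_h_edge(H, (u, 1), (v, -1), reverse_complement(resolved[v])[d:])
                _add_h_edge(H, (v, 1), (u, -1), reverse_complement(resolved[u])[d:])
    return H


def _add_h_edge(H: nx.DiGraph, a, b, seg: str) -> None:
    if H.has_edge(a, b):
        # parallel traversals between the same oriented pair are ambiguous
        H[a][b]["multi"] = True
        return
    H.add_edge(a, b, seg=seg, multi=False)


def extract_contigs(
    graph: SeedsGraph,
    read_paths: dict[int, list[int]] | None = None,
    min_length: int = 100,
) -> list[Contig]:
    """Emit maximal unambiguous oriented paths as contigs.

    An edge is traversed only when its source has out-degree one and its
    target in-degree one in the oriented graph, so no contig spans a branch.
    Reverse-complement twin paths are deduplicated.
    """
    H = _oriented_graph(graph)
    resolved = {sid: _resolved(s) for sid, s in graph.seeds.items()}

    def safe_succ(n):
        succs = list(H.successors(n))
        if len(succs) != 1:
            return None
        m = succs[0]
        if H.in_degree(m) != 1 or H[n][m].get("multi"):
            return None
        return m

    def has_safe_pred(n):
        preds = list(H.predecessors(n))
        if len(preds) != 1:
            return False
        p = preds[0]
        return H.out_degree(p) == 1 and not H[p][n].get("multi")

    def walk(start, visited):
        path = [start]
        visited.add(start)
        used = {start[0]}
        node = start
        while True:
            nxt = safe_succ(node)
            if nxt is None or nxt[0] in used:
                break
            path.append(nxt)
            visited.add(nxt)
            used.add(nxt[0])
            node = nxt
        return path

    visited: set = set()
    paths = []
    for start in sorted(H.nodes):
        if start not in visited and not has_safe_pred(start):
            paths.append(walk(start, visited))
    for start in sorted(H.nodes):  # cycles of safe edges
        if start not in visited:
            paths.append(walk(start, visited))

    canonical: dict[tuple, list] = {}
    for path in paths:
        comp = tuple((sid, -o) for sid, o in reversed(path))
        key = min(tuple(path), comp)
        if key not in canonical or len(path) > len(canonical[key]):
            canonical[key] = path

    contigs = []
    cid = 0
    for key in sorted(canonical):
        path = canonical[key]
        sid0, o0 = path[0]
        seq = resolved[sid0] if o0 == 1 else reverse_complement(resolved[sid0])
        coords = {sid0: 0}
        orients = {sid0: o0}
        for a, b in zip(path, path[1:]):
            seq += H[a][b]["seg"]
            coords[b[0]] = len(seq) - len(resolved[b[0]])
            orients[b[0]] = b[1]
        if len(seq) < min_length:
            continue
        support = set()
        for sid, _ in path:
            for mem in graph.seeds[sid].members:
                support.add(mem.seq_id)
        contigs.append(
            Contig(
                contig_id=cid,
                seed_path=list(path),
                seq=seq,
                supporting_reads=support,
                seed_coords=coords,
                seed_orients=orients,
            )
        )
        cid += 1
    return contigs


# ---------------------------------------------------------------------------
# scaffolding
# ---------------------------------------------------------------------------


def _read_placements(
    contigs: list[Contig], reads: ReadSet, seeds: dict[int, Seed], l: int
):
    """First placement of each read: (contig id, start, orientation).

    ``start`` is the contig-forward position where the contig-matching form
    of the read begins; orientation +1 when that form is the read itself,
    -1 when it is the reverse complement.
    """
    place: dict[int, tuple[int, int, int]] = {}
    for ctg in contigs:
        for sid, so in ctg.seed_path:
            seed = seeds.get(sid)
            if seed is None:
                continue
            coord = ctg.seed_coords[sid]
            for mem in seed.members:
                if mem.seq_id in place:
                    continue
                rlen = len(reads[mem.seq_id].seq)
                orient = mem.strand * so
                if so == 1:
                    start = coord - mem.offset
                else:
                    start = coord - (rlen - mem.offset - l)
                place[mem.seq_id] = (ctg.contig_id, start, orient)
    return place


def scaffold(
    contigs: list[Contig],
    mate_pairs: ReadSet,
    insert_size: int,
    min_links: int = 3,
    seeds: dict[int, Seed] | None = None,
) -> list[Scaffold]:
    """Order and orient contigs into scaffolds from mate-pair links.

    Links between contig ends are bundled by the pair of ends they join;
    bundles with fewer than ``min_links`` pairs are dropped; remaining links
    apply greedily by descending weight, rejecting any that would reuse an
    occupied contig end or close a cycle.  Unlinked contigs become singleton
    scaffolds.  Gap estimates are the median of insert size minus the two
    end overhangs and may be negative.
    """
    if not contigs:
        return []
    seeds = seeds or {}
    l = next((len(s.pattern) for s in seeds.values()), None)
    if l is None or not mate_pairs.paired:
        return [Scaffold(i, [(c.contig_id, 1, 0)]) for i, c in enumerate(contigs)]

    place = _read_placements(contigs, mate_pairs, seeds, l)
    clen = {c.contig_id: len(c.seq) for c in contigs}

    bundles: dict[tuple, list[int]] = defaultdict(list)
    for r in mate_pairs:
        if r.mate_id is None or r.read_id > r.mate_id:
            continue
        p1, p2 = place.get(r.read_id), place.get(r.mate_id)
        if p1 is None or p2 is None or p1[0] == p2[0]:
            continue
        (ca, pa, oa), (cb, pb, ob) = p1, p2
        rlen_a = len(mate_pairs[r.read_id].seq)
        rlen_b = len(mate_pairs[r.mate_id].seq)
        # the fragment leaves contig A through its right end when the first
        # read maps forward, through its left end otherwise; likewise for B.
        end_a = "R" if oa == 1 else "L"
        end_b = "R" if ob == 1 else "L"
        over_a = clen[ca] - pa if oa == 1 else pa + rlen_a
        over_b = clen[cb] - pb if ob == 1 else pb + rlen_b
        gap = insert_size - over_a - over_b
        key = (ca, end_a, cb, end_b)
        alt = (cb, end_b, ca, end_a)
        if alt < key:
            key = alt
        bundles[key].append(gap)

    links = []
    for (ca, ea, cb, eb), gaps in bundles.items():
        if len(gaps) >= min_links:
            gaps.sort()
            links.append((len(gaps), gaps[len(gaps) // 2], ca, ea, cb, eb))
    links.sort(key=lambda t: (-t[0], t[2:]))

    used_ends: set[tuple[int, str]] = set()
    adj: dict[tuple[int, str], tuple[int, str, int]] = {}
    parent: dict[int, int] = {c.contig_id: c.contig_id for c in contigs}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for n, gap, ca, ea, cb, eb in links:
        if (ca, ea) in used_ends or (cb, eb) in used_ends:
            continue
        if find(ca) == find(cb):
            continue
        used_ends.add((ca, ea))
        used_ends.add((cb, eb))
        adj[(ca, ea)] = (cb, eb, gap)
        adj[(cb, eb)] = (ca, ea, gap)
        parent[find(ca)] = find(cb)

    comps: dict[int, list[int]] = defaultdict(list)
    for c in contigs:
        comps[find(c.contig_id)].append(c.contig_id)

    scaffolds = []
    sid_counter = 0
    for root in sorted(comps, key=lambda r: min(comps[r])):
        comp = sorted(comps[root])
        start, start_end = None, None
        for x in comp:
            for e in ("L", "R"):
                if (x, e) not in adj:
                    start, start_end = x, e
                    break
            if start is not None:
                break
        if start is None:  # circular; break at the smallest id
            start, start_end = comp[0], "L"
        parts = []
        node, free_end = start, start_end
        seen = set()
        while True:
            seen.add(node)
            orient = 1 if free_end == "L" else -1
            exit_end = "R" if free_end == "L" else "L"
            nxt = adj.get((node, exit_end))
            parts.append((node, orient, nxt[2] if nxt else 0))
            if nxt is None or nxt[0] in seen:
                break
            node, free_end = nxt[0], nxt[1]
        scaffolds.append(Scaffold(sid_counter, parts))
        sid_counter += 1
    return scaffolds


def scaffold_sequences(
    scaffolds: list[Scaffold], contigs: list[Contig]
) -> list[tuple[str, str]]:
    """Render scaffolds as (name, sequence) with gap runs of N."""
    by_id = {c.contig_id: c for c in contigs}
    out = []
    for sc in scaffolds:
        chunks = []
        for i, (cid, orient, gap) in enumerate(sc.parts):
            seq = by_id[cid].seq
            chunks.append(seq if orient == 1 else reverse_complement(seq))
            if i + 1 < len(sc.parts):
                chunks.append("N" * max(gap, 1))
        out.append((f"scaffold_{sc.scaffold_id}", "".join(chunks)))
    return out
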