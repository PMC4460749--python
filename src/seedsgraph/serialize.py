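"""Plain-text interchange formats for staged runs.

k-mer groups::

    kmer<TAB>seq_id:coded_offset,seq_id:coded_offset,...

chains (one ``C`` header per chain, one ``S`` line per seed)::

    C<TAB>chain_id<TAB>center_id<TAB>origin<TAB>consensus<TAB>member_ids(,)
    S<TAB>chain_id<TAB>seed_id<TAB>start<TAB>pattern<TAB>next_id|.<TAB>next_dist|.<TAB>members

    members = seq_id:offset:strand:window;...   (strand is + or -)

graph edges::

    u<TAB>v<TAB>kind<TAB>weight<TAB>flip<TAB>seg_fwd<TAB>seg_rev

All files round-trip exactly; the staged pipeline is bit-identical to the
monolithic run.
"""

from __future__ import annotations

import networkx as nx

from .clustering import Seed, SeedMember, SeedsChain
from .kmer_index import KmerGroup, KmerGroupSet, OffsetInfo
from .seeds_graph import SeedsGraph

__all__ = [
    "dump_kmer_groups",
    "load_kmer_groups",
    "dump_chains",
    "load_chains",
    "dump_graph",
    "load_graph",
    "graph_to_dot",
]


def dump_kmer_groups(groups: KmerGroupSet, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"#k={groups.k}\tt={groups.t}\n")
        for kmer in sorted(groups.groups):
            members = ",".join(
                f"{m.seq_id}:{m.coded_offset}" for m in groups.groups[kmer].members
            )
            fh.write(f"{kmer}\t{members}\n")


def load_kmer_groups(path: str) -> KmerGroupSet:
    groups: dict[str, KmerGroup] = {}
    k = t = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                fields = dict(f.split("=") for f in line[1:].split("\t"))
                k, t = int(fields["k"]), int(fields["t"])
                continue
            kmer, members = line.split("\t")
            infos = [
                OffsetInfo(int(a), int(b))
                for a, b in (m.split(":") for m in members.split(","))
            ]
            groups[kmer] = KmerGroup(m_k=kmer, members=infos)
    if k is None:
        raise ValueError(f"{path}: missing #k= header")
    return KmerGroupSet(groups=groups, k=k, t=t)


def _fmt_members(members: list[SeedMember]) -> str:
    return ";".join(
        f"{m.seq_id}:{m.offset}:{'+' if m.strand == 1 else '-'}:{m.window}"
        for m in members
    )


def _parse_members(text: str) -> list[SeedMember]:
    out = []
    if not text:
        return out
    for item in text.split(";"):
        sid, off, strand, window = item.split(":")
        out.append(SeedMember(int(sid), int(off), 1 if strand == "+" else -1, window))
    return out


def dump_chains(chains: list[SeedsChain], path: str) -> None:
    with open(path, "w") as fh:
        for c in chains:
            mids = ",".join(str(i) for i in sorted(c.member_ids))
            fh.write(f"C\t{c.chain_id}\t{c.center_id}\t{c.origin}\t{c.consensus}\t{mids}\n")
            for s, ws in zip(c.seeds, c.starts):
                nid = "." if s.next_id is None else str(s.next_id)
                nd = "." if s.next_distance is None else str(s.next_distance)
                fh.write(
                    f"S\t{c.chain_id}\t{s.seed_id}\t{ws}\t{s.pattern}\t{nid}\t{nd}\t"
                    f"{_fmt_members(s.members)}\n"
                )


def load_chains(path: str) -> list[SeedsChain]:
    chains: dict[int, SeedsChain] = {}
    seen_seeds: dict[int, Seed] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if parts[0] == "C":
                _, cid, center, origin, consensus, mids = parts
                chains[int(cid)] = SeedsChain(
                    chain_id=int(cid),
                    center_id=int(center),
                    origin=int(origin),
                    consensus=consensus,
                    member_ids=set(int(i) for i in mids.split(",") if i),
                )
            elif parts[0] == "S":
                _, cid, sid, ws, pattern, nid, nd, members = parts
                sid = int(sid)
                if sid in seen_seeds:  # seed shared across chains post-merge
                    seed = seen_seeds[sid]
                else:
                    seed = Seed(
                        seed_id=sid,
                        pattern=pattern,
                        members=_parse_members(members),
                        next_id=None if nid == "." else int(nid),
                        next_distance=None if nd == "." else int(nd),
                    )
                    seen_seeds[sid] = seed
                c = chains[int(cid)]
                c.seeds.append(seed)
                c.starts.append(int(ws))
    return list(chains.values())


def dump_graph(graph: SeedsGraph, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("#u\tv\tkind\tweight\tflip\tseg_fwd\tseg_rev\n")
        rows = []
        for u, v, data in graph.g.edges(data=True):
            rows.append(
                (
                    u,
                    v,
                    data["kind"],
                    data["weight"],
                    1 if data.get("flip") else 0,
                    data.get("seg_fwd", ""),
                    data.get("seg_rev", ""),
                )
            )
        for row in sorted(rows):
            fh.write("\t".join(str(x) for x in row) + "\n")


def load_graph(path: str, chains: list[SeedsChain]) -> SeedsGraph:
    sg = SeedsGraph()
    sg.chains = list(chains)
    for c in chains:
        for s in c.seeds:
            sg.seeds[s.seed_id] = s
            sg.g.add_node(s.seed_id)
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            u, v, kind, weight, flip, seg_fwd, seg_rev = line.rstrip("\n").split("\t")
            attrs = dict(kind=kind, weight=int(weight), flip=bool(int(flip)))
            if kind == "chain":
                attrs["seg_fwd"] = seg_fwd
                attrs["seg_rev"] = seg_rev
            sg.g.add_edge(int(u), int(v), **attrs)
    return sg


def graph_to_dot(graph: SeedsGraph, path: str) -> None:
    """GraphViz DOT dump (chain edges solid, overlap edges dashed)."""
    with open(path, "w") as fh:
        fh.write("digraph seeds {\n")
        for sid in sorted(graph.seeds):
            fh.write(f'  s{sid} [label="{sid}"];\n')
        rows = sorted(
            (u, v, d["kind"], d["weight"], bool(d.get("flip")))
            for u, v, d in graph.g.edges(data=True)
        )
        for u, v, kind, w, flip in rows:
            style = "solid" if kind == "chain" else "dashed"
            extra = ' color="red"' if flip else ""
            fh.write(f'  s{u} -> s{v} [label="{w}" style={style}{extra}];\n')
        fh.write("}\n")
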