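"""End-to-end assembly orchestration shared by the CLI and the library.

Phases: k-mer grouping -> read clustering -> seed/chain merging and graph
building -> read threading and mate-pair repeat resolution -> contig
extraction -> scaffolding.  Each phase's output can be dumped/reloaded via
:mod:`seedsgraph.serialize`, and the staged run is bit-identical to the
monolithic one.
"""

from __future__ import annotations

import copy
import json
import logging
from dataclasses import asdict, dataclass, field

from . import contigs as contigs_mod
from . import seeds_graph as graph_mod
from .clustering import AssemblyParams, cluster_all
from .io import ReadSet
from .kmer_index import build_kmer_groups
from .simulate import n50

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "AssemblyResult", "assemble"]


@dataclass
class RunConfig:
    """Full run configuration: algorithm parameters plus pipeline knobs."""

    params: AssemblyParams = field(default_factory=AssemblyParams)
    merge_mode: str = "wildcard"
    min_contig_length: int = 100
    min_links: int = 3
    insert_tol: float = 0.2
    resolve_repeats: bool = True

    def to_dict(self) -> dict:
        d = asdict(self.params)
        d.update(
            merge_mode=self.merge_mode,
            min_contig_length=self.min_contig_length,
            min_links=self.min_links,
            insert_tol=self.insert_tol,
            resolve_repeats=self.resolve_repeats,
        )
        return d


@dataclass
class AssemblyResult:
    chains: list
    graph: object
    contigs: list
    scaffolds: list
    read_paths: dict
    counters: dict

    def summary(self) -> dict:
        return dict(self.counters)


def assemble(reads: ReadSet, config: RunConfig | None = None) -> AssemblyResult:
    """Run the full pipeline on a read set."""
    config = config or RunConfig()
    p = config.params
    counters: dict = {"reads": len(reads)}

    groups = build_kmer_groups(reads, k=p.k, t=p.t)
    counters["kmer_groups_kept"] = len(groups)
    logger.info("k-mer groups kept: %d", len(groups))

    chains = cluster_all(reads, groups, p)
    counters["clusters"] = len(chains)
    counters["cluster_partition_sum"] = sum(len(c.member_ids) for c in chains)
    counters["singleton_clusters"] = sum(
        1 for c in chains if len(c.member_ids) == 1
    )
    logger.info("clusters: %d", len(chains))

    chains = graph_mod.merge_identical_seeds(chains, mode=config.merge_mode)
    chains = graph_mod.merge_chains(chains)
    counters["chains_after_merge"] = len(chains)
    graph = graph_mod.build_graph(chains, q=p.q)
    counters["seeds"] = len(graph.seeds)
    counters["edges_chain"] = len(graph.edges_by_kind("chain"))
    counters["edges_overlap"] = len(graph.edges_by_kind("overlap"))

    read_paths = contigs_mod.thread_reads(graph, reads)
    if config.resolve_repeats and reads.paired and reads.insert_size:
        seeds_before = len(graph.seeds)
        graph = contigs_mod.resolve_repeats(
            graph,
            read_paths,
            reads,
            reads.insert_size,
            insert_tol=config.insert_tol,
        )
        counters["seeds_after_resolution"] = len(graph.seeds)
        counters["repeat_nodes_duplicated"] = max(
            0, len(graph.seeds) - seeds_before
        )

    ctgs = contigs_mod.extract_contigs(
        graph, read_paths, min_length=config.min_contig_length
    )
    counters["contigs"] = len(ctgs)
    counters["contig_bp"] = sum(len(c) for c in ctgs)
    counters["n50_contigs"] = n50([len(c) for c in ctgs]) if ctgs else 0

    if reads.paired and reads.insert_size:
        scaffolds = contigs_mod.scaffold(
            ctgs,
            reads,
            reads.insert_size,
            min_links=config.min_links,
            seeds=graph.seeds,
        )
    else:
        scaffolds = [
            contigs_mod.Scaffold(i, [(c.contig_id, 1, 0)])
            for i, c in enumerate(ctgs)
        ]
    counters["scaffolds"] = len(scaffolds)
    if scaffolds:
        lens = [
            sum(
                len(next(c for c in ctgs if c.contig_id == cid))
                + (max(gap, 1) if i + 1 < len(sc.parts) else 0)
                for i, (cid, _, gap) in enumerate(sc.parts)
            )
            for sc in scaffolds
        ]
        counters["n50_scaffolds"] = n50(lens)
    else:
        counters["n50_scaffolds"] = 0
    counters["config"] = config.to_dict()
    return AssemblyResult(
        chains=chains,
        graph=graph,
        contigs=ctgs,
        scaffolds=scaffolds,
        read_paths=read_paths,
        counters=counters,
    )


def write_summary(counters: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(counters, fh, indent=2, sort_keys=True)
        fh.write("\n")
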