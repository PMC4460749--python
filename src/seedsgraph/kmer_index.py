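"""Both-strand k-mer grouping (in-process map / shuffle / reduce).

Every read is scanned on both strands; each k-mer occurrence is emitted as an
``OffsetInfo`` (read id, signed coded offset).  Occurrences are grouped by
k-mer string and a group is kept only when shared by more than one and at most
``t`` distinct reads — singleton k-mers carry no overlap evidence and
over-abundant k-mers mark repeat regions hazardous for clustering.

Offset coding: a forward occurrence at 0-based offset ``o`` is coded ``o``;
an occurrence at offset ``o`` of the reverse-complemented read is coded
``-(o + 1)`` so strand is recoverable and offset 0 stays unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

from .io import Read, ReadSet, reverse_complement

__all__ = [
    "OffsetInfo",
    "KmerGroup",
    "KmerGroupSet",
    "map_kmers",
    "build_kmer_groups",
    "decode_offset",
]


class OffsetInfo(NamedTuple):
    seq_id: int
    coded_offset: int


def decode_offset(coded: int) -> tuple[int, int]:
    """Return ``(offset, strand)`` with strand +1 forward, -1 reverse."""
    if coded >= 0:
        return coded, 1
    return -coded - 1, -1


@dataclass
class KmerGroup:
    m_k: str
    members: list[OffsetInfo] = field(default_factory=list)

    def distinct_reads(self) -> int:
        return len({m.seq_id for m in self.members})


@dataclass
class KmerGroupSet:
    groups: dict[str, KmerGroup]
    k: int
    t: int

    def __len__(self) -> int:
        return len(self.groups)

    def get(self, kmer: str) -> KmerGroup | None:
        return self.groups.get(kmer)


def map_kmers(read: Read, k: int) -> list[tuple[str, OffsetInfo]]:
    """Emit ``(kmer, OffsetInfo)`` for every window of both strands.

    Windows containing ``N`` are skipped; reads shorter than ``k`` yield an
    empty list.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    seq = read.seq
    n = len(seq)
    out: list[tuple[str, OffsetInfo]] = []
    if n < k:
        return out
    for o in range(n - k + 1):
        win = seq[o : o + k]
        if "N" not in win:
            out.append((win, OffsetInfo(read.read_id, o)))
    rc = reverse_complement(seq)
    for o in range(n - k + 1):
        win = rc[o : o + k]
        if "N" not in win:
            out.append((win, OffsetInfo(read.read_id, -(o + 1))))
    return out


def build_kmer_groups(reads: ReadSet | Iterable[Read], k: int, t: int) -> KmerGroupSet:
    """Group k-mer occurrences across reads and apply the abundance filter.

    Keeps exactly the groups whose number of distinct reads ``c`` satisfies
    ``1 < c <= t``.  ``CountSeqs`` counts distinct reads, not occurrences: a
    read containing a k-mer twice, or on both strands, counts once.
    """
    if t < 2:
        raise ValueError("t must be >= 2 (1 < count <= t would be empty)")
    shuffled: dict[str, list[OffsetInfo]] = {}
    for read in reads:
        for kmer, info in map_kmers(read, k):
            shuffled.setdefault(kmer, []).append(info)
    groups: dict[str, KmerGroup] = {}
    for kmer, members in shuffled.items():
        c = len({m.seq_id for m in members})
        if 1 < c <= t:
            groups[kmer] = KmerGroup(m_k=kmer, members=members)
    return KmerGroupSet(groups=groups, k=k, t=t)
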