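"""Sequence I/O and strand utilities.

Reads are ingested from FASTA/FASTQ into a :class:`ReadSet`, with optional
mate-pair wiring (interleaved records or two parallel files).  Quality strings
are parsed but discarded: the assembler never uses them.  All coordinates are
0-based, half-open.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

from Bio import SeqIO

__all__ = [
    "Read",
    "ReadSet",
    "read_sequences",
    "write_fasta",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_VALID_BASES = frozenset("ACGTNn")


@dataclass
class Read:
    """One sequencing read.

    ``mate_id`` links the two ends of a pair (symmetric).  ``source_offset``
    and ``source_strand`` are ground truth populated only by the simulator.
    """

    read_id: int
    name: str
    seq: str
    mate_id: int | None = None
    source_offset: int | None = None
    source_strand: int | None = None

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class ReadSet:
    reads: list[Read] = field(default_factory=list)
    paired: bool = False
    insert_size: int | None = None

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self):
        return iter(self.reads)

    def __getitem__(self, read_id: int) -> Read:
        return self.reads[read_id]

    def validate(self) -> None:
        for i, r in enumerate(self.reads):
            if r.read_id != i:
                raise ValueError(f"read ids not dense: position {i} holds id {r.read_id}")
            if not r.seq:
                raise ValueError(f"read {i} has empty sequence")
            if r.mate_id is not None and self.reads[r.mate_id].mate_id != r.read_id:
                raise ValueError(f"asymmetric mate link at read {i}")
        if self.paired:
            if any(r.mate_id is None for r in self.reads):
                raise ValueError("paired ReadSet with unpaired reads")
            if self.insert_size is None:
                raise ValueError("paired ReadSet without insert_size")


def reverse_complement(seq: str) -> str:
    """Reverse complement of ``seq``; ``N``/``n`` map to themselves."""
    bad = set(seq) - _VALID_BASES
    if bad:
        raise ValueError(f"non-DNA characters in sequence: {sorted(bad)!r}")
    return seq.translate(_COMPLEMENT)[::-1]


def _parse_records(path: str, fmt: str):
    try:
        records = list(SeqIO.parse(path, fmt))
    except ValueError as exc:
        raise ValueError(f"malformed {fmt} in {path}: {exc}") from exc
    # Biopython tolerates some malformations lazily; force sequence access and
    # sanity-check record integrity here so errors name the record index.
    out = []
    for i, rec in enumerate(records):
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"record {i} in {path}: empty sequence")
        if fmt == "fastq":
            quals = rec.letter_annotations.get("phred_quality", [])
            if len(quals) != len(seq):
                raise ValueError(
                    f"record {i} in {path}: sequence/quality length mismatch"
                )
        out.append((rec.id, seq))
    return out


def read_sequences(
    path: str,
    format: str | None = None,
    pairing: str = "none",
    mate_path: str | None = None,
    insert_size: int | None = None,
) -> ReadSet:
    """Load reads from a FASTA/FASTQ file into a :class:`ReadSet`.

    Parameters
    ----------
    path
        Input file.  ``format`` is inferred from the extension when omitted.
    pairing
        ``none``, ``interleaved`` (records 2i and 2i+1 are mates) or
        ``two_files`` (i-th record of ``path`` and ``mate_path`` are mates).
    """
    if format is None:
        ext = os.path.splitext(path)[1].lower()
        format = "fastq" if ext in (".fastq", ".fq") else "fasta"
    if format not in ("fastq", "fasta"):
        raise ValueError(f"unsupported format {format!r}")
    if pairing not in ("none", "interleaved", "two_files"):
        raise ValueError(f"unknown pairing mode {pairing!r}")

    records = _parse_records(path, format)
    if pairing == "two_files":
        if mate_path is None:
            raise ValueError("pairing='two_files' requires mate_path")
        records2 = _parse_records(mate_path, format)
        if len(records) != len(records2):
            raise ValueError(
                f"two_files record counts differ: {len(records)} vs {len(records2)}"
            )
        # interleave so mates are adjacent, preserving pair order
        merged = []
        for a, b in zip(records, records2):
            merged.append(a)
            merged.append(b)
        records = merged
        pairing = "interleaved"

    reads = [Read(read_id=i, name=name, seq=seq) for i, (name, seq) in enumerate(records)]
    paired = False
    if pairing == "interleaved":
        if len(reads) % 2:
            raise ValueError("interleaved pairing with odd record count")
        for i in range(0, len(reads), 2):
            reads[i].mate_id = i + 1
            reads[i + 1].mate_id = i
        paired = True
    rs = ReadSet(reads=reads, paired=paired, insert_size=insert_size)
    rs.validate()
    return rs


def write_fasta(records, path: str, line_width: int = 70) -> None:
    """Write ``(name, sequence)`` pairs as wrapped multi-FASTA."""
    with open(path, "w") as fh:
        for name, seq in records:
            bad = set(seq) - _VALID_BASES
            if bad:
                raise ValueError(f"record {name!r}: non-DNA characters {sorted(bad)!r}")
            fh.write(f">{name}\n")
            for i in range(0, len(seq), line_width):
                fh.write(seq[i : i + line_width] + "\n")


def write_fastq(reads, path: str) -> None:
    """Write reads as 4-line FASTQ with uniform placeholder qualities."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.name}\n{r.seq}\n+\n{'I' * len(r.seq)}\n")
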