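"""Shotgun read simulation and assembly evaluation.

The simulator emulates a paired-end Illumina-like regime (about 100 bp
reads, short inserts, substitution errors only — seed alignment throughout
the assembler is gap-free, so indels are out of model).  Fragments are drawn
uniformly from a linear genome; each yields a forward read from the 5' end
and a reverse-complemented read from the 3' end.  Ground-truth offsets and
strands are recorded on the reads for evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np

from .io import Read, ReadSet, reverse_complement

__all__ = [
    "SimSpec",
    "simulate_genome",
    "simulate_reads",
    "n50",
    "evaluate_assembly",
    "AssemblyReport",
]

_BASES = np.array(list("ACGT"))


@dataclass
class SimSpec:
    """Simulation regime.

    Defaults mirror the benchmark regime the assembler targets: 101 bp
    paired reads with a 180 bp insert, at a desk-scale genome size.
    """

    genome_length: int = 10_000
    repeat_spec: list[tuple[int, int]] = field(default_factory=list)
    read_length: int = 101
    coverage: float = 30.0
    insert_size: int = 180
    insert_sd: int = 18
    error_rate: float = 0.0
    rng_seed: int = 0

    def __post_init__(self):
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        if self.read_length > self.genome_length:
            raise ValueError("read_length exceeds genome_length")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")


def simulate_genome(spec: SimSpec) -> tuple[str, list[tuple[int, int]]]:
    """I.i.d. uniform genome with optional exact repeats.

    Each ``(repeat_length, copies)`` entry copies one randomly placed
    template verbatim to additional non-overlapping positions.  Returns the
    sequence and the coordinates ``(start, end)`` of every repeat copy.
    """
    rng = np.random.default_rng(spec.rng_seed)
    G = spec.genome_length
    for rlen, copies in spec.repeat_spec:
        if rlen * copies > G:
            raise ValueError(f"repeat ({rlen} bp x {copies}) does not fit the genome")
    genome = rng.choice(_BASES, size=G)
    coords: list[tuple[int, int]] = []
    occupied: list[tuple[int, int]] = []

    def overlaps(s: int, e: int) -> bool:
        return any(s < oe and os_ < e for os_, oe in occupied)

    for rlen, copies in spec.repeat_spec:
        placed: list[int] = []
        for _ in range(copies):
            for _attempt in range(1000):
                s = int(rng.integers(0, G - rlen + 1))
                if not overlaps(s, s + rlen):
                    placed.append(s)
                    occupied.append((s, s + rlen))
                    break
            else:
                raise ValueError(
                    f"could not place {copies} non-overlapping copies of a "
                    f"{rlen} bp repeat in {G} bp"
                )
        template = genome[placed[0] : placed[0] + rlen].copy()
        for s in placed:
            genome[s : s + rlen] = template
            coords.append((s, s + rlen))
    return "".join(genome), coords


def simulate_reads(genome: str, spec: SimSpec) -> ReadSet:
    """Paired-end shotgun reads with substitution errors.

    N = ceil(coverage * genome_length / (2 * read_length)) fragments with
    length ~ Normal(insert_size, insert_sd), truncated to at least
    read_length; deterministic under ``spec.rng_seed``.
    """
    rng = np.random.default_rng(spec.rng_seed + 1)
    G = len(genome)
    rl = spec.read_length
    n_frag = int(np.ceil(spec.coverage * G / (2 * rl)))
    reads: list[Read] = []
    arr = np.frombuffer(genome.encode(), dtype="S1")

    def add_errors(seq: str) -> str:
        if spec.error_rate == 0:
            return seq
        hits = np.nonzero(rng.random(len(seq)) < spec.error_rate)[0]
        if len(hits) == 0:
            return seq
        out = list(seq)
        for i in hits:
            alts = [b for b in "ACGT" if b != out[i]]
            out[i] = alts[int(rng.integers(3))]
        return "".join(out)

    for i in range(n_frag):
        flen = int(round(rng.normal(spec.insert_size, spec.insert_sd)))
        flen = max(rl, min(flen, G))
        pos = int(rng.integers(0, G - flen + 1))
        fwd = genome[pos : pos + rl]
        rev_start = pos + flen - rl
        rev = reverse_complement(genome[rev_start : rev_start + rl])
        r1 = Read(
            read_id=2 * i,
            name=f"frag{i}/1",
            seq=add_errors(fwd),
            mate_id=2 * i + 1,
            source_offset=pos,
            source_strand=1,
        )
        r2 = Read(
            read_id=2 * i + 1,
            name=f"frag{i}/2",
            seq=add_errors(rev),
            mate_id=2 * i,
            source_offset=rev_start,
            source_strand=-1,
        )
        reads.extend((r1, r2))
    return ReadSet(reads=reads, paired=True, insert_size=spec.insert_size)


def n50(lengths) -> int:
    """Largest L such that pieces of length >= L hold half the total."""
    lengths = sorted(lengths, reverse=True)
    if not lengths:
        raise ValueError("n50 of an empty length list is undefined")
    if any(x <= 0 for x in lengths):
        raise ValueError("lengths must be positive")
    half = sum(lengths) / 2
    acc = 0
    for x in lengths:
        acc += x
        if acc >= half:
            return x
    return lengths[-1]


@dataclass
class AssemblyReport:
    genome_fraction: float  # percent of genome bases covered by placed contigs
    mismatches_per_kb: float
    contig_count: int
    n50: int
    total_bp: int
    unplaced: int = 0


def evaluate_assembly(contigs, genome: str) -> AssemblyReport:
    """Locate each contig in the ground-truth genome and summarize.

    Exact substring search on both strands first; otherwise the best
    semi-global alignment (substitutions and indels counted as mismatches).
    Genome fraction is the percentage of genome bases covered by at least
    one placed contig.
    """
    seqs = [c.seq if hasattr(c, "seq") else c for c in contigs]
    if not seqs:
        return AssemblyReport(0.0, 0.0, 0, 0, 0)
    G = len(genome)
    rc_genome = reverse_complement(genome)
    covered = np.zeros(G, dtype=bool)
    total_mismatch = 0
    aligned_bp = 0
    unplaced = 0
    for seq in seqs:
        pos = genome.find(seq)
        if pos >= 0:
            covered[pos : pos + len(seq)] = True
            aligned_bp += len(seq)
            continue
        pos = rc_genome.find(seq)
        if pos >= 0:
            s = G - pos - len(seq)
            covered[s : s + len(seq)] = True
            aligned_bp += len(seq)
            continue
        best = None
        for target_rc, target in ((False, genome), (True, rc_genome)):
            res = edlib.align(seq, target, mode="HW", task="locations")
            if res["editDistance"] >= 0 and (
                best is None or res["editDistance"] < best[0]
            ):
                best = (res["editDistance"], res["locations"][0], target_rc)
        if best is None or best[0] > 0.2 * len(seq):
            unplaced += 1
            continue
        ed, (s, e), was_rc = best
        e += 1
        if was_rc:
            s, e = G - e, G - s
        covered[s:e] = True
        aligned_bp += len(seq)
        total_mismatch += ed
    frac = 100.0 * covered.sum() / G
    mpk = 1000.0 * total_mismatch / aligned_bp if aligned_bp else 0.0
    return AssemblyReport(
        genome_fraction=float(frac),
        mismatches_per_kb=float(mpk),
        contig_count=len(seqs),
        n50=n50([len(s) for s in seqs]),
        total_bp=sum(len(s) for s in seqs),
        unplaced=unplaced,
    )
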