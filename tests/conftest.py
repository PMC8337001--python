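"""Shared fixtures and independent brute-force oracles.

The oracles here enumerate position sets one nucleotide at a time with
modular wrap; they are deliberately naive and independent of the package
implementation they check.
"""

from __future__ import annotations

import numpy as np
import pytest

from riboprof.core import (
    AlignedRead,
    GenomeSequence,
    GenomicInterval,
    Orf,
)


# ------------------------------------------------------------------ oracles

def position_set(start: int, end: int, length: int) -> set[int]:
    """Wrapped positions covered by an unwrapped [start, end) interval."""
    return {p % length for p in range(start, end)}


def oracle_overlap(a: GenomicInterval, b: GenomicInterval, length: int) -> bool:
    return bool(position_set(a.start, a.end, length) & position_set(b.start, b.end, length))


def oracle_coverage(reads, genome: GenomeSequence, mode: str, strand: str) -> np.ndarray:
    """Per-position coverage by stepping every read one nucleotide at a time."""
    values = np.zeros(genome.length)
    for read in reads:
        iv = read.interval
        if iv.contig_id != genome.contig_id or iv.strand != strand:
            continue
        if mode == "full":
            for p in range(iv.start, iv.end):
                values[p % genome.length] += 1
        else:
            positions = [p % genome.length for p in range(iv.start, iv.end)]
            if iv.strand == "-":
                positions = positions[::-1]  # reading direction 5'->3'
            if mode == "fiveprime":
                anchor = positions[0]
            elif mode == "threeprime":
                anchor = positions[-1]
            else:  # center: left of the two central candidates
                anchor = positions[(len(positions) - 1) // 2]
            values[anchor] += 1
    return values


def oracle_anchor(read: AlignedRead, mode: str, length: int) -> int:
    track = oracle_coverage([read], GenomeSequence(read.interval.contig_id, "A" * length, circular=True), mode, read.interval.strand)
    (pos,) = np.nonzero(track)[0]
    return int(pos)


def oracle_metagene_mass(reads, starts, genomes, up: int, down: int, lengths) -> int:
    """Number of (read, window) incidence pairs by testing every pair."""
    from riboprof.coverage import anchor_position

    lengths = set(lengths)
    total = 0
    for read in reads:
        if read.read_length not in lengths:
            continue
        genome = genomes[read.interval.contig_id]
        anchor = anchor_position(read, "fiveprime", genome)
        for site in starts:
            if site.contig_id != read.interval.contig_id or site.strand != read.interval.strand:
                continue
            window = []
            if site.strand == "+":
                window = [site.position + o for o in range(-up, down)]
            else:
                window = [site.position - o for o in range(-up, down)]
            if genome.circular:
                window = [p % genome.length for p in window]
            if anchor in window:
                total += 1
    return total


# ----------------------------------------------------------------- fixtures

@pytest.fixture
def circular10() -> GenomeSequence:
    return GenomeSequence("c", "ATGAAATAGC", circular=True)


@pytest.fixture
def linear10() -> GenomeSequence:
    return GenomeSequence("l", "ATGAAATAGC", circular=False)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def make_read(contig: str, start: int, end: int, strand: str = "+", hit_count: int = 1) -> AlignedRead:
    iv = GenomicInterval(contig, start, end, strand)
    return AlignedRead(iv, iv.length, hit_count)


def make_orf(orf_id: str, contig: str, start: int, end: int, strand: str = "+",
             feature_type: str = "CDS", source: str = "annotation", **attrs) -> Orf:
    return Orf(orf_id, GenomicInterval(contig, start, end, strand), source, feature_type, dict(attrs))


def random_reads(rng: np.random.Generator, genome: GenomeSequence, n: int,
                 max_len: int = 10, allow_multimap: bool = False) -> list[AlignedRead]:
    """Random reads on one contig; may span the origin when circular."""
    reads = []
    for _ in range(n):
        rl = int(rng.integers(1, min(max_len, genome.length) + 1))
        if genome.circular:
            start = int(rng.integers(0, genome.length))
        else:
            start = int(rng.integers(0, genome.length - rl + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        hit = 1
        if allow_multimap and rng.random() < 0.3:
            hit = int(rng.integers(2, 5))
        reads.append(make_read(genome.contig_id, start, start + rl, strand, hit))
    return reads
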