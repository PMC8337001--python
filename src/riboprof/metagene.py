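"""Metagene profiling of read density around annotated start codons.

Reads are anchored to a single nucleotide (5' end by default) and
aggregated over all start-codon windows, stratified by read length.
Offset 0 is the first nucleotide of the start codon; negative offsets are
upstream.  A per-frame summary over the coding-side window quantifies
three-nucleotide periodicity.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import AlignedRead, GenomeSequence, Orf, require_genome
from .coverage import anchor_position

DEFAULT_UPSTREAM = 50
DEFAULT_DOWNSTREAM = 50
DEFAULT_READ_LENGTHS = range(20, 46)

__all__ = [
    "MetageneProfile",
    "StartSite",
    "collect_start_positions",
    "metagene_profile",
    "frame_summary",
    "write_profile",
    "write_frame_summary",
]


@dataclass(frozen=True)
class StartSite:
    contig_id: str
    strand: str
    position: int  # first nucleotide of the start codon, wrapped


@dataclass
class MetageneProfile:
    window_upstream: int
    window_downstream: int
    read_lengths: list[int]
    counts: np.ndarray  # shape (len(read_lengths), upstream + downstream)
    n_genes: int

    def __post_init__(self) -> None:
        expected = (len(self.read_lengths), self.window_upstream + self.window_downstream)
        if self.counts.shape != expected:
            raise ValueError(
                f"counts shape {self.counts.shape} != expected {expected}"
            )
        if np.any(self.counts < 0) or self.n_genes < 0:
            raise ValueError("counts and n_genes must be non-negative")

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(-self.window_upstream, self.window_downstream)

    def total(self) -> float:
        return float(self.counts.sum())

    def to_dataframe(self, normalized: bool = False) -> pd.DataFrame:
        """Rows = read length, columns = offset.

        With ``normalized=True`` each read-length row is scaled to sum 1
        (zero rows stay zero) for cross-length comparison.
        """
        counts = self.counts.astype(float)
        if normalized:
            sums = counts.sum(axis=1, keepdims=True)
            with np.errstate(invalid="ignore", divide="ignore"):
                counts = np.where(sums > 0, counts / sums, 0.0)
        return pd.DataFrame(counts, index=self.read_lengths, columns=self.offsets)


def collect_start_positions(
    annotation: Iterable[Orf],
    genomes: dict[str, GenomeSequence],
    window_upstream: int = DEFAULT_UPSTREAM,
    window_downstream: int = DEFAULT_DOWNSTREAM,
    feature_types: Sequence[str] = ("CDS",),
) -> tuple[list[StartSite], int]:
    """Start-codon first-nucleotide positions for profiling.

    Genes whose full window would cross the edge of a linear contig are
    excluded; the second return value counts them.  Windows wrap on
    circular contigs.
    """
    wanted = set(feature_types)
    starts: list[StartSite] = []
    n_excluded = 0
    for orf in annotation:
        if orf.feature_type not in wanted:
            continue
        iv = orf.interval
        genome = require_genome(genomes, iv.contig_id)
        length = genome.length
        pos = iv.start if iv.strand == "+" else iv.end - 1
        pos %= length
        if not genome.circular:
            if iv.strand == "+":
                fits = pos - window_upstream >= 0 and pos + window_downstream <= length
            else:
                fits = pos + window_upstream < length and pos - window_downstream + 1 >= 0
            if not fits:
                n_excluded += 1
                continue
        starts.append(StartSite(iv.contig_id, iv.strand, pos))
    return starts, n_excluded


def _window_offset(
    anchor: int,
    start: StartSite,
    genome: GenomeSequence,
    window_upstream: int,
    window_downstream: int,
) -> int | None:
    """Signed offset of anchor relative to the start codon, or None if outside."""
    if start.strand == "+":
        d = anchor - start.position
    else:
        d = start.position - anchor
    if genome.circular:
        d %= genome.length
        if d < window_downstream:
            return d
        if d >= genome.length - window_upstream:
            return d - genome.length
        return None
    if -window_upstream <= d < window_downstream:
        return d
    return None


def metagene_profile(
    reads: Sequence[AlignedRead],
    starts: Sequence[StartSite],
    genomes: dict[str, GenomeSequence],
    window_upstream: int = DEFAULT_UPSTREAM,
    window_downstream: int = DEFAULT_DOWNSTREAM,
    read_lengths: Iterable[int] = DEFAULT_READ_LENGTHS,
    anchor_mode: str = "fiveprime",
) -> MetageneProfile:
    """Aggregate anchored read density over all start-codon windows.

    A read landing in k overlapping windows (matching strand) contributes
    k increments.
    """
    lengths = sorted(set(read_lengths))
    row_of = {length: i for i, length in enumerate(lengths)}
    counts = np.zeros((len(lengths), window_upstream + window_downstream))
    for read in reads:
        row = row_of.get(read.read_length)
        if row is None:
            continue
        genome = require_genome(genomes, read.interval.contig_id)
        anchor = anchor_position(read, anchor_mode, genome)
        for start in starts:
            if (
                start.contig_id != read.interval.contig_id
                or start.strand != read.interval.strand
            ):
                continue
            offset = _window_offset(
                anchor, start, genome, window_upstream, window_downstream
            )
            if offset is not None:
                counts[row, offset + window_upstream] += 1
    return MetageneProfile(
        window_upstream=window_upstream,
        window_downstream=window_downstream,
        read_lengths=lengths,
        counts=counts,
        n_genes=len(starts),
    )


def frame_summary(profile: MetageneProfile) -> pd.DataFrame:
    """Per-read-length fraction of coding-side signal in each frame.

    Sums counts at offsets 0..window_downstream-1 grouped by offset mod 3
    and normalizes to fractions; zero-signal rows are all zero.
    """
    down = profile.counts[:, profile.window_upstream :]
    frames = np.zeros((len(profile.read_lengths), 3))
    for frame in range(3):
        frames[:, frame] = down[:, frame::3].sum(axis=1)
    totals = frames.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        fractions = np.where(totals > 0, frames / totals, 0.0)
    return pd.DataFrame(
        fractions,
        index=profile.read_lengths,
        columns=["frame_0", "frame_1", "frame_2"],
    )


def write_profile(profile: MetageneProfile, path: str | Path, normalized: bool = False) -> None:
    df = profile.to_dataframe(normalized=normalized)
    df.index.name = "read_length"
    df.to_csv(path, sep="\t")


def write_frame_summary(profile: MetageneProfile, path: str | Path) -> None:
    df = frame_summary(profile)
    df.index.name = "read_length"
    df.to_csv(path, sep="\t")
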