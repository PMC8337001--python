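"""Strand-specific per-nucleotide coverage tracks.

Four mapping modes: ``full`` increments every covered position;
``fiveprime``/``threeprime``/``center`` increment a single anchor
nucleotide per read.  Tracks wrap around the origin on circular contigs.
Output formats are text wiggle (1-based variableStep) and bedGraph
(0-based half-open, run-length collapsed).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .core import (
    AlignedRead,
    CoordinateError,
    EmptyLibraryError,
    GenomeSequence,
    normalize_coordinate,
)

MODES = ("full", "fiveprime", "threeprime", "center")
SINGLE_NT_MODES = ("fiveprime", "threeprime", "center")
NORMALIZATIONS = ("raw", "cpm")

__all__ = [
    "MODES",
    "SINGLE_NT_MODES",
    "CoverageTrack",
    "anchor_position",
    "compute_coverage",
    "normalize_cpm",
    "write_wiggle",
    "read_wiggle",
    "write_bedgraph",
    "read_bedgraph",
]


@dataclass(frozen=True)
class CoverageTrack:
    contig_id: str
    strand: str
    mode: str
    normalization: str
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.normalization not in NORMALIZATIONS:
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if np.any(self.values < 0):
            raise ValueError("coverage values must be non-negative")


def anchor_position(read: AlignedRead, mode: str, genome: GenomeSequence) -> int:
    """Single-nucleotide anchor of a read under the given mapping mode.

    The center of an even-length read is the left of the two central
    positions.  The result is wrapped on circular contigs.
    """
    iv = read.interval
    if mode == "fiveprime":
        pos = iv.start if iv.strand == "+" else iv.end - 1
    elif mode == "threeprime":
        pos = iv.end - 1 if iv.strand == "+" else iv.start
    elif mode == "center":
        offset = (read.read_length - 1) // 2
        pos = iv.start + offset if iv.strand == "+" else iv.end - 1 - offset
    else:
        raise ValueError(f"mode {mode!r} has no anchor position")
    return normalize_coordinate(pos, genome)


def compute_coverage(
    reads: Sequence[AlignedRead],
    genome: GenomeSequence,
    mode: str,
    strand: str,
) -> CoverageTrack:
    """Raw coverage for reads on one contig/strand in one mapping mode."""
    values = np.zeros(genome.length, dtype=float)
    length = genome.length
    for read in reads:
        iv = read.interval
        if iv.contig_id != genome.contig_id or iv.strand != strand:
            continue
        if iv.end > length and not genome.circular:
            raise CoordinateError(
                f"read [{iv.start}, {iv.end}) off linear contig "
                f"{genome.contig_id!r} (length {length})"
            )
        if mode == "full":
            if iv.end <= length:
                values[iv.start : iv.end] += 1
            else:
                values[iv.start :] += 1
                values[: iv.end - length] += 1
        else:
            values[anchor_position(read, mode, genome)] += 1
    return CoverageTrack(genome.contig_id, strand, mode, "raw", values)


def normalize_cpm(track: CoverageTrack, library_size: int) -> CoverageTrack:
    """Scale a raw track to counts-per-million of retained library reads."""
    if library_size <= 0:
        raise EmptyLibraryError("cannot CPM-normalize with library size 0")
    return replace(
        track, values=track.values * (1e6 / library_size), normalization="cpm"
    )


def _fmt(value: float) -> str:
    v = float(value)
    return str(int(v)) if v.is_integer() else repr(v)


def write_wiggle(track: CoverageTrack, path: str | Path) -> None:
    """variableStep wiggle; positions 1-based, zero positions omitted."""
    try:
        with open(path, "w") as handle:
            handle.write(
                f"track type=wiggle_0 name={track.contig_id}_{track.strand}"
                f"_{track.mode}_{track.normalization}\n"
            )
            handle.write(f"variableStep chrom={track.contig_id}\n")
            for pos, value in enumerate(track.values):
                if value != 0:
                    handle.write(f"{pos + 1} {_fmt(value)}\n")
    except OSError as exc:
        raise OSError(f"failed writing wiggle to {path}: {exc}") from exc


def read_wiggle(path: str | Path, contig_length: int) -> np.ndarray:
    values = np.zeros(contig_length, dtype=float)
    with open(path) as handle:
        for line in handle:
            if line.startswith(("track", "variableStep", "fixedStep", "#")):
                continue
            pos_s, val_s = line.split()
            values[int(pos_s) - 1] = float(val_s)
    return values


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    """0-based half-open bedGraph with equal-value runs collapsed; zero runs omitted."""
    values = track.values
    try:
        with open(path, "w") as handle:
            handle.write(
                f"track type=bedGraph name={track.contig_id}_{track.strand}"
                f"_{track.mode}_{track.normalization}\n"
            )
            start = 0
            for pos in range(1, len(values) + 1):
                if pos == len(values) or values[pos] != values[start]:
                    if values[start] != 0:
                        handle.write(
                            f"{track.contig_id}\t{start}\t{pos}\t{_fmt(values[start])}\n"
                        )
                    start = pos
    except OSError as exc:
        raise OSError(f"failed writing bedGraph to {path}: {exc}") from exc


def read_bedgraph(path: str | Path, contig_length: int) -> np.ndarray:
    values = np.zeros(contig_length, dtype=float)
    with open(path) as handle:
        for line in handle:
            if line.startswith(("track", "#")) or not line.strip():
                continue
            _contig, start_s, end_s, val_s = line.split("\t")
            values[int(start_s) : int(end_s)] = float(val_s)
    return values
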