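"""Domain types and coordinate arithmetic shared by every stage.

All internal coordinates are 0-based, half-open.  Features on circular
contigs that cross the origin are stored *unwrapped*: ``start`` lies in
``[0, length)`` and ``end`` may exceed the contig length, so interval
length arithmetic stays trivial.  Conversions to 1-based conventions
(GFF3, wiggle) happen only at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

__all__ = [
    "CoordinateError",
    "ParseError",
    "SampleSheetError",
    "EmptyLibraryError",
    "MalformedOrfError",
    "GenomeSequence",
    "GenomicInterval",
    "AlignedRead",
    "Orf",
    "Sample",
    "SampleSheet",
    "reverse_complement",
    "normalize_coordinate",
    "unwrap_interval",
    "interval_positions",
    "wrapped_segments",
    "intervals_overlap",
    "extract_sequence",
    "five_prime",
    "three_prime",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class CoordinateError(ValueError):
    """A genomic position or interval is invalid for its contig."""


class ParseError(ValueError):
    """A standard-format file failed to parse."""


class SampleSheetError(ValueError):
    """The sample sheet violates its structural contract."""


class EmptyLibraryError(ValueError):
    """An operation requiring reads was given a zero-read library."""


class MalformedOrfError(ValueError):
    """An ORF violates minimal structural requirements."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeSequence:
    """A named contig: nucleotide string plus a circularity flag."""

    contig_id: str
    sequence: str
    circular: bool = False

    def __post_init__(self) -> None:
        if not self.contig_id:
            raise ValueError("contig_id must be non-empty")
        if not self.sequence:
            raise ValueError(f"contig {self.contig_id!r} has empty sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval; unwrapped on circular contigs.

    ``start`` is always in ``[0, contig length)`` for valid intervals;
    ``end > contig length`` marks an origin-spanning feature.
    """

    contig_id: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.start < 0:
            raise CoordinateError(
                f"interval start {self.start} < 0 on {self.contig_id!r}"
            )
        if self.end <= self.start:
            raise CoordinateError(
                f"empty or inverted interval [{self.start}, {self.end}) "
                f"on {self.contig_id!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def flipped(self) -> "GenomicInterval":
        return GenomicInterval(
            self.contig_id, self.start, self.end, "-" if self.strand == "+" else "+"
        )


@dataclass(frozen=True)
class AlignedRead:
    """One mapped read, treated as an ungapped block on the reference."""

    interval: GenomicInterval
    read_length: int
    hit_count: int = 1

    def __post_init__(self) -> None:
        if self.read_length != self.interval.length:
            raise ValueError(
                f"read_length {self.read_length} != interval length "
                f"{self.interval.length}"
            )
        if self.hit_count < 1:
            raise ValueError("hit_count must be >= 1")


@dataclass
class Orf:
    """An annotated or predicted feature; usually a CDS-like ORF."""

    orf_id: str
    interval: GenomicInterval
    source: str = "annotation"
    feature_type: str = "CDS"
    attributes: dict = field(default_factory=dict)

    @property
    def length_nt(self) -> int:
        return self.interval.length


@dataclass(frozen=True)
class Sample:
    library_id: str
    method: str  # RIBO | RNA
    condition: str
    replicate: int
    path: str


@dataclass
class SampleSheet:
    samples: list[Sample]

    def __post_init__(self) -> None:
        seen: set[tuple[str, str, int]] = set()
        for s in self.samples:
            if s.method not in ("RIBO", "RNA"):
                raise SampleSheetError(
                    f"library {s.library_id!r}: method must be RIBO or RNA, "
                    f"got {s.method!r}"
                )
            if s.replicate < 1:
                raise SampleSheetError(
                    f"library {s.library_id!r}: replicate must be >= 1"
                )
            key = (s.method, s.condition, s.replicate)
            if key in seen:
                raise SampleSheetError(f"duplicate (method, condition, replicate) {key}")
            seen.add(key)

    @property
    def conditions(self) -> list[str]:
        out: list[str] = []
        for s in self.samples:
            if s.condition not in out:
                out.append(s.condition)
        return out

    def libraries(self, method: str | None = None, condition: str | None = None) -> list[Sample]:
        return [
            s
            for s in self.samples
            if (method is None or s.method == method)
            and (condition is None or s.condition == condition)
        ]

    def validate_te_support(self) -> None:
        """Every condition with a RIBO library must also carry an RNA library."""
        for cond in self.conditions:
            if self.libraries("RIBO", cond) and not self.libraries("RNA", cond):
                raise SampleSheetError(
                    f"condition {cond!r} has RIBO libraries but no RNA library"
                )


def normalize_coordinate(pos: int, genome: GenomeSequence) -> int:
    """Map ``pos`` into ``[0, length)``: modular on circular contigs."""
    if genome.circular:
        return pos % genome.length
    if 0 <= pos < genome.length:
        return pos
    raise CoordinateError(
        f"position {pos} outside linear contig {genome.contig_id!r} "
        f"(length {genome.length})"
    )


def unwrap_interval(start: int, end: int, strand: str, genome: GenomeSequence) -> GenomicInterval:
    """Canonicalize possibly-wrapped or negative coordinates.

    On circular contigs a record with ``end <= start`` (or negative
    coordinates) denotes an origin-spanning feature; the result has
    ``start`` in ``[0, length)`` and ``end > length`` exactly in that case.
    """
    length = genome.length
    if not genome.circular:
        if end <= start:
            raise ParseError(
                f"malformed annotation on linear contig {genome.contig_id!r}: "
                f"end {end} <= start {start}"
            )
        if start < 0 or end > length:
            raise CoordinateError(
                f"interval [{start}, {end}) outside linear contig "
                f"{genome.contig_id!r} (length {length})"
            )
        return GenomicInterval(genome.contig_id, start, end, strand)
    span = end - start
    if span <= 0:
        span = span % length
        if span == 0:
            # span 0 mod L is ambiguous; non-empty invariant forces full circle
            span = length
    if span > length:
        raise CoordinateError(
            f"interval span {span} exceeds circular contig "
            f"{genome.contig_id!r} length {length}"
        )
    s = start % length
    return GenomicInterval(genome.contig_id, s, s + span, strand)


def interval_positions(interval: GenomicInterval, genome: GenomeSequence) -> Iterator[int]:
    """Yield the wrapped genomic positions covered by ``interval`` in order."""
    length = genome.length
    if interval.end > length and not genome.circular:
        raise CoordinateError(
            f"interval [{interval.start}, {interval.end}) exceeds linear contig "
            f"{genome.contig_id!r} (length {length})"
        )
    for p in range(interval.start, interval.end):
        yield p % length


def wrapped_segments(interval: GenomicInterval, genome: GenomeSequence) -> list[tuple[int, int]]:
    """Decompose an interval into at most two linear [start, end) pieces."""
    length = genome.length
    if interval.end <= length:
        return [(interval.start, interval.end)]
    if not genome.circular:
        raise CoordinateError(
            f"interval [{interval.start}, {interval.end}) exceeds linear contig "
            f"{genome.contig_id!r} (length {length})"
        )
    return [(interval.start, length), (0, interval.end - length)]


def intervals_overlap(
    a: GenomicInterval,
    b: GenomicInterval,
    genome: GenomeSequence,
    stranded: bool = False,
) -> bool:
    """True iff the wrapped position sets of ``a`` and ``b`` intersect."""
    if a.contig_id != b.contig_id:
        return False
    if stranded and a.strand != b.strand:
        return False
    for s1, e1 in wrapped_segments(a, genome):
        for s2, e2 in wrapped_segments(b, genome):
            if s1 < e2 and s2 < e1:
                return True
    return False


def extract_sequence(interval: GenomicInterval, genome: GenomeSequence) -> str:
    """Extract the interval's nucleotide sequence in reading direction.

    Wraps around the origin on circular contigs; reverse-complements for
    minus-strand intervals.  Result length equals the interval length.
    """
    if interval.contig_id != genome.contig_id:
        raise CoordinateError(
            f"interval contig {interval.contig_id!r} != genome "
            f"{genome.contig_id!r}"
        )
    length = genome.length
    if interval.end <= length:
        sub = genome.sequence[interval.start : interval.end]
    else:
        if not genome.circular:
            raise CoordinateError(
                f"interval [{interval.start}, {interval.end}) exceeds linear "
                f"contig {genome.contig_id!r} (length {length})"
            )
        sub = genome.sequence[interval.start :] + genome.sequence[: interval.end - length]
    if interval.strand == "-":
        sub = reverse_complement(sub)
    return sub


def five_prime(interval: GenomicInterval) -> int:
    """Unwrapped coordinate of the biological 5' end."""
    return interval.start if interval.strand == "+" else interval.end - 1


def three_prime(interval: GenomicInterval) -> int:
    """Unwrapped coordinate of the biological 3' end."""
    return interval.end - 1 if interval.strand == "+" else interval.start


GenomeSet = Mapping[str, GenomeSequence]


def require_genome(genomes: GenomeSet, contig_id: str) -> GenomeSequence:
    try:
        return genomes[contig_id]
    except KeyError:
        raise CoordinateError(f"unknown contig {contig_id!r}") from None
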