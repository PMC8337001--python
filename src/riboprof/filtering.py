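"""Pre-analysis read filtering: multimapped and rRNA-overlapping reads."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .core import (
    AlignedRead,
    GenomeSequence,
    Orf,
    intervals_overlap,
    require_genome,
)

__all__ = ["FilterReport", "filter_multimapped", "filter_rrna", "filter_reads"]


@dataclass(frozen=True)
class FilterReport:
    input_reads: int
    removed_multimapped: int
    removed_rrna: int

    @property
    def retained(self) -> int:
        return self.input_reads - self.removed_multimapped - self.removed_rrna

    def __post_init__(self) -> None:
        for name in ("input_reads", "removed_multimapped", "removed_rrna"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.retained < 0:
            raise ValueError("removed counts exceed input reads")


def filter_multimapped(reads: Sequence[AlignedRead]) -> tuple[list[AlignedRead], int]:
    """Drop reads reported at more than one genomic location."""
    retained = [r for r in reads if r.hit_count == 1]
    return retained, len(reads) - len(retained)


def filter_rrna(
    reads: Sequence[AlignedRead],
    rrna_features: Iterable[Orf],
    genomes: dict[str, GenomeSequence],
) -> tuple[list[AlignedRead], int]:
    """Drop reads overlapping any rRNA-class feature by >= 1 nt.

    Overlap is strand-agnostic; wrapped position sets are used on
    circular contigs.
    """
    features = list(rrna_features)
    for feat in features:
        require_genome(genomes, feat.interval.contig_id)
    retained = []
    for read in reads:
        genome = require_genome(genomes, read.interval.contig_id)
        hit = any(
            intervals_overlap(read.interval, feat.interval, genome, stranded=False)
            for feat in features
            if feat.interval.contig_id == read.interval.contig_id
        )
        if not hit:
            retained.append(read)
    return retained, len(reads) - len(retained)


def filter_reads(
    reads: Sequence[AlignedRead],
    rrna_features: Iterable[Orf],
    genomes: dict[str, GenomeSequence],
) -> tuple[list[AlignedRead], FilterReport]:
    """Multimapper removal followed by rRNA removal, with a count report."""
    after_mm, n_mm = filter_multimapped(reads)
    after_rrna, n_rrna = filter_rrna(after_mm, rrna_features, genomes)
    report = FilterReport(
        input_reads=len(reads), removed_multimapped=n_mm, removed_rrna=n_rrna
    )
    assert report.retained == len(after_rrna)
    return after_rrna, report


def select_rrna_features(annotation: Iterable[Orf], types: Sequence[str]) -> list[Orf]:
    wanted = set(types)
    return [orf for orf in annotation if orf.feature_type in wanted]
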