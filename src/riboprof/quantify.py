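"""Per-ORF read counting, RPKM/TPM normalization and translation efficiency.

Counting is strand-specific with >= 1 nt overlap; a read overlapping two
or more ORFs is discarded as ambiguous (tracked in a diagnostic), so
assigned + ambiguous + unassigned always equals the retained read count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    AlignedRead,
    EmptyLibraryError,
    GenomeSequence,
    SampleSheet,
    SampleSheetError,
    intervals_overlap,
    require_genome,
)
from .merge import MergedOrf

__all__ = [
    "CountResult",
    "count_reads",
    "rpkm",
    "tpm",
    "translation_efficiency",
    "build_count_matrix",
    "rpkm_matrix",
    "tpm_matrix",
    "te_table",
]


@dataclass
class CountResult:
    counts: dict[str, int]
    ambiguous: int
    unassigned: int

    @property
    def assigned(self) -> int:
        return sum(self.counts.values())

    @property
    def total(self) -> int:
        return self.assigned + self.ambiguous + self.unassigned


def count_reads(
    reads: Sequence[AlignedRead],
    orfs: Sequence[MergedOrf],
    genomes: dict[str, GenomeSequence],
) -> CountResult:
    """Assign each read to exactly one ORF, or to ambiguous/unassigned."""
    counts = {rec.orf.orf_id: 0 for rec in orfs}
    by_contig: dict[str, list[MergedOrf]] = {}
    for rec in orfs:
        by_contig.setdefault(rec.orf.interval.contig_id, []).append(rec)
    ambiguous = unassigned = 0
    for read in reads:
        genome = require_genome(genomes, read.interval.contig_id)
        hits = [
            rec.orf.orf_id
            for rec in by_contig.get(read.interval.contig_id, [])
            if intervals_overlap(read.interval, rec.orf.interval, genome, stranded=True)
        ]
        if len(hits) == 1:
            counts[hits[0]] += 1
        elif len(hits) > 1:
            ambiguous += 1
        else:
            unassigned += 1
    return CountResult(counts=counts, ambiguous=ambiguous, unassigned=unassigned)


def rpkm(count: float, orf_length_nt: int, library_size: int) -> float:
    """Reads per kilobase per million mapped (retained) reads."""
    if orf_length_nt <= 0:
        raise ValueError("orf_length_nt must be > 0")
    if library_size <= 0:
        raise EmptyLibraryError("cannot compute RPKM with library size 0")
    return count * 1e9 / (orf_length_nt * library_size)


def tpm(counts: Sequence[float], lengths: Sequence[int]) -> np.ndarray:
    """Transcripts per million: length-normalized rates scaled to 1e6 total."""
    counts_arr = np.asarray(counts, dtype=float)
    lengths_arr = np.asarray(lengths, dtype=float)
    if np.any(lengths_arr <= 0):
        raise ValueError("all lengths must be > 0")
    rates = counts_arr / lengths_arr
    total = rates.sum()
    if total == 0:
        return np.zeros_like(rates)
    return rates * 1e6 / total


def translation_efficiency(
    rpkm_ribo: Sequence[float], rpkm_rna: Sequence[float]
) -> float | None:
    """mean(RIBO RPKM) / mean(RNA RPKM); None (NA) when RNA mean is 0."""
    if len(rpkm_ribo) == 0 or len(rpkm_rna) == 0:
        raise SampleSheetError("translation efficiency requires both RIBO and RNA replicates")
    mean_rna = float(np.mean(rpkm_rna))
    if mean_rna == 0:
        return None
    return float(np.mean(rpkm_ribo)) / mean_rna


def build_count_matrix(
    reads_by_library: Mapping[str, Sequence[AlignedRead]],
    orfs: Sequence[MergedOrf],
    genomes: dict[str, GenomeSequence],
) -> tuple[pd.DataFrame, dict[str, int], pd.DataFrame]:
    """Raw count matrix (rows ORFs, columns libraries) plus diagnostics.

    Returns (counts, library_sizes, diagnostics) where library sizes are
    retained read counts and diagnostics holds per-library
    assigned/ambiguous/unassigned totals.
    """
    orf_ids = [rec.orf.orf_id for rec in orfs]
    data: dict[str, list[int]] = {}
    library_sizes: dict[str, int] = {}
    diag_rows = []
    for library_id, reads in reads_by_library.items():
        result = count_reads(reads, orfs, genomes)
        data[library_id] = [result.counts[orf_id] for orf_id in orf_ids]
        library_sizes[library_id] = len(reads)
        diag_rows.append(
            {
                "library_id": library_id,
                "assigned": result.assigned,
                "ambiguous": result.ambiguous,
                "unassigned": result.unassigned,
                "retained": len(reads),
            }
        )
    counts_df = pd.DataFrame(data, index=pd.Index(orf_ids, name="orf_id"))
    diagnostics = pd.DataFrame(
        diag_rows,
        columns=["library_id", "assigned", "ambiguous", "unassigned", "retained"],
    )
    return counts_df, library_sizes, diagnostics


def _orf_lengths(orfs: Sequence[MergedOrf]) -> pd.Series:
    return pd.Series(
        {rec.orf.orf_id: rec.orf.interval.length for rec in orfs}, name="length_nt"
    )


def rpkm_matrix(
    counts: pd.DataFrame,
    orfs: Sequence[MergedOrf],
    library_sizes: Mapping[str, int],
) -> pd.DataFrame:
    lengths = _orf_lengths(orfs).reindex(counts.index)
    out = {}
    for library_id in counts.columns:
        size = library_sizes[library_id]
        if size <= 0:
            raise EmptyLibraryError(f"library {library_id!r} has no retained reads")
        out[library_id] = counts[library_id] * 1e9 / (lengths * size)
    return pd.DataFrame(out, index=counts.index)


def tpm_matrix(counts: pd.DataFrame, orfs: Sequence[MergedOrf]) -> pd.DataFrame:
    lengths = _orf_lengths(orfs).reindex(counts.index)
    out = {
        library_id: tpm(counts[library_id].to_numpy(), lengths.to_numpy())
        for library_id in counts.columns
    }
    return pd.DataFrame(out, index=counts.index)


def te_table(rpkms: pd.DataFrame, sheet: SampleSheet) -> pd.DataFrame:
    """Per-condition TE from replicate-mean RPKM ratios; NA when RNA mean is 0."""
    sheet.validate_te_support()
    out = {}
    for condition in sheet.conditions:
        ribo_libs = [s.library_id for s in sheet.libraries("RIBO", condition)]
        rna_libs = [s.library_id for s in sheet.libraries("RNA", condition)]
        if not ribo_libs:
            continue
        missing = [lib for lib in ribo_libs + rna_libs if lib not in rpkms.columns]
        if missing:
            raise SampleSheetError(f"libraries {missing} absent from RPKM matrix")
        ribo_mean = rpkms[ribo_libs].mean(axis=1)
        rna_mean = rpkms[rna_libs].mean(axis=1)
        te = ribo_mean / rna_mean
        te[rna_mean == 0] = np.nan
        out[condition] = te
    return pd.DataFrame(out, index=rpkms.index)
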