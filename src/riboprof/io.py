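"""Readers/writers for FASTA, GFF3, SAM/BAM and the sample sheet.

GFF3 is 1-based inclusive and converts to the internal 0-based half-open
convention at this boundary (``start_internal = start_gff - 1``,
``end_internal = end_gff``).  Origin-spanning features on circular contigs
are written as a single record with wrapped 1-based coordinates
(``end_gff < start_gff``) plus an ``origin_spanning=true`` attribute, and
unwrapped again on reading.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import (
    AlignedRead,
    GenomeSequence,
    GenomicInterval,
    Orf,
    ParseError,
    Sample,
    SampleSheet,
    require_genome,
    unwrap_interval,
)

logger = logging.getLogger(__name__)

SAMPLE_SHEET_COLUMNS = ["library_id", "method", "condition", "replicate", "path"]


# ---------------------------------------------------------------------- FASTA

def read_fasta(path: str | Path, circular: bool | set[str] | None = None) -> dict[str, GenomeSequence]:
    """Read a genome FASTA into a contig_id -> GenomeSequence map.

    Circularity is taken from a ``circular=true`` token in the record
    description, or forced via ``circular`` (True for all contigs, or a
    set of contig ids).
    """
    genomes: dict[str, GenomeSequence] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in genomes:
            raise ParseError(f"{path}: duplicate contig {rec.id!r}")
        if circular is True:
            circ = True
        elif isinstance(circular, set):
            circ = rec.id in circular
        else:
            circ = "circular=true" in rec.description.lower()
        genomes[rec.id] = GenomeSequence(rec.id, str(rec.seq).upper(), circular=circ)
    if not genomes:
        raise ParseError(f"{path}: no FASTA records found")
    return genomes


def write_fasta(genomes: dict[str, GenomeSequence], path: str | Path) -> None:
    records = [
        SeqRecord(
            Seq(g.sequence),
            id=g.contig_id,
            description="circular=true" if g.circular else "",
        )
        for g in genomes.values()
    ]
    SeqIO.write(records, str(path), "fasta")


# ----------------------------------------------------------------------- GFF3

def read_gff3(path: str | Path, genomes: dict[str, GenomeSequence]) -> list[Orf]:
    """Parse GFF3 records into Orf objects with internal coordinates."""
    orfs: list[Orf] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, "
                    f"got {len(cols)}"
                )
            contig, source, ftype, start_s, end_s, score, strand, _phase, attr_s = cols
            if contig not in genomes:
                raise ParseError(f"{path}:{lineno}: unknown contig {contig!r}")
            try:
                start_gff, end_gff = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: non-integer coordinates "
                    f"{start_s!r}/{end_s!r}"
                ) from None
            if strand not in ("+", "-"):
                raise ParseError(f"{path}:{lineno}: missing strand {strand!r}")
            attributes = _parse_attributes(attr_s)
            if score not in (".", ""):
                attributes.setdefault("score", score)
            genome = genomes[contig]
            try:
                interval = unwrap_interval(start_gff - 1, end_gff, strand, genome)
            except ParseError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            orf_id = attributes.get("ID", f"{ftype}_{lineno}")
            orfs.append(
                Orf(
                    orf_id=orf_id,
                    interval=interval,
                    source=source,
                    feature_type=ftype,
                    attributes=attributes,
                )
            )
    return orfs


def _parse_attributes(attr_s: str) -> dict[str, str]:
    attributes: dict[str, str] = {}
    for item in attr_s.split(";"):
        item = item.strip()
        if not item or item == ".":
            continue
        if "=" not in item:
            raise ParseError(f"malformed attribute {item!r}")
        key, value = item.split("=", 1)
        attributes[key] = value
    return attributes


def _format_attributes(attributes: dict[str, str]) -> str:
    if not attributes:
        return "."
    return ";".join(f"{k}={v}" for k, v in attributes.items() if k != "score")


def gff_coordinates(interval: GenomicInterval, genome: GenomeSequence) -> tuple[int, int, bool]:
    """Internal interval -> 1-based (start, end, origin_spanning) for GFF3."""
    length = genome.length
    if interval.end <= length:
        return interval.start + 1, interval.end, False
    return interval.start + 1, interval.end - length, True


def write_gff3(orfs: Iterable[Orf], genomes: dict[str, GenomeSequence], path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("##gff-version 3\n")
        for orf in orfs:
            genome = require_genome(genomes, orf.interval.contig_id)
            start_gff, end_gff, spans = gff_coordinates(orf.interval, genome)
            attributes = dict(orf.attributes)
            attributes["ID"] = orf.orf_id
            if spans:
                attributes["origin_spanning"] = "true"
            else:
                attributes.pop("origin_spanning", None)
            score = orf.attributes.get("score", ".")
            handle.write(
                "\t".join(
                    [
                        orf.interval.contig_id,
                        orf.source,
                        orf.feature_type,
                        str(start_gff),
                        str(end_gff),
                        str(score),
                        orf.interval.strand,
                        ".",
                        _format_attributes(attributes),
                    ]
                )
                + "\n"
            )


# -------------------------------------------------------------------- SAM/BAM

def read_alignments(path: str | Path, genomes: dict[str, GenomeSequence]) -> list[AlignedRead]:
    """Load mapped primary alignments as ungapped AlignedRead blocks.

    Multimapping is read from the NH tag when present, otherwise a
    MAPQ == 0 heuristic is applied (logged).  Alignments containing
    indels use the reference span as read length (logged).
    """
    reads: list[AlignedRead] = []
    warned_nh = warned_indel = False
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            contig = rec.reference_name
            if contig not in genomes:
                raise ParseError(f"{path}: alignment on unknown contig {contig!r}")
            span = rec.reference_length
            if span is None or span <= 0:
                continue
            if rec.query_length and rec.query_length != span and not warned_indel:
                logger.warning(
                    "%s: alignment with indels (e.g. read %s); using reference span",
                    path,
                    rec.query_name,
                )
                warned_indel = True
            if rec.has_tag("NH"):
                hit_count = int(rec.get_tag("NH"))
            else:
                hit_count = 2 if rec.mapping_quality == 0 else 1
                if not warned_nh:
                    logger.warning(
                        "%s: no NH tag; using MAPQ==0 multimapper heuristic", path
                    )
                    warned_nh = True
            strand = "-" if rec.is_reverse else "+"
            interval = GenomicInterval(contig, rec.reference_start, rec.reference_end, strand)
            reads.append(AlignedRead(interval, span, max(1, hit_count)))
    return reads


def sam_header(genomes: dict[str, GenomeSequence]) -> dict:
    return {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": g.contig_id, "LN": g.length} for g in genomes.values()],
    }


# --------------------------------------------------------------- sample sheet

def read_sample_sheet(path: str | Path) -> SampleSheet:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: cannot parse sample sheet: {exc}") from None
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing sample-sheet columns {missing}")
    samples = []
    for idx, row in df.iterrows():
        try:
            replicate = int(row["replicate"])
        except (TypeError, ValueError):
            raise ParseError(
                f"{path}: line {idx + 2}: replicate must be an integer, "
                f"got {row['replicate']!r}"
            ) from None
        samples.append(
            Sample(
                library_id=str(row["library_id"]),
                method=str(row["method"]),
                condition=str(row["condition"]),
                replicate=replicate,
                path=str(row["path"]),
            )
        )
    return SampleSheet(samples)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "library_id": s.library_id,
                "method": s.method,
                "condition": s.condition,
                "replicate": s.replicate,
                "path": s.path,
            }
            for s in sheet.samples
        ],
        columns=SAMPLE_SHEET_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)
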