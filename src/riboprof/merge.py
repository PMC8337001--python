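"""Merge reference annotation with external ORF predictions.

Identity is exact (strand, wrapped start, wrapped stop-anchor) match, so
the same origin-spanning ORF written with wrapped or unwrapped coordinates
merges into one record.  Same-stop/different-start predictions stay
distinct.  Novelty means no annotated CDS shares the key.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .core import (
    GenomeSequence,
    MalformedOrfError,
    Orf,
    extract_sequence,
    require_genome,
)
from . import io as _io

ANNOTATION_TOOL = "annotation"

__all__ = [
    "ANNOTATION_TOOL",
    "DetectionEvidence",
    "MergedOrf",
    "orf_key",
    "merge_predictions",
    "annotate_features",
    "write_merged_gff3",
]


@dataclass(frozen=True)
class DetectionEvidence:
    tool: str
    condition: str
    replicate: int
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.tool:
            raise ValueError("evidence tool must be non-empty")

    @property
    def key(self) -> tuple[str, str, int]:
        return (self.tool, self.condition, self.replicate)


@dataclass
class MergedOrf:
    orf: Orf
    novelty: bool
    evidence: list[DetectionEvidence] = field(default_factory=list)
    start_codon: str | None = None
    sequence: str | None = None
    length_nt: int | None = None
    length_aa: int | None = None


OrfKey = tuple[str, str, int, int]


def orf_key(orf: Orf, genomes: dict[str, GenomeSequence]) -> OrfKey:
    """(contig, strand, wrapped stop-anchor, wrapped start) identity key.

    The stop-anchor is the final nucleotide of the ORF in reading
    direction: end - 1 (wrapped) on the plus strand, start on the minus
    strand.
    """
    genome = require_genome(genomes, orf.interval.contig_id)
    length = genome.length
    iv = orf.interval
    start = iv.start % length
    if iv.strand == "+":
        stop_anchor = (iv.end - 1) % length
    else:
        stop_anchor = start
        start = (iv.end - 1) % length
    return (iv.contig_id, iv.strand, stop_anchor, start)


def merge_predictions(
    annotation: Sequence[Orf],
    prediction_sets: Sequence[tuple[str, str, int, Sequence[Orf]]],
    genomes: dict[str, GenomeSequence],
    annotation_condition: str = "all",
    annotation_replicate: int = 0,
) -> list[MergedOrf]:
    """One MergedOrf per distinct orf_key across annotation and predictions.

    Coordinates come from the annotation record when present, else from
    the first prediction producing the key.  Evidence accumulates every
    distinct (tool, condition, replicate) source.  Output order is
    deterministic: (contig, wrapped start, strand).
    """
    merged: dict[OrfKey, MergedOrf] = {}
    evidence_seen: dict[OrfKey, set] = {}

    def add(key: OrfKey, orf: Orf, ev: DetectionEvidence, annotated: bool) -> None:
        rec = merged.get(key)
        if rec is None:
            rec = MergedOrf(orf=orf, novelty=not annotated)
            merged[key] = rec
            evidence_seen[key] = set()
        elif annotated:
            rec.orf = orf  # annotation coordinates take precedence
            rec.novelty = False
        if ev.key not in evidence_seen[key]:
            evidence_seen[key].add(ev.key)
            rec.evidence.append(ev)

    for orf in annotation:
        key = orf_key(orf, genomes)
        ev = DetectionEvidence(ANNOTATION_TOOL, annotation_condition, annotation_replicate)
        add(key, orf, ev, annotated=True)
    for tool, condition, replicate, orfs in prediction_sets:
        for orf in orfs:
            key = orf_key(orf, genomes)
            score = orf.attributes.get("score")
            ev = DetectionEvidence(
                tool,
                condition,
                replicate,
                float(score) if score not in (None, ".", "") else None,
            )
            add(key, orf, ev, annotated=False)

    def sort_key(item: tuple[OrfKey, MergedOrf]):
        iv = item[1].orf.interval
        length = genomes[iv.contig_id].length
        # full key as tiebreaker keeps order independent of input order
        return (iv.contig_id, iv.start % length, iv.strand, item[0])

    out = [rec for _key, rec in sorted(merged.items(), key=sort_key)]
    for rec in out:
        rec.evidence.sort(key=lambda e: e.key)
    return out


def annotate_features(
    merged: Iterable[MergedOrf], genomes: dict[str, GenomeSequence]
) -> list[MergedOrf]:
    """Fill start codon, nucleotide sequence and length fields in place."""
    out = list(merged)
    for rec in out:
        iv = rec.orf.interval
        genome = require_genome(genomes, iv.contig_id)
        if iv.length < 6:
            raise MalformedOrfError(
                f"ORF {rec.orf.orf_id!r} is {iv.length} nt long (< 6 nt)"
            )
        seq = extract_sequence(iv, genome)
        rec.sequence = seq
        rec.start_codon = seq[:3]
        rec.length_nt = iv.length
        rec.length_aa = iv.length // 3 - 1 if iv.length % 3 == 0 else None
    return out


def write_merged_gff3(
    merged: Sequence[MergedOrf],
    genomes: dict[str, GenomeSequence],
    path: str | Path,
) -> None:
    orfs = []
    for rec in merged:
        attributes = dict(rec.orf.attributes)
        attributes["novelty"] = "true" if rec.novelty else "false"
        attributes["evidence"] = ",".join(
            f"{e.tool}:{e.condition}:{e.replicate}" for e in rec.evidence
        )
        if rec.start_codon:
            attributes["start_codon"] = rec.start_codon
        orfs.append(
            Orf(
                orf_id=rec.orf.orf_id,
                interval=rec.orf.interval,
                source="riboprof",
                feature_type="CDS",
                attributes=attributes,
            )
        )
    _io.write_gff3(orfs, genomes, path)
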