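"""Self-contained synthetic datasets with planted ground truth.

Generates a (optionally circular) genome whose first ORF spans the
origin, a CDS + rRNA annotation, and per-library SAM reads for RIBO and
RNA methods across conditions/replicates.  Planted quantities — rRNA read
counts, multimapper counts, per-ORF read totals, translation-efficiency
ratios — are recorded in a truth dict so pipeline diagnostics can be
checked exactly.

All randomness flows through one numpy Generator seeded from the spec, so
outputs are byte-reproducible.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .core import (
    AlignedRead,
    GenomeSequence,
    GenomicInterval,
    Orf,
    Sample,
    SampleSheet,
    reverse_complement,
)
from . import io as _io

__all__ = [
    "SimulationSpec",
    "simulate_genome",
    "simulate_reads",
    "write_dataset",
    "write_sam",
    "balanced_expression_weights",
]

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationSpec:
    genome_length: int = 8000
    circular: bool = True
    n_orfs: int = 6
    orf_length_range: tuple[int, int] = (90, 300)
    conditions: tuple[str, ...] = ("c1",)
    replicates: int = 1
    te: Mapping[str, Sequence[float]] | None = None  # condition -> per-ORF TE
    rna_weights: Sequence[float] | None = None  # per-ORF RNA expression weight
    reads_per_orf: int = 300
    library_size: int | None = None  # overrides reads_per_orf when set
    read_length_distribution: tuple[tuple[int, float], ...] = (
        (28, 0.5),
        (29, 0.3),
        (30, 0.2),
    )
    start_enrichment: float = 5.0
    in_frame_prob: float = 0.9
    rrna_fraction: float = 0.1
    multimap_fraction: float = 0.05
    intergenic_range: tuple[int, int] = (30, 80)
    rrna_length: int = 120
    seed: int = 0

    def __post_init__(self) -> None:
        probs = [p for _, p in self.read_length_distribution]
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError("read length probabilities must sum to 1")
        if not 0 <= self.rrna_fraction < 1 or not 0 <= self.multimap_fraction < 1:
            raise ValueError("rrna_fraction and multimap_fraction must be in [0, 1)")
        if self.orf_length_range[0] < 9:
            raise ValueError("minimum ORF length is 9 nt (start + codon + stop)")
        if self.te is not None:
            for cond, values in self.te.items():
                if len(values) != self.n_orfs:
                    raise ValueError(
                        f"te for condition {cond!r} must list {self.n_orfs} values"
                    )

    def te_for(self, condition: str) -> list[float]:
        if self.te is None or condition not in self.te:
            return [1.0] * self.n_orfs
        return list(self.te[condition])

    def weights(self) -> list[float]:
        if self.rna_weights is None:
            return [1.0] * self.n_orfs
        if len(self.rna_weights) != self.n_orfs:
            raise ValueError(f"rna_weights must list {self.n_orfs} values")
        return list(self.rna_weights)


def balanced_expression_weights(te_values: Sequence[float]) -> list[float]:
    """RNA weights making ratio-of-RPKM TE estimates identifiable.

    Within-library normalization forces the read-weighted mean of
    estimated TEs to 1, so absolute planted TEs are only recoverable when
    sum(w_i * te_i) == sum(w_i).  This solves for one weight to satisfy
    that constraint exactly.
    """
    te = [float(v) for v in te_values]
    weights = [1.0] * len(te)
    deviation = sum(v - 1.0 for v in te)
    if deviation == 0:
        return weights
    j = int(np.argmin(te)) if deviation > 0 else int(np.argmax(te))
    rest = sum(v - 1.0 for i, v in enumerate(te) if i != j)
    denom = 1.0 - te[j]
    if denom == 0 or rest / denom <= 0:
        raise ValueError(f"cannot balance TE values {te}")
    weights[j] = rest / denom
    return weights


# ------------------------------------------------------------------- genome

def simulate_genome(
    spec: SimulationSpec, rng: np.random.Generator | None = None
) -> tuple[GenomeSequence, list[Orf], Orf]:
    """Random genome plus CDS annotation and one designated rRNA feature.

    Every ORF begins ATG and ends TAA in reading direction; ORFs and the
    rRNA feature never overlap.  On circular genomes the first ORF is
    rotated to span the origin.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    length = spec.genome_length
    seq = list(rng.choice(_BASES, size=length))

    lo, hi = spec.orf_length_range
    layout: list[tuple[int, int, str]] = []
    cursor = 0
    for _ in range(spec.n_orfs):
        gap = int(rng.integers(spec.intergenic_range[0], spec.intergenic_range[1] + 1))
        orf_len = int(rng.integers(lo // 3, hi // 3 + 1)) * 3
        strand = str(rng.choice(["+", "-"]))
        start = cursor + gap
        layout.append((start, start + orf_len, strand))
        cursor = start + orf_len
    gap = int(rng.integers(spec.intergenic_range[0], spec.intergenic_range[1] + 1))
    rrna_start = cursor + gap
    rrna_end = rrna_start + spec.rrna_length
    tail_gap = spec.intergenic_range[0]
    if rrna_end + tail_gap > length:
        raise ValueError(
            f"infeasible packing: need {rrna_end + tail_gap} nt, genome is {length} nt"
        )

    delta = 0
    if spec.circular:
        # rotate so the first ORF straddles the origin
        first_start, first_end, _ = layout[0]
        delta = length - first_start - (first_end - first_start) // 2

    def shift(start: int, end: int) -> tuple[int, int]:
        s = start + delta
        if s >= length:
            s -= length
        return s, s + (end - start)

    if delta:
        seq = seq[length - delta :] + seq[: length - delta]
        layout = [(*shift(s, e), strand) for s, e, strand in layout]
        rrna_start, rrna_end = shift(rrna_start, rrna_end)

    def set_base(pos: int, base: str) -> None:
        seq[pos % length] = base

    def plant(start: int, end: int, strand: str) -> None:
        head = "ATG" if strand == "+" else reverse_complement("TAA")
        tail = "TAA" if strand == "+" else reverse_complement("ATG")
        for i, base in enumerate(head):
            set_base(start + i, base)
        for i, base in enumerate(tail):
            set_base(end - 3 + i, base)

    orfs: list[Orf] = []
    for i, (start, end, strand) in enumerate(layout):
        plant(start, end, strand)
        orfs.append(
            Orf(
                orf_id=f"gene{i:03d}",
                interval=GenomicInterval("chr", start, end, strand),
                source="annotation",
                feature_type="CDS",
                attributes={"Name": f"gene{i:03d}"},
            )
        )
    rrna = Orf(
        orf_id="rrna1",
        interval=GenomicInterval("chr", rrna_start, rrna_end, "+"),
        source="annotation",
        feature_type="rRNA",
        attributes={"Name": "rrna1"},
    )
    genome = GenomeSequence("chr", "".join(seq), circular=spec.circular)
    return genome, orfs, rrna


# -------------------------------------------------------------------- reads

def _largest_remainder(total: int, weights: Sequence[float]) -> list[int]:
    w = np.asarray(weights, dtype=float)
    quotas = total * w / w.sum()
    base = np.floor(quotas).astype(int)
    remainder = total - int(base.sum())
    order = np.argsort(-(quotas - base), kind="stable")
    for idx in order[:remainder]:
        base[idx] += 1
    return base.tolist()


def _snap_offset(off: int, orf_len: int, rl: int, cross_lo: int, step: int) -> int:
    """Move ``off`` (preserving residue mod step) off the origin-crossing zone.

    Offsets in the open interval (cross_lo, cross_lo + rl) would place the
    read across the origin, which plain SAM cannot express.
    """
    cross_hi = cross_lo + rl
    if off <= cross_lo or off >= cross_hi:
        return off
    left = off - math.ceil((off - cross_lo) / step) * step
    right = off + math.ceil((cross_hi - off) / step) * step
    candidates = [
        c
        for c in (left, right)
        if 0 <= c <= orf_len - rl and (c <= cross_lo or c >= cross_hi)
    ]
    if not candidates:
        raise ValueError("cannot place read without crossing the origin")
    return min(candidates, key=lambda c: abs(c - off))


def _read_interval(
    orf: Orf, off: int, rl: int, genome: GenomeSequence, step: int
) -> GenomicInterval:
    """Genomic interval of a read at 5'-offset ``off`` inside ``orf``."""
    length = genome.length
    iv = orf.interval
    if iv.end > length:
        # unwrapped read start; crossing zone expressed on the offset axis
        if iv.strand == "+":
            cross_lo = length - iv.start - rl
        else:
            cross_lo = iv.end - length - rl
        off = _snap_offset(off, iv.length, rl, cross_lo, step)
    if iv.strand == "+":
        start = iv.start + off
    else:
        start = iv.end - off - rl
    if start >= length:
        start -= length
    return GenomicInterval(iv.contig_id, start, start + rl, iv.strand)


def _draw_read_length(spec: SimulationSpec, rng: np.random.Generator, max_len: int) -> int:
    lengths = [l for l, _ in spec.read_length_distribution]
    probs = [p for _, p in spec.read_length_distribution]
    rl = int(rng.choice(lengths, p=probs))
    return min(rl, max_len)


def _ribo_offset(
    spec: SimulationSpec, rng: np.random.Generator, orf_len: int, rl: int
) -> int:
    frame = 0 if rng.random() < spec.in_frame_prob else int(rng.integers(1, 3))
    max_codon = (orf_len - rl - frame) // 3
    if max_codon < 0:
        return 0
    w = np.ones(max_codon + 1)
    w[0] = spec.start_enrichment
    codon = int(rng.choice(max_codon + 1, p=w / w.sum()))
    return 3 * codon + frame


def simulate_reads(
    spec: SimulationSpec,
    genome: GenomeSequence,
    orfs: Sequence[Orf],
    rrna: Orf,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, list[tuple[str, AlignedRead]]], dict]:
    """Simulate per-library (qname, read) lists plus a planted-truth dict.

    RIBO 5' ends are placed in frame with probability ``in_frame_prob``
    and enriched ``start_enrichment``-fold at the start codon; RNA reads
    are uniform within each ORF.  rRNA and multimapper contamination is
    planted at exact counts recorded in the truth dict.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    libraries: dict[str, list[tuple[str, AlignedRead]]] = {}
    truth: dict = {
        "seed": spec.seed,
        "conditions": list(spec.conditions),
        "rna_weights": spec.weights(),
        "te": {c: spec.te_for(c) for c in spec.conditions},
        "libraries": {},
    }
    base_weights = spec.weights()
    for condition in spec.conditions:
        te_values = spec.te_for(condition)
        for replicate in range(1, spec.replicates + 1):
            for method in ("RIBO", "RNA"):
                library_id = f"{condition}-{method}-{replicate}"
                if method == "RIBO":
                    weights = [w * t for w, t in zip(base_weights, te_values)]
                else:
                    weights = list(base_weights)
                if spec.library_size is not None:
                    n_total = spec.library_size
                    n_rrna = round(spec.rrna_fraction * n_total)
                    n_multi = round(spec.multimap_fraction * n_total)
                    orf_counts = _largest_remainder(n_total - n_rrna, weights)
                else:
                    orf_counts = [round(spec.reads_per_orf * w) for w in weights]
                    n_base = sum(orf_counts)
                    n_rrna = (
                        round(spec.rrna_fraction / (1 - spec.rrna_fraction) * n_base)
                        if spec.rrna_fraction > 0
                        else 0
                    )
                    n_total = n_base + n_rrna
                    n_multi = round(spec.multimap_fraction * n_total)
                orf_reads: list[tuple[int, AlignedRead]] = []
                for i, orf in enumerate(orfs):
                    for _ in range(orf_counts[i]):
                        rl = _draw_read_length(spec, rng, orf.interval.length)
                        if method == "RIBO":
                            off = _ribo_offset(spec, rng, orf.interval.length, rl)
                        else:
                            off = int(rng.integers(0, orf.interval.length - rl + 1))
                        iv = _read_interval(
                            orf, off, rl, genome, step=3 if method == "RIBO" else 1
                        )
                        orf_reads.append((i, AlignedRead(iv, rl, 1)))
                if n_multi > len(orf_reads):
                    raise ValueError("multimap_fraction too high for ORF read count")
                multi_idx = set(
                    rng.choice(len(orf_reads), size=n_multi, replace=False).tolist()
                )
                reads: list[tuple[str, AlignedRead]] = []
                retained_counts = [0] * len(orfs)
                for j, (orf_i, read) in enumerate(orf_reads):
                    if j in multi_idx:
                        read = AlignedRead(read.interval, read.read_length, 2)
                    else:
                        retained_counts[orf_i] += 1
                    reads.append((f"{library_id}_orf_{j}", read))
                for j in range(n_rrna):
                    rl = _draw_read_length(spec, rng, rrna.interval.length)
                    off = int(rng.integers(0, rrna.interval.length - rl + 1))
                    iv = _read_interval(rrna, off, rl, genome, step=1)
                    reads.append((f"{library_id}_rrna_{j}", AlignedRead(iv, rl, 1)))
                libraries[library_id] = reads
                truth["libraries"][library_id] = {
                    "method": method,
                    "condition": condition,
                    "replicate": replicate,
                    "n_total": n_total,
                    "n_rrna": n_rrna,
                    "n_multimapped": n_multi,
                    "orf_counts": {
                        orf.orf_id: orf_counts[i] for i, orf in enumerate(orfs)
                    },
                    "orf_counts_retained": {
                        orf.orf_id: retained_counts[i] for i, orf in enumerate(orfs)
                    },
                }
    return libraries, truth


# ------------------------------------------------------------------- output

def write_sam(
    reads: Sequence[tuple[str, AlignedRead]],
    genomes: dict[str, GenomeSequence],
    path: str | Path,
) -> None:
    """Minimal valid SAM with NH tags; sequences on the forward strand."""
    with open(path, "w") as handle:
        handle.write("@HD\tVN:1.6\tSO:unsorted\n")
        for g in genomes.values():
            handle.write(f"@SQ\tSN:{g.contig_id}\tLN:{g.length}\n")
        for qname, read in reads:
            iv = read.interval
            genome = genomes[iv.contig_id]
            if iv.end > genome.length:
                raise ValueError(
                    f"read {qname!r} crosses the origin; SAM cannot express that"
                )
            seq = genome.sequence[iv.start : iv.end]
            flag = 16 if iv.strand == "-" else 0
            handle.write(
                f"{qname}\t{flag}\t{iv.contig_id}\t{iv.start + 1}\t42\t"
                f"{read.read_length}M\t*\t0\t0\t{seq}\t*\tNH:i:{read.hit_count}\n"
            )


def write_dataset(spec: SimulationSpec, out_dir: str | Path) -> dict[str, Path]:
    """Write FASTA, GFF3, per-library SAM, sample sheet and truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    genome, orfs, rrna = simulate_genome(spec, rng)
    libraries, truth = simulate_reads(spec, genome, orfs, rrna, rng)
    genomes = {genome.contig_id: genome}

    paths: dict[str, Path] = {
        "genome": out / "genome.fa",
        "annotation": out / "annotation.gff3",
        "samples": out / "samples.tsv",
        "truth": out / "truth.json",
    }
    _io.write_fasta(genomes, paths["genome"])
    _io.write_gff3([*orfs, rrna], genomes, paths["annotation"])
    samples = []
    for library_id, reads in libraries.items():
        sam_path = out / f"{library_id}.sam"
        write_sam(reads, genomes, sam_path)
        paths[library_id] = sam_path
        info = truth["libraries"][library_id]
        samples.append(
            Sample(
                library_id=library_id,
                method=info["method"],
                condition=info["condition"],
                replicate=info["replicate"],
                path=sam_path.name,
            )
        )
    _io.write_sample_sheet(SampleSheet(samples), paths["samples"])
    with open(paths["truth"], "w") as handle:
        json.dump(truth, handle, indent=1, sort_keys=True)
    return paths
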