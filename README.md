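# riboprof

Post-mapping analysis toolkit for **bacterial ribosome profiling (Ribo-seq)**
data, with first-class support for **circular chromosomes**. Starting from
mapped reads (SAM/BAM), a genome FASTA and a GFF3 annotation, it provides:

- **Read filtering** — removal of multimapped reads (SAM `NH` tag, with a
  MAPQ-0 fallback heuristic) and reads overlapping rRNA/tRNA features, with a
  conservation-checked count report.
- **Coverage tracks** — strand-specific per-nucleotide tracks in four mapping
  modes (`full`, `fiveprime`, `threeprime`, `center`), raw or CPM-normalized,
  written as text wiggle or bedGraph.
- **Metagene profiling** — read density around annotated start codons,
  stratified by read length, plus a per-frame periodicity summary for
  detecting three-nucleotide periodicity.
- **ORF merging** — reference annotation plus GFF3 predictions from external
  predictors (e.g. REPARATION, DeepRibo) merged into a non-redundant list
  with novelty classification and per-tool/condition/replicate evidence.
- **Quantification** — strand-specific per-ORF read counting (ambiguous reads
  discarded and diagnosed), RPKM, TPM, and per-condition translation
  efficiency (mean RIBO RPKM / mean RNA RPKM).
- **Overview table** — one enriched TSV row per ORF: coordinates, novelty,
  start codon, lengths, sequence, counts/RPKM/TPM per library, TE per
  condition, detection evidence, and optional joined differential-expression
  results.
- **Synthetic fixtures** — a simulator that generates genome, annotation,
  and RIBO/RNA SAM libraries with planted truth (rRNA/multimapper fractions,
  per-ORF counts, TE ratios), so everything is testable offline.

## Coordinate conventions

Internally all coordinates are 0-based half-open. Features on circular
contigs that cross the origin are stored *unwrapped* (`start < length`,
`end > length`). GFF3 I/O is 1-based inclusive; origin-spanning features are
written as a single record with wrapped coordinates (`end < start`) plus an
`origin_spanning=true` attribute, and unwrapped on reading. Wiggle output is
1-based; bedGraph is 0-based half-open.

## CLI

One entry point, `riboprof`, with subcommands:

```bash
# generate a toy dataset with planted truth
riboprof simulate --seed 1 --out-dir data/

# individual stages
riboprof filter   --bam data/c1-RIBO-1.sam --gff data/annotation.gff3 \
                  --genome data/genome.fa --out filtered.sam --report report.tsv
riboprof coverage --bam data/c1-RIBO-1.sam --genome data/genome.fa \
                  --mode fiveprime --norm cpm --out-dir tracks/
riboprof metagene --bam data/c1-RIBO-1.sam --gff data/annotation.gff3 \
                  --genome data/genome.fa --lengths 20:45 --out-dir metagene/
riboprof merge    --annotation data/annotation.gff3 --genome data/genome.fa \
                  --pred tool=deepribo,cond=c1,rep=1,file=pred.gff3 --out merged.gff3
riboprof quantify --merged merged.gff3 --genome data/genome.fa \
                  --samples data/samples.tsv --gff data/annotation.gff3 --out-dir quant/
riboprof report   --merged merged.gff3 --genome data/genome.fa \
                  --quant-dir quant/ --samples data/samples.tsv --out overview.tsv

# whole pipeline from a YAML config (deterministic; emits manifest.json)
riboprof run-all --config config.yaml
```

Minimal `config.yaml`:

```yaml
genome: genome.fa
annotation: annotation.gff3
sample_sheet: samples.tsv      # columns: library_id method condition replicate path
output_dir: out
predictions:                   # optional
  - {tool: deepribo, condition: c1, replicate: 1, file: pred.gff3}
de_tables:                     # optional
  - {contrast: c2_vs_c1, file: de.tsv}
seed: 1
```

## Overview table columns

`orf_id, contig, start, stop, strand, novelty, start_codon, length_nt,
length_aa, sequence, evidence`, then `count_<library>`, `rpkm_<library>`,
`tpm_<library>` per library, `te_<condition>` per condition, and
`<contrast>_<field>` for any joined DE tables. Floats are printed with 4
significant digits; missing values as `NA`.
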