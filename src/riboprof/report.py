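"""The enriched per-ORF overview table.

One row per merged ORF joining coordinates, novelty, sequence features,
per-library counts/RPKM/TPM, per-condition TE, detection evidence, and
optional external differential-expression results (left join).  Output is
TSV with floats at 4 significant digits and ``NA`` for missing values.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import GenomeSequence, ParseError, require_genome
from .io import gff_coordinates
from .merge import MergedOrf, orf_key

__all__ = ["join_differential", "build_overview", "write_overview"]

NA = "NA"


def _de_key_map(
    merged: Sequence[MergedOrf], genomes: Mapping[str, GenomeSequence]
) -> dict[tuple, str]:
    return {orf_key(rec.orf, dict(genomes)): rec.orf.orf_id for rec in merged}


def join_differential(
    merged: Sequence[MergedOrf],
    de_tables: Sequence[tuple[str, pd.DataFrame]],
    genomes: Mapping[str, GenomeSequence],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Left-join DE results onto merged ORFs.

    Each DE table is keyed either by an ``orf_id`` column or by
    ``contig``/``start``/``end``/``strand`` columns (1-based inclusive,
    wrapped allowed on circular contigs) convertible via the ORF identity
    key.  Returns (DE columns indexed by orf_id, unmatched-row diagnostic).
    """
    from .core import Orf, unwrap_interval  # local import avoids cycle noise

    orf_ids = [rec.orf.orf_id for rec in merged]
    key_map = _de_key_map(merged, genomes)
    out = pd.DataFrame(index=pd.Index(orf_ids, name="orf_id"))
    unmatched_rows = []
    for contrast, table in de_tables:
        value_cols = [
            c
            for c in table.columns
            if c not in ("orf_id", "contig", "start", "end", "strand")
        ]
        seen_ids: set[str] = set()
        matched: dict[str, pd.Series] = {}
        for _, row in table.iterrows():
            if "orf_id" in table.columns and pd.notna(row.get("orf_id")):
                target = row["orf_id"] if row["orf_id"] in orf_ids else None
            else:
                needed = ("contig", "start", "end", "strand")
                if any(c not in table.columns for c in needed):
                    raise ParseError(
                        f"DE table {contrast!r}: need orf_id or "
                        f"contig/start/end/strand columns"
                    )
                genome = require_genome(dict(genomes), str(row["contig"]))
                interval = unwrap_interval(
                    int(row["start"]) - 1, int(row["end"]), str(row["strand"]), genome
                )
                key = orf_key(Orf("q", interval), dict(genomes))
                target = key_map.get(key)
            if target is None:
                unmatched_rows.append({"contrast": contrast, "row": _row_repr(row)})
                continue
            if target in seen_ids:
                raise ParseError(
                    f"DE table {contrast!r}: duplicate key for ORF {target!r}"
                )
            seen_ids.add(target)
            matched[target] = row[value_cols]
        for col in value_cols:
            series = pd.Series(
                {oid: vals[col] for oid, vals in matched.items()}, dtype=object
            )
            out[f"{contrast}_{col}"] = series.reindex(orf_ids).to_numpy()
    diagnostics = pd.DataFrame(unmatched_rows, columns=["contrast", "row"])
    return out, diagnostics


def _row_repr(row: pd.Series) -> str:
    return ";".join(f"{k}={row[k]}" for k in row.index)


def build_overview(
    merged: Sequence[MergedOrf],
    counts: pd.DataFrame,
    rpkms: pd.DataFrame,
    tpms: pd.DataFrame,
    te: pd.DataFrame,
    genomes: Mapping[str, GenomeSequence],
    de_columns: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Assemble the overview table, one row per merged ORF.

    Column order: identity/coordinates, novelty and sequence features,
    per-library count/RPKM/TPM blocks, per-condition TE, evidence, then
    any DE columns.
    """
    orf_ids = [rec.orf.orf_id for rec in merged]
    for frame, name in ((counts, "counts"), (rpkms, "rpkm"), (tpms, "tpm")):
        extra = set(frame.index) - set(orf_ids)
        if extra:
            raise ValueError(f"{name} matrix contains unknown ORF ids: {sorted(extra)}")
    rows = []
    for rec in merged:
        genome = require_genome(dict(genomes), rec.orf.interval.contig_id)
        start_gff, end_gff, _spans = gff_coordinates(rec.orf.interval, genome)
        rows.append(
            {
                "orf_id": rec.orf.orf_id,
                "contig": rec.orf.interval.contig_id,
                "start": start_gff,
                "stop": end_gff,
                "strand": rec.orf.interval.strand,
                "novelty": rec.novelty,
                "start_codon": rec.start_codon or NA,
                "length_nt": rec.length_nt or rec.orf.interval.length,
                "length_aa": rec.length_aa if rec.length_aa is not None else np.nan,
                "sequence": rec.sequence or NA,
                "evidence": ",".join(
                    f"{e.tool}:{e.condition}:{e.replicate}" for e in rec.evidence
                ),
            }
        )
    base_columns = [
        "orf_id", "contig", "start", "stop", "strand", "novelty", "start_codon",
        "length_nt", "length_aa", "sequence", "evidence",
    ]
    df = pd.DataFrame(rows, columns=base_columns).set_index("orf_id")
    for library_id in counts.columns:
        df[f"count_{library_id}"] = counts[library_id].reindex(df.index)
    for library_id in rpkms.columns:
        df[f"rpkm_{library_id}"] = rpkms[library_id].reindex(df.index)
    for library_id in tpms.columns:
        df[f"tpm_{library_id}"] = tpms[library_id].reindex(df.index)
    for condition in te.columns:
        df[f"te_{condition}"] = te[condition].reindex(df.index)
    if de_columns is not None:
        for col in de_columns.columns:
            df[col] = de_columns[col].reindex(df.index)
    # deterministic row order: (contig, start, strand)
    df = df.sort_values(["contig", "start", "strand"], kind="mergesort")
    return df.reset_index()


def _format_value(value) -> str:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return NA
    if isinstance(value, (bool, np.bool_)):
        return "true" if value else "false"
    if isinstance(value, (float, np.floating)):
        return f"{value:.4g}"
    if isinstance(value, (int, np.integer)):
        return str(value)
    return str(value)


def write_overview(df: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("\t".join(df.columns) + "\n")
        for _, row in df.iterrows():
            handle.write("\t".join(_format_value(v) for v in row) + "\n")
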