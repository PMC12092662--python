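"""MAF-like table I/O, sequence-context extraction, annotation-table I/O.

Tables are tab-separated with a header row.  Default column names follow the
Mutation Annotation Format (MAF) convention; a ``column_map`` from logical
field names to file column names overrides them.  Reference sequence access
accepts either a FASTA path (indexed via pyfaidx) or an in-memory mapping
``chrom -> sequence`` (as produced by the cohort simulator).
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, CoordinateError, EmptyInputError, LookupError_
from .variants import UNKNOWN, VariantRecord, variant_key

logger = logging.getLogger(__name__)

#: logical field -> default MAF column name
DEFAULT_COLUMNS = {
    "patient": "Tumor_Sample_Barcode",
    "chrom": "Chromosome",
    "pos": "Start_Position",
    "ref": "Reference_Allele",
    "alt": "Tumor_Seq_Allele2",
    "gene": "Hugo_Symbol",
    "cancer_type": "Cancer_Type",
    "vaf": "VAF",
    "label": "Label",
    "context": "Context",
    "context_truncated": "Context_Truncated",
}

_REQUIRED = ("patient", "chrom", "pos", "ref", "alt", "gene")


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    return isinstance(value, str) and value.strip() == ""


def read_variant_table(path, column_map: Mapping[str, str] | None = None) -> list[VariantRecord]:
    """Read a MAF-like TSV into :class:`VariantRecord` objects.

    Rows whose required fields cannot be parsed are rejected and reported
    (with 1-based data row numbers) rather than aborting the whole read.
    """
    columns = dict(DEFAULT_COLUMNS)
    if column_map:
        columns.update(column_map)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[0] == 0:
        raise EmptyInputError(f"variant table {path} contains no data rows")
    for field in _REQUIRED:
        if columns[field] not in df.columns:
            raise ConfigurationError(
                f"required column {columns[field]!r} (field {field!r}) missing from {path}"
            )

    def get(row, field, default=None):
        col = columns[field]
        if col not in df.columns:
            return default
        val = row[col]
        return default if _is_missing(val) else val

    records: list[VariantRecord] = []
    bad_rows: list[tuple[int, str]] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row = dict(zip(df.columns, row))
        try:
            vaf_raw = get(row, "vaf")
            trunc_raw = get(row, "context_truncated", "False")
            records.append(
                VariantRecord(
                    patient_id=str(row[columns["patient"]]),
                    chrom=str(row[columns["chrom"]]),
                    pos=int(row[columns["pos"]]),
                    ref=str(row[columns["ref"]]).upper(),
                    alt=str(row[columns["alt"]]).upper(),
                    gene=str(row[columns["gene"]]),
                    cancer_type=str(get(row, "cancer_type", UNKNOWN)),
                    vaf=None if vaf_raw is None else float(vaf_raw),
                    context=(lambda c: None if c is None else str(c).upper())(get(row, "context")),
                    label=str(get(row, "label", UNKNOWN)),
                    context_truncated=str(trunc_raw).strip().lower() in ("true", "1"),
                )
            )
        except (ValueError, KeyError) as exc:
            bad_rows.append((i, str(exc)))
    if bad_rows:
        logger.warning(
            "read_variant_table: rejected %d row(s): %s",
            len(bad_rows),
            "; ".join(f"row {i}: {msg}" for i, msg in bad_rows[:10]),
        )
    return records


def write_variant_table(records: list[VariantRecord], path, column_map: Mapping[str, str] | None = None) -> None:
    """Write records as a MAF-like TSV, appending derived columns.

    Derived columns: context, truncation flag and the canonical variant key.
    A table written here round-trips bit-exactly through
    :func:`read_variant_table`.
    """
    columns = dict(DEFAULT_COLUMNS)
    if column_map:
        columns.update(column_map)
    rows = []
    for rec in records:
        rows.append(
            {
                columns["patient"]: rec.patient_id,
                columns["chrom"]: rec.chrom,
                columns["pos"]: rec.pos,
                columns["ref"]: rec.ref,
                columns["alt"]: rec.alt,
                columns["gene"]: rec.gene,
                columns["cancer_type"]: rec.cancer_type,
                columns["vaf"]: "" if rec.vaf is None else repr(rec.vaf),
                columns["label"]: rec.label,
                columns["context"]: rec.context or "",
                columns["context_truncated"]: str(rec.context_truncated),
                "Variant_Key": variant_key(rec),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _contig(fasta, chrom: str):
    """Resolve a contig by name from a mapping, pyfaidx.Fasta, or FASTA path."""
    if isinstance(fasta, (str, Path)):
        import pyfaidx

        fasta = pyfaidx.Fasta(str(fasta))
    try:
        return fasta[chrom]
    except KeyError:
        raise LookupError_(f"chromosome {chrom!r} absent from reference") from None


def attach_contexts(records: list[VariantRecord], fasta, flank: int = 10) -> list[VariantRecord]:
    """Attach alt-centered sequence-context windows to records lacking one.

    For SNVs the context is ``flank`` upstream reference bases, the alt base,
    and ``flank`` downstream reference bases (2*flank+1 characters).  Indels
    follow the same rule with the alt sequence replacing the reference span:
    insertions carry their full inserted sequence, deletions omit the deleted
    bases.  Windows are truncated (never padded) at contig ends and flagged.
    """
    if isinstance(fasta, (str, Path)):
        import pyfaidx

        fasta = pyfaidx.Fasta(str(fasta))
    out: list[VariantRecord] = []
    for rec in records:
        if rec.context is not None:
            out.append(rec)
            continue
        contig = _contig(fasta, rec.chrom)
        length = len(contig)
        start0 = rec.pos - 1
        ref_end = start0 + len(rec.ref)
        if start0 >= length or ref_end > length:
            raise CoordinateError(
                f"{rec.chrom}:{rec.pos} (ref length {len(rec.ref)}) exceeds contig length {length}"
            )
        up = str(contig[max(0, start0 - flank):start0]).upper()
        down = str(contig[ref_end:ref_end + flank]).upper()
        observed_ref = str(contig[start0:ref_end]).upper()
        if observed_ref != rec.ref:
            logger.warning(
                "reference mismatch at %s:%d: table says %s, FASTA says %s",
                rec.chrom, rec.pos, rec.ref, observed_ref,
            )
        truncated = len(up) < flank or len(down) < flank
        out.append(rec.with_(context=up + rec.alt + down, context_truncated=truncated))
    return out


def write_fasta(contigs: Mapping[str, str], path, width: int = 60) -> None:
    """Write contigs as an uncompressed FASTA file (deterministic order)."""
    with open(path, "w") as fh:
        for name in contigs:
            fh.write(f">{name}\n")
            seq = contigs[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
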