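"""Variant records, canonical keys, and record-level filters.

A :class:`VariantRecord` is one observed variant in one patient: genomic
coordinates (1-based, fully closed, MAF convention), alleles, gene symbol,
cancer type, variant allele frequency (VAF) and an origin label.  Labels
distinguish tumor-derived variants from clonal-hematopoiesis (CH) variants;
CH carries a three-class refinement (oncogenic / non-oncogenic) used by the
sequence-based classifiers, while cfDNA-style data may only know the binary
CH label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from .errors import AggregationError

logger = logging.getLogger(__name__)

# Origin labels.
TUMOR = "TUMOR"
CH_ONCOGENIC = "CH_ONCOGENIC"
CH_NON_ONCOGENIC = "CH_NON_ONCOGENIC"
CH = "CH"
UNKNOWN = "UNKNOWN"

LABELS = (TUMOR, CH_ONCOGENIC, CH_NON_ONCOGENIC, CH, UNKNOWN)
#: labels counting as blood (CH) origin in the binary task
CH_LABELS = frozenset({CH, CH_ONCOGENIC, CH_NON_ONCOGENIC})

_DNA = frozenset("ACGT")


@dataclass(frozen=True)
class VariantRecord:
    """One observed variant in one patient.

    ``pos`` is 1-based; ``ref``/``alt`` are non-empty uppercase DNA strings
    (no ``-`` placeholders: indels are anchored, VCF-style).  ``context`` is
    the alt-centered sequence window attached by
    :func:`metach.io.attach_contexts` and may contain ``N``.
    """

    patient_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    cancer_type: str = UNKNOWN
    vaf: float | None = None
    context: str | None = None
    label: str = UNKNOWN
    context_truncated: bool = False

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        for name, allele in (("ref", self.ref), ("alt", self.alt)):
            if not allele or not set(allele) <= _DNA:
                raise ValueError(f"{name} must be a nonempty ACGT string, got {allele!r}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.vaf is not None and not (0.0 <= self.vaf <= 1.0):
            raise ValueError(f"vaf must lie in [0, 1], got {self.vaf}")
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}; expected one of {LABELS}")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def is_ch(self) -> bool:
        """Binary origin: True when the label is any flavour of CH."""
        return self.label in CH_LABELS

    def with_(self, **changes) -> "VariantRecord":
        return replace(self, **changes)


def variant_key(record: VariantRecord) -> str:
    """Canonical ``chrom:pos:ref:alt`` identity, patient-independent."""
    return f"{record.chrom}:{record.pos}:{record.ref}:{record.alt}"


def deduplicate_within_dataset(records: list[VariantRecord]) -> list[VariantRecord]:
    """Keep the first occurrence of each variant key; order preserved.

    Mirrors the per-dataset duplicate removal applied before training the
    sequence-based classifiers.
    """
    seen: set[str] = set()
    out: list[VariantRecord] = []
    for rec in records:
        key = variant_key(rec)
        if key not in seen:
            seen.add(key)
            out.append(rec)
    return out


def filter_unknown_significance(records: list[VariantRecord]) -> list[VariantRecord]:
    """Drop records whose origin label is UNKNOWN (training preparation).

    Variants of unknown significance carry no usable supervision for the
    binary CH-vs-tumor task and are excluded before classifier training.
    """
    kept = [r for r in records if r.label != UNKNOWN]
    removed = len(records) - len(kept)
    if removed:
        logger.info("filter_unknown_significance: removed %d of %d records", removed, len(records))
    return kept
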