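"""Per-variant feature assembly for the base classifiers.

Two feature layouts exist:

* ``cfdna``   : Ev | Eg | Epv | Epg | Ef | VAF | Ct — the full set, including
  patient-level mean embeddings and VAF, used by the cfDNA-based classifier;
* ``sequence``: Ev | Eg | Ef | Ct — no patient-level blocks and no VAF, used
  by the two sequence-based classifiers (their training data carries neither
  a cfDNA patient context nor comparable VAFs).

Cancer type is one-hot encoded over the vocabulary seen at fit time plus an
UNKNOWN slot; unseen types map to UNKNOWN.  Missing VAF is imputed with the
training median.  ``group_index_`` maps each feature group name to its column
indices and partitions the columns exactly once — the unit the grouped
permutation-importance analysis shuffles jointly.
"""

from __future__ import annotations

import logging

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import GroupingError, StateError
from .variants import UNKNOWN, VariantRecord

logger = logging.getLogger(__name__)

CFDNA = "cfdna"
SEQUENCE = "sequence"


class FeatureAssembler(BaseEstimator, TransformerMixin):
    """Assemble the numeric feature matrix for one classifier kind.

    Parameters are the fitted embedding/annotation components; ``fit`` only
    learns the cancer-type vocabulary and the training VAF median.
    """

    def __init__(self, kind: str = CFDNA, variant_embedder=None,
                 gene_embedder=None, functional_imputer=None):
        self.kind = kind
        self.variant_embedder = variant_embedder
        self.gene_embedder = gene_embedder
        self.functional_imputer = functional_imputer

    def fit(self, records: list[VariantRecord], y=None) -> "FeatureAssembler":
        if self.kind not in (CFDNA, SEQUENCE):
            raise ValueError(f"kind must be {CFDNA!r} or {SEQUENCE!r}")
        self.cancer_types_ = sorted(
            {r.cancer_type for r in records if r.cancer_type != UNKNOWN})
        vafs = [r.vaf for r in records if r.vaf is not None]
        self.vaf_median_ = float(np.median(vafs)) if vafs else 0.0
        self._build_layout()
        return self

    def _build_layout(self) -> None:
        dv = self.variant_embedder.dim
        dg = self.gene_embedder.dim
        df = len(self.functional_imputer.channel_names_) \
            if self.functional_imputer is not None else 0
        blocks = [("Ev", dv), ("Eg", dg)]
        if self.kind == CFDNA:
            blocks += [("Epv", dv), ("Epg", dg)]
        if df:
            blocks.append(("Ef", df))
        if self.kind == CFDNA:
            blocks.append(("VAF", 1))
        blocks.append(("Ct", len(self.cancer_types_) + 1))
        self.group_index_: dict[str, np.ndarray] = {}
        names: list[str] = []
        start = 0
        for name, width in blocks:
            self.group_index_[name] = np.arange(start, start + width)
            names.extend(f"{name}_{i}" for i in range(width))
            start += width
        self.feature_names_ = names
        self.n_features_ = start
        covered = np.concatenate(list(self.group_index_.values()))
        if sorted(covered) != list(range(self.n_features_)):
            raise GroupingError("group index does not partition the feature columns")

    def _check_fitted(self) -> None:
        if not hasattr(self, "group_index_"):
            raise StateError("FeatureAssembler is not fitted")

    def transform(self, records: list[VariantRecord]) -> np.ndarray:
        """Feature matrix; patient-level blocks average over this batch.

        The batch is therefore the patient context: pass a patient's full
        variant table (or a whole cohort) rather than isolated rows when the
        cfdna layout is in use.
        """
        self._check_fitted()
        n = len(records)
        X = np.zeros((n, self.n_features_))
        if n == 0:
            return X
        ev = self.variant_embedder.transform(records)
        eg = self.gene_embedder.transform([r.gene for r in records])
        X[:, self.group_index_["Ev"]] = ev
        X[:, self.group_index_["Eg"]] = eg
        if self.kind == CFDNA:
            patients = np.array([r.patient_id for r in records])
            epv = np.zeros_like(ev)
            epg = np.zeros((n, eg.shape[1]))
            for pid in np.unique(patients):
                mask = patients == pid
                epv[mask] = ev[mask].mean(axis=0)
                genes = sorted({r.gene for r, m in zip(records, mask) if m})
                epg[mask] = self.gene_embedder.transform(genes).mean(axis=0)
            X[:, self.group_index_["Epv"]] = epv
            X[:, self.group_index_["Epg"]] = epg
        if "Ef" in self.group_index_:
            X[:, self.group_index_["Ef"]] = self.functional_imputer.transform(records)
        if self.kind == CFDNA:
            vaf = np.array([self.vaf_median_ if r.vaf is None else r.vaf
                            for r in records])
            n_missing = sum(r.vaf is None for r in records)
            if n_missing:
                logger.info("imputed %d missing VAF values with training median %.4g",
                            n_missing, self.vaf_median_)
            X[:, self.group_index_["VAF"]] = vaf[:, None]
        ct_cols = self.group_index_["Ct"]
        slot = {ct: i for i, ct in enumerate(self.cancer_types_)}
        for i, rec in enumerate(records):
            j = slot.get(rec.cancer_type, len(self.cancer_types_))
            X[i, ct_cols[j]] = 1.0
        return X


def assemble_features(records: list[VariantRecord], variant_embedder,
                      gene_embedder, functional_imputer, kind: str):
    """One-shot wrapper: fit an assembler on the records and transform them.

    Returns ``(X, group_index)``.
    """
    asm = FeatureAssembler(kind=kind, variant_embedder=variant_embedder,
                           gene_embedder=gene_embedder,
                           functional_imputer=functional_imputer).fit(records)
    return asm.transform(records), asm.group_index_
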