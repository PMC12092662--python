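"""Functional-prediction score vectors (Ef): schema, ingestion, imputation.

The classifier stack consumes a fixed-width block of 37 numeric channels per
variant, the shape of compiled functional-annotation scores (deleteriousness
predictors and the like) for non-synonymous variants.  This module ingests a
precomputed annotation table keyed by (chrom, pos, ref, alt) and fills
missing cells — including entire vectors for variants absent from the table,
e.g. synonymous or non-coding ones — with per-channel medians computed over
the *training* variants only, so inference never leaks test information into
the fill values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import ImputationError, ParseError, SchemaError, StateError
from .variants import VariantRecord, variant_key

logger = logging.getLogger(__name__)

N_CHANNELS = 37

_KEY_COLUMNS = ("Chromosome", "Start_Position", "Reference_Allele", "Tumor_Seq_Allele2")


@dataclass
class FunctionalScoreVector:
    """Fixed-order numeric channels with per-channel observed/imputed flags."""

    values: np.ndarray          # (n_channels,), NaN where unobserved
    observed: np.ndarray        # (n_channels,) bool

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.observed = np.asarray(self.observed, dtype=bool)
        if self.values.shape != self.observed.shape:
            raise SchemaError("values/observed shape mismatch")


def load_annotation_table(path, channel_names: list[str]) -> dict[str, FunctionalScoreVector]:
    """Read a functional-annotation TSV into partially observed vectors.

    The file must contain the four variant-key columns plus exactly the given
    channels.  Empty cells are unobserved; non-numeric non-empty cells raise
    :class:`ParseError` with their coordinates.  Duplicate keys keep the
    first row.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _KEY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"annotation table missing key columns {missing}")
    file_channels = [c for c in df.columns if c not in _KEY_COLUMNS]
    if file_channels != list(channel_names):
        raise SchemaError(
            f"annotation table has {len(file_channels)} channel columns; "
            f"expected the {len(channel_names)} configured channels in order")
    out: dict[str, FunctionalScoreVector] = {}
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row = dict(zip(df.columns, row))
        key = (f"{row['Chromosome']}:{int(row['Start_Position'])}:"
               f"{row['Reference_Allele']}:{row['Tumor_Seq_Allele2']}")
        if key in out:
            logger.warning("duplicate annotation row for %s (row %d); first wins", key, i)
            continue
        values = np.full(len(channel_names), np.nan)
        for j, ch in enumerate(channel_names):
            cell = row[ch].strip()
            if cell == "":
                continue
            try:
                values[j] = float(cell)
            except ValueError:
                raise ParseError(
                    f"non-numeric cell at row {i}, channel {ch!r}: {cell!r}") from None
        out[key] = FunctionalScoreVector(values=values, observed=~np.isnan(values))
    return out


def annotation_from_dataframe(df: pd.DataFrame) -> dict[str, FunctionalScoreVector]:
    """Convert an in-memory annotation table (key columns + channels) to vectors."""
    channels = [c for c in df.columns if c not in _KEY_COLUMNS]
    out: dict[str, FunctionalScoreVector] = {}
    for row in df.itertuples(index=False):
        row = dict(zip(df.columns, row))
        key = (f"{row['Chromosome']}:{int(row['Start_Position'])}:"
               f"{row['Reference_Allele']}:{row['Tumor_Seq_Allele2']}")
        if key in out:
            continue
        values = np.array([np.nan if _blank(row[ch]) else float(row[ch])
                           for ch in channels])
        out[key] = FunctionalScoreVector(values=values, observed=~np.isnan(values))
    return out


def _blank(cell) -> bool:
    if cell is None:
        return True
    if isinstance(cell, float) and np.isnan(cell):
        return True
    return isinstance(cell, str) and cell.strip() == ""


class FunctionalImputer(BaseEstimator, TransformerMixin):
    """Median imputation of functional-score channels, training-set anchored.

    ``fit`` computes per-channel medians over the observed values of the
    training keys only; ``transform`` produces a dense (n, n_channels) matrix
    for arbitrary records or keys, filling unobserved cells — and whole
    vectors for unannotated variants — with the stored training medians.
    Deterministic and idempotent.
    """

    def __init__(self, channel_names: list[str] | None = None):
        self.channel_names = channel_names

    def fit(self, annotation: dict[str, FunctionalScoreVector],
            training_keys: set[str] | None = None) -> "FunctionalImputer":
        names = self.channel_names
        if names is None:
            any_vec = next(iter(annotation.values()), None)
            n = len(any_vec.values) if any_vec is not None else N_CHANNELS
            names = [f"channel_{i:02d}" for i in range(1, n + 1)]
        if training_keys is None:
            training_keys = set(annotation)
        if not training_keys:
            raise ImputationError("training_keys must be nonempty")
        stacked = [annotation[k].values for k in sorted(training_keys) if k in annotation]
        mat = np.vstack(stacked) if stacked else np.full((1, len(names)), np.nan)
        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", message="All-NaN slice")
            medians = np.nanmedian(mat, axis=0)
        for j, name in enumerate(names):
            if np.isnan(medians[j]):
                raise ImputationError(
                    f"channel {name!r} has no observed training values")
        self.channel_names_ = list(names)
        self.medians_ = medians
        self.annotation_ = annotation
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "medians_"):
            raise StateError("FunctionalImputer is not fitted")

    def set_annotation(self, annotation: dict[str, FunctionalScoreVector]) -> "FunctionalImputer":
        """Swap the observed-score lookup (e.g. for a new inference table).

        The training medians are untouched, preserving the no-leakage
        contract.
        """
        self._check_fitted()
        self.annotation_ = annotation
        return self

    def transform(self, items: list) -> np.ndarray:
        """Ef matrix for records or key strings (training medians fill gaps)."""
        self._check_fitted()
        keys = [variant_key(x) if isinstance(x, VariantRecord) else x for x in items]
        out = np.tile(self.medians_, (len(keys), 1))
        for i, key in enumerate(keys):
            vec = self.annotation_.get(key)
            if vec is not None:
                obs = vec.observed
                out[i, obs] = vec.values[obs]
        return out


def impute_scores(vectors: dict[str, FunctionalScoreVector],
                  training_keys: set[str]) -> dict[str, FunctionalScoreVector]:
    """Fill every missing cell with the per-channel training median.

    Returns a new map with all values finite and the original observed flags
    preserved (imputed cells keep ``observed=False``).
    """
    names = None
    imp = FunctionalImputer(channel_names=names).fit(vectors, training_keys)
    out = {}
    for key, vec in vectors.items():
        filled = vec.values.copy()
        filled[~vec.observed] = imp.medians_[~vec.observed]
        out[key] = FunctionalScoreVector(values=filled, observed=vec.observed.copy())
    return out
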